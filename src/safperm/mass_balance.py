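"""Yield and enrichment arithmetic for supercritical extraction and
antisolvent fractionation (SAF) experiments.

A SAF experiment sprays an ethanolic plant extract (the feed solution, FS)
into supercritical CO2.  Compounds insoluble in the CO2/ethanol mixture
precipitate in the precipitation vessel (PV); the rest travel dissolved to
the downstream vessel (DV).  Everything here is simple mass-balance
arithmetic: recovery yields are expressed in wt% on a 0-100 scale, and
enrichment ratios compare a compound's concentration in a collected
fraction against its concentration in the feed solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FractionMasses",
    "SAFRun",
    "ConcentrationRecord",
    "extraction_yield",
    "fraction_yield",
    "overall_yield",
    "concentration",
    "enrichment_ratio",
    "total_enrichment",
    "validate_mass_balance",
]


@dataclass(frozen=True)
class FractionMasses:
    """Masses charged to and collected from an extraction device.

    Parameters
    ----------
    extractor_load_mass:
        Mass (g) of dried plant material or extract charged.
    collected:
        Mapping from fraction label (e.g. ``C1``, ``C2``, ``PV``, ``DV``)
        to collected mass (g).
    """

    extractor_load_mass: float
    collected: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.extractor_load_mass <= 0:
            raise ValueError("extractor load mass must be positive")
        for label, mass in self.collected.items():
            if mass < 0:
                raise ValueError(f"collected mass for {label!r} is negative")


@dataclass(frozen=True)
class SAFRun:
    """One SAF experiment: operating conditions, yields and enrichments.

    ``enrichments`` maps a compound code (``CHA``, ``CAF``, ``FA``, or
    ``ALL`` for the pooled ratio) to its PV enrichment ratio; unmeasured
    entries are simply absent.
    """

    run_id: int
    pressure: float  # bar
    co2_flow: float  # g/min
    y_pv: float  # wt%
    y_dv: float  # wt%
    y_saf: float  # wt%
    enrichments: Mapping[str, float] = field(default_factory=dict)
    run_order: int | None = None

    def __post_init__(self) -> None:
        if self.y_pv < 0 or self.y_dv < 0:
            raise ValueError("fraction yields must be non-negative")
        for compound, ratio in self.enrichments.items():
            if ratio <= 0:
                raise ValueError(f"enrichment ratio for {compound!r} must be > 0")


@dataclass(frozen=True)
class ConcentrationRecord:
    """Concentration (wt%) of one compound in one SAF fraction."""

    compound: str
    fraction: str  # FS | PV | DV
    concentration: float  # wt%

    def __post_init__(self) -> None:
        if not 0 <= self.concentration <= 100:
            raise ValueError("concentration must lie in [0, 100] wt%")


def extraction_yield(collected_masses: Sequence[float], load_mass: float) -> float:
    """Extraction yield in wt%: collected mass over charged mass.

    Covers both the supercritical-CO2 defatting step (several collectors)
    and the single-collector ethanol maceration step.
    """
    if load_mass <= 0:
        raise ValueError("load mass must be positive")
    total = 0.0
    for mass in collected_masses:
        if mass < 0:
            raise ValueError("collected masses must be non-negative")
        total += mass
    return 100.0 * total / load_mass


def fraction_yield(fraction_mass: float, fs_extract_mass: float) -> float:
    """Recovery yield (wt%) of one SAF vessel relative to the extract fed."""
    if fs_extract_mass <= 0:
        raise ValueError("feed-solution extract mass must be positive")
    if fraction_mass < 0:
        raise ValueError("fraction mass must be non-negative")
    return 100.0 * fraction_mass / fs_extract_mass


def overall_yield(y_pv: float, y_dv: float) -> float:
    """Overall SAF recovery: the sum of the PV and DV yields (wt%)."""
    if y_pv < 0 or y_dv < 0:
        raise ValueError("yields must be non-negative")
    return y_pv + y_dv


def concentration(mass_compound: float, mass_fraction: float) -> float:
    """Concentration (wt%) of a compound within a collected fraction."""
    if mass_fraction <= 0:
        raise ValueError("fraction mass must be positive")
    if mass_compound < 0:
        raise ValueError("compound mass must be non-negative")
    if mass_compound > mass_fraction:
        raise ValueError("compound mass cannot exceed fraction mass")
    return 100.0 * mass_compound / mass_fraction


def enrichment_ratio(c_fraction: float, c_fs: float) -> float:
    """Enrichment of a compound in a fraction relative to the feed solution."""
    if c_fs <= 0:
        raise ValueError("feed-solution concentration must be positive")
    if c_fraction < 0:
        raise ValueError("fraction concentration must be non-negative")
    return c_fraction / c_fs


def total_enrichment(
    c_pv: Mapping[str, float], c_fs: Mapping[str, float]
) -> float:
    """Pooled enrichment of all tracked compounds in the PV fraction.

    The sums run over the same compound set in numerator (PV) and
    denominator (FS); this is a concentration-weighted mean of the
    individual enrichment ratios.
    """
    if set(c_pv) != set(c_fs):
        raise KeyError(
            "compound keys differ between PV and FS maps: "
            f"{sorted(set(c_pv) ^ set(c_fs))}"
        )
    denom = sum(c_fs.values())
    if denom <= 0:
        raise ValueError("total feed-solution concentration must be positive")
    return sum(c_pv.values()) / denom


def validate_mass_balance(
    runs: Iterable[SAFRun], tolerance: float = 0.05
) -> list[SAFRun]:
    """Return the runs whose overall yield breaks Y_SAF = Y_PV + Y_DV.

    The default tolerance of 0.05 wt% is half a unit of the last digit at
    which yields are typically tabulated (0.1 wt%).
    """
    return [
        run
        for run in runs
        if abs(run.y_saf - (run.y_pv + run.y_dv)) > tolerance
    ]
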