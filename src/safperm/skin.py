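"""Compartmental series-parallel resistance model of epidermal permeation.

The epidermis is modelled as four stacked compartments — stratum corneum
(SC), granulosum (SG), spinosum (SS) and basale (SB), outermost to
innermost.  Within each compartment a permeant can take two parallel
routes, intercellular (between cells, through the lipid matrix) or
transcellular (through the cells), whose resistances combine harmonically.
The four combined compartment resistances add in series to give the
stratified-cell resistance, which is then in parallel with a fixed-
conductance shunt route (hair follicles and glands).  The permeability
coefficient is the reciprocal of the total skin resistance, reported as
log10 in cm/s, and corrected by a constant empirical offset.

Units: resistances in s/m; permeability logs in cm/s, so
log10 Kp = log10(100 / R) for R in s/m.  The desquamation comparison is
made on the m/s scale (subtract 2 from a cm/s log).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "COMPARTMENTS",
    "CompartmentResistance",
    "ResistanceProfile",
    "PermeabilityResult",
    "DEFAULT_SHUNT_CONDUCTANCE",
    "DEFAULT_OFFSET",
    "DEFAULT_LOG_KD",
    "combine_pathways",
    "stratified_resistance",
    "skin_resistance",
    "log_permeability",
    "corrected_log_permeability",
    "analyze",
    "deviation_vs_reference",
]

#: Epidermal compartments, outermost first.  The order fixes the
#: rate-limiting tie-break: the barrier met first wins.
COMPARTMENTS = ("SC", "SG", "SS", "SB")

DEFAULT_SHUNT_CONDUCTANCE = 2e-11  # m/s, appendageal (follicle/gland) route
DEFAULT_OFFSET = -1.12  # log10(cm/s), empirical calibration offset
DEFAULT_LOG_KD = -9.0  # log10(m/s), desquamation (skin turnover) rate


@dataclass(frozen=True)
class CompartmentResistance:
    """Parallel-pathway resistances of one epidermal compartment (s/m).

    A blocked pathway is represented by ``math.inf``.
    """

    compartment: str
    r_inter: float
    r_trans: float

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        for name, r in (("r_inter", self.r_inter), ("r_trans", self.r_trans)):
            if not r > 0:
                raise ValueError(f"{name} must be positive (inf allowed), got {r}")

    @property
    def combined(self) -> float:
        return combine_pathways(self.r_inter, self.r_trans)

    @property
    def preferred_pathway(self) -> str:
        """The lower-resistance (dominant) route; ties go to ``inter``."""
        return "inter" if self.r_inter <= self.r_trans else "trans"


@dataclass(frozen=True)
class ResistanceProfile:
    """Full epidermal resistance profile for one compound.

    ``log_k_vehicle_water`` shifts the predicted log Kp additively for a
    non-aqueous vehicle; it is 0 for water.
    """

    compound: str
    compartments: Mapping[str, CompartmentResistance]
    vehicle: str = "water"
    log_k_vehicle_water: float = 0.0
    shunt_conductance: float = DEFAULT_SHUNT_CONDUCTANCE  # m/s
    offset: float = DEFAULT_OFFSET  # log10(cm/s)
    log_kd: float = DEFAULT_LOG_KD  # log10(m/s)

    def __post_init__(self) -> None:
        if set(self.compartments) != set(COMPARTMENTS):
            raise ValueError(
                f"profile must define exactly the compartments {COMPARTMENTS}, "
                f"got {sorted(self.compartments)}"
            )
        if self.shunt_conductance < 0:
            raise ValueError("shunt conductance must be non-negative")


def combine_pathways(r_inter: float, r_trans: float) -> float:
    """Parallel (harmonic) combination of the two pathway resistances."""
    for name, r in (("r_inter", r_inter), ("r_trans", r_trans)):
        if not r > 0:
            raise ValueError(f"{name} must be positive (inf allowed), got {r}")
    if math.isinf(r_inter) and math.isinf(r_trans):
        return math.inf
    g = (0.0 if math.isinf(r_inter) else 1.0 / r_inter) + (
        0.0 if math.isinf(r_trans) else 1.0 / r_trans
    )
    return 1.0 / g


def stratified_resistance(r_sc: float, r_sg: float, r_ss: float, r_sb: float) -> float:
    """Serial sum of the four combined compartment resistances (s/m)."""
    for name, r in (("r_sc", r_sc), ("r_sg", r_sg), ("r_ss", r_ss), ("r_sb", r_sb)):
        if not r > 0:
            raise ValueError(f"{name} must be positive, got {r}")
    return r_sc + r_sg + r_ss + r_sb


def skin_resistance(r_cells: float, shunt_conductance: float) -> float:
    """Stratified-cell resistance in parallel with the shunt route."""
    if not r_cells > 0:
        raise ValueError(f"r_cells must be positive, got {r_cells}")
    if shunt_conductance < 0:
        raise ValueError("shunt conductance must be non-negative")
    if shunt_conductance == 0.0:
        return r_cells  # no shunt: exact identity, no reciprocal round-trip
    return 1.0 / (1.0 / r_cells + shunt_conductance)


def log_permeability(r: float) -> float:
    """log10 permeability in cm/s from a resistance in s/m.

    Kp = 1/R is in m/s; the factor 100 converts to cm/s before the log.
    """
    if not r > 0 or math.isinf(r):
        raise ValueError(f"resistance must be positive and finite, got {r}")
    return math.log10(100.0 / r)


def corrected_log_permeability(logkp_pred: float, offset: float = DEFAULT_OFFSET) -> float:
    """Apply the constant empirical calibration offset (both in log10 cm/s)."""
    return logkp_pred + offset


def deviation_vs_reference(logkp_corrected: float, reference: float) -> float:
    """Reference minus corrected prediction (both log10 cm/s).

    Positive values mean the model under-predicts the reference
    permeability.
    """
    return reference - logkp_corrected


@dataclass(frozen=True)
class PermeabilityResult:
    """Composed resistances, permeability and classification for one compound."""

    compound: str
    compartment_resistance: Mapping[str, float]  # combined R_i, s/m
    preferred_pathway: Mapping[str, str]  # inter | trans per compartment
    layer_log_permeability: Mapping[str, float]  # log10(100 / R_i), cm/s
    r_stratified_cells: float  # s/m
    r_skin: float  # s/m
    logkp_pred: float  # log10(cm/s)
    logkp_corrected: float  # log10(cm/s)
    rate_limiting_compartment: str
    classification: str
    deviations: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "compartment_resistance_s_per_m": dict(self.compartment_resistance),
            "preferred_pathway": dict(self.preferred_pathway),
            "layer_log_permeability_cm_per_s": dict(self.layer_log_permeability),
            "r_stratified_cells_s_per_m": self.r_stratified_cells,
            "r_skin_s_per_m": self.r_skin,
            "log_kp_pred_cm_per_s": self.logkp_pred,
            "log_kp_corrected_cm_per_s": self.logkp_corrected,
            "rate_limiting_compartment": self.rate_limiting_compartment,
            "classification": self.classification,
            "deviations": dict(self.deviations),
        }


def analyze(
    profile: ResistanceProfile,
    references: Mapping[str, float] | None = None,
) -> PermeabilityResult:
    """Run the full resistance-network analysis for one compound.

    Composes the per-compartment parallel combinations, the serial
    stratified-cell sum, the shunt-parallel total resistance and the
    permeability conversion; identifies the rate-limiting compartment
    (largest combined resistance; ties go to the outermost layer) and its
    dominant pathway; and classifies safety:

    * ``"retained in SC"`` — the stratum corneum, a layer of dead cells
      where no irritation occurs, is rate limiting;
    * ``"safe — below desquamation"`` — a deeper layer is rate limiting
      but the corrected permeability (on the m/s scale) stays below the
      desquamation rate, so skin turnover outpaces penetration;
    * ``"flag for review"`` — a deeper layer is rate limiting and the
      permeability exceeds the desquamation rate.

    ``references`` optionally maps reference-source labels to measured or
    independently calculated log Kp values (cm/s); the matching deviations
    (reference minus corrected) are included in the result.
    """
    combined = {
        name: profile.compartments[name].combined for name in COMPARTMENTS
    }
    pathways = {
        name: profile.compartments[name].preferred_pathway for name in COMPARTMENTS
    }
    layer_logkp = {
        name: log_permeability(r) if math.isfinite(r) else -math.inf
        for name, r in combined.items()
    }
    r_cells = stratified_resistance(*(combined[name] for name in COMPARTMENTS))
    r_skin = skin_resistance(r_cells, profile.shunt_conductance)
    logkp_pred = log_permeability(r_skin) + profile.log_k_vehicle_water
    logkp_corr = corrected_log_permeability(logkp_pred, profile.offset)

    # argmax of combined resistance; COMPARTMENTS order breaks ties
    # outermost-first.
    rate_limiting = max(COMPARTMENTS, key=lambda name: (combined[name], -COMPARTMENTS.index(name)))

    if rate_limiting == "SC":
        classification = "retained in SC"
    elif logkp_corr - 2.0 < profile.log_kd:  # cm/s -> m/s
        classification = "safe — below desquamation"
    else:
        classification = "flag for review"

    deviations = {}
    if references:
        deviations = {
            label: deviation_vs_reference(logkp_corr, ref)
            for label, ref in references.items()
        }

    return PermeabilityResult(
        compound=profile.compound,
        compartment_resistance=combined,
        preferred_pathway=pathways,
        layer_log_permeability=layer_logkp,
        r_stratified_cells=r_cells,
        r_skin=r_skin,
        logkp_pred=logkp_pred,
        logkp_corrected=logkp_corr,
        rate_limiting_compartment=rate_limiting,
        classification=classification,
        deviations=deviations,
    )
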