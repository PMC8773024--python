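"""Seeded generators emulating the study's data-generating assumptions.

Two kinds of synthetic data make every stage testable without downloads:

* noisy quadratic response surfaces sampled on the CCD — the measurement
  model implicitly assumed by the OLS analysis (polynomial mean plus
  independent homoscedastic Gaussian error);
* random layered resistance profiles — log-uniform draws per compartment
  and pathway, covering the many-orders-of-magnitude spread seen in real
  membrane resistances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .rsm import DesignSpec, DesignTable, generate_ccd
from .skin import (
    COMPARTMENTS,
    DEFAULT_LOG_KD,
    DEFAULT_OFFSET,
    DEFAULT_SHUNT_CONDUCTANCE,
    CompartmentResistance,
    ResistanceProfile,
)

__all__ = ["SurfaceTruth", "ProfileTruth", "simulate_saf_table", "simulate_profile"]


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground-truth quadratic surface and noise level for one response.

    ``coefficients`` uses the natural-unit term names (``intercept``,
    ``P``, ``Q``, ``P2``, ``Q2``, ``PQ``); absent terms are zero.
    ``sigma`` is the Gaussian error standard deviation in the response
    units.
    """

    coefficients: Mapping[str, float]
    sigma: float
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((80.0, 160.0), (10.0, 60.0))

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise standard deviation must be non-negative")

    def mean(self, pressure: float, flow: float) -> float:
        c = self.coefficients
        return (
            c.get("intercept", 0.0)
            + c.get("P", 0.0) * pressure
            + c.get("Q", 0.0) * flow
            + c.get("P2", 0.0) * pressure**2
            + c.get("Q2", 0.0) * flow**2
            + c.get("PQ", 0.0) * pressure * flow
        )


def simulate_saf_table(
    truths: Mapping[str, SurfaceTruth] | SurfaceTruth,
    spec: DesignSpec,
    seed: int,
    design: DesignTable | None = None,
) -> pd.DataFrame:
    """Draw one synthetic run table on the CCD.

    Each design row gets one draw per response, ``mean(point) + N(0, s^2)``.
    Negative draws are clipped to zero (yields are mass fractions) and
    flagged in a boolean ``<response>_clipped`` column.  A single
    ``SurfaceTruth`` simulates a lone response named ``response``.
    Reproducible for a fixed ``seed``; the design row order itself is
    randomized from the same seed unless an explicit ``design`` is given.
    """
    if isinstance(truths, SurfaceTruth):
        truths = {"response": truths}
    rng = np.random.default_rng(seed)
    if design is None:
        design = generate_ccd(spec, seed)
    for name, truth in truths.items():
        (p_lo, p_hi), (q_lo, q_hi) = truth.bounds
        for row in design.rows:
            p, q = row.natural
            if not (p_lo <= p <= p_hi and q_lo <= q <= q_hi):
                raise ValueError(
                    f"truth bounds for {name!r} do not cover design point {row.natural}"
                )

    data: dict[str, list] = {
        "run_id": [row.run_id for row in design.rows],
        "pressure_bar": [row.natural[0] for row in design.rows],
        "co2_flow_g_min": [row.natural[1] for row in design.rows],
    }
    for name, truth in truths.items():
        means = np.array([truth.mean(*row.natural) for row in design.rows])
        draws = means + rng.normal(0.0, truth.sigma, size=len(means))
        clipped = draws < 0
        draws = np.where(clipped, 0.0, draws)
        data[name] = draws.tolist()
        data[f"{name}_clipped"] = clipped.tolist()
    return pd.DataFrame(data)


@dataclass(frozen=True)
class ProfileTruth:
    """Log-uniform sampling ranges for random resistance profiles.

    ``inter_range`` / ``trans_range`` map each compartment to a positive
    ``(low, high)`` resistance interval in s/m; draws are uniform in
    log10 space.
    """

    inter_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {name: (1e6, 1e17) for name in COMPARTMENTS}
    )
    trans_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {name: (1e5, 1e12) for name in COMPARTMENTS}
    )
    shunt_conductance: float = DEFAULT_SHUNT_CONDUCTANCE
    offset: float = DEFAULT_OFFSET
    log_kd: float = DEFAULT_LOG_KD

    def __post_init__(self) -> None:
        for ranges in (self.inter_range, self.trans_range):
            missing = set(COMPARTMENTS) - set(ranges)
            if missing:
                raise ValueError(f"missing range(s) for compartment(s) {sorted(missing)}")
            for name, (lo, hi) in ranges.items():
                if not 0 < lo <= hi:
                    raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def simulate_profile(
    truth: ProfileTruth, seed: int, compound: str = "synthetic"
) -> ResistanceProfile:
    """Draw one random resistance profile, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    compartments = {}
    for name in COMPARTMENTS:
        lo_i, hi_i = truth.inter_range[name]
        lo_t, hi_t = truth.trans_range[name]
        r_inter = 10 ** rng.uniform(np.log10(lo_i), np.log10(hi_i))
        r_trans = 10 ** rng.uniform(np.log10(lo_t), np.log10(hi_t))
        compartments[name] = CompartmentResistance(name, float(r_inter), float(r_trans))
    return ResistanceProfile(
        compound=compound,
        compartments=compartments,
        shunt_conductance=truth.shunt_conductance,
        offset=truth.offset,
        log_kd=truth.log_kd,
    )
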