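"""Multi-response optimization over fitted surfaces via desirability
functions.

Each response value is mapped onto a dimensionless score d in [0, 1] by a
piecewise-linear (optionally power-weighted) ramp between user-chosen
anchors, and the composite desirability D is the geometric mean of the
individual scores.  The optimum is located by a deterministic dense grid
scan over the factor rectangle followed by a derivative-free local polish,
so results are reproducible without seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

from .rsm import QuadraticFit, predict_surface

__all__ = [
    "DesirabilitySpec",
    "CompositeResult",
    "individual_desirability",
    "composite_desirability",
    "optimize",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Goal and anchors for one response.

    ``goal`` is ``"maximize"``, ``"minimize"`` or ``"target"``.  ``low``
    and ``high`` anchor the 0/1 ends of the ramp; for a target goal the
    score peaks at ``target`` and falls to zero at both anchors.  ``weight``
    is the ramp exponent (1 = linear).
    """

    response: str
    goal: str = "maximize"
    low: float = 0.0
    high: float = 1.0
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if self.low >= self.high:
            raise ValueError("lower anchor must be below upper anchor")
        if self.weight <= 0:
            raise ValueError("weight exponent must be positive")
        if self.goal == "target":
            if self.target is None:
                raise ValueError("target goal requires a target value")
            if not self.low < self.target < self.high:
                raise ValueError("target must lie strictly between the anchors")

    @property
    def effective_target(self) -> float:
        if self.goal == "maximize":
            return self.high
        if self.goal == "minimize":
            return self.low
        return float(self.target)  # type: ignore[arg-type]


def individual_desirability(value: float, spec: DesirabilitySpec) -> float:
    """Map one response value to its desirability score in [0, 1]."""
    lo, hi, w = spec.low, spec.high, spec.weight
    if spec.goal == "maximize":
        if value <= lo:
            return 0.0
        if value >= hi:
            return 1.0
        return ((value - lo) / (hi - lo)) ** w
    if spec.goal == "minimize":
        if value >= hi:
            return 0.0
        if value <= lo:
            return 1.0
        return ((hi - value) / (hi - lo)) ** w
    t = float(spec.target)  # type: ignore[arg-type]
    if value <= lo or value >= hi:
        return 0.0
    if value <= t:
        return ((value - lo) / (t - lo)) ** w
    return ((hi - value) / (hi - t)) ** w


def composite_desirability(
    values: Mapping[str, float], specs: Mapping[str, DesirabilitySpec]
) -> float:
    """Equal-weight geometric mean of the individual desirabilities."""
    if set(values) != set(specs):
        raise KeyError(
            f"response keys differ: {sorted(set(values) ^ set(specs))}"
        )
    if not values:
        raise ValueError("at least one response is required")
    scores = [individual_desirability(values[name], specs[name]) for name in values]
    if any(d == 0.0 for d in scores):
        return 0.0
    return math.exp(sum(math.log(d) for d in scores) / len(scores))


@dataclass(frozen=True)
class CompositeResult:
    """Optimum found by the desirability search."""

    point: tuple[float, float]  # (pressure bar, flow g/min)
    composite: float  # D in [0, 1]
    individual: Mapping[str, float]
    predictions: Mapping[str, float]
    degenerate: bool = False  # True when D == 0 everywhere on the grid

    def to_dict(self) -> dict:
        return {
            "pressure_bar": self.point[0],
            "co2_flow_g_min": self.point[1],
            "composite_desirability": self.composite,
            "individual_desirability": dict(self.individual),
            "predicted_responses": dict(self.predictions),
            "degenerate": self.degenerate,
        }


def _evaluate(
    point: tuple[float, float],
    fits: Mapping[str, QuadraticFit],
    specs: Mapping[str, DesirabilitySpec],
) -> tuple[float, dict[str, float], dict[str, float]]:
    import warnings as _warnings

    preds = {}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # grid edges may brush the domain
        for name, fit in fits.items():
            preds[name] = predict_surface(fit, point)
    scores = {name: individual_desirability(preds[name], specs[name]) for name in fits}
    if any(d == 0.0 for d in scores.values()):
        comp = 0.0
    else:
        comp = math.exp(sum(math.log(d) for d in scores.values()) / len(scores))
    return comp, scores, preds


def optimize(
    fits: Mapping[str, QuadraticFit],
    specs: Mapping[str, DesirabilitySpec],
    bounds: tuple[tuple[float, float], tuple[float, float]],
    grid: int = 201,
) -> CompositeResult:
    """Locate the point of maximum composite desirability.

    A dense ``grid`` x ``grid`` scan over the ``((p_lo, p_hi), (q_lo, q_hi))``
    rectangle finds the best cell; a bounded Nelder-Mead polish refines it.
    Deterministic for fixed inputs.  When every grid point scores zero the
    result is returned with ``degenerate=True`` rather than raising.
    """
    if set(fits) != set(specs):
        raise KeyError(f"response keys differ: {sorted(set(fits) ^ set(specs))}")
    if not fits:
        raise ValueError("at least one response is required")
    (p_lo, p_hi), (q_lo, q_hi) = bounds
    if p_hi <= p_lo or q_hi <= q_lo:
        raise ValueError("bounds rectangle is degenerate")
    if grid < 2:
        raise ValueError("grid resolution must be at least 2")

    p_axis = np.linspace(p_lo, p_hi, grid)
    q_axis = np.linspace(q_lo, q_hi, grid)
    best_point, best_comp = (p_axis[0], q_axis[0]), -1.0
    # Vectorized scan: evaluate every surface on the lattice at once.
    pp, qq = np.meshgrid(p_axis, q_axis, indexing="ij")
    log_sum = np.zeros_like(pp)
    zero_mask = np.zeros_like(pp, dtype=bool)
    for name, fit in fits.items():
        c = fit.coefficients
        vals = (
            c.get("intercept", 0.0)
            + c.get("P", 0.0) * pp
            + c.get("Q", 0.0) * qq
            + c.get("P2", 0.0) * pp * pp
            + c.get("Q2", 0.0) * qq * qq
            + c.get("PQ", 0.0) * pp * qq
        )
        spec = specs[name]
        d = np.array([[individual_desirability(float(v), spec) for v in row] for row in vals])
        zero_mask |= d == 0.0
        with np.errstate(divide="ignore"):
            log_sum += np.where(d > 0, np.log(np.maximum(d, 1e-300)), 0.0)
    comp_grid = np.where(zero_mask, 0.0, np.exp(log_sum / len(fits)))
    flat = int(np.argmax(comp_grid))
    i, j = np.unravel_index(flat, comp_grid.shape)
    best_point = (float(p_axis[i]), float(q_axis[j]))
    best_comp = float(comp_grid[i, j])

    if best_comp == 0.0:
        comp, scores, preds = _evaluate(best_point, fits, specs)
        return CompositeResult(best_point, 0.0, scores, preds, degenerate=True)

    # Local polish from the best grid cell.
    def negated(x: np.ndarray) -> float:
        comp, _, _ = _evaluate((float(x[0]), float(x[1])), fits, specs)
        return -comp

    res = minimize(
        negated,
        x0=np.array(best_point),
        method="Nelder-Mead",
        bounds=[(p_lo, p_hi), (q_lo, q_hi)],
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    polished = (float(res.x[0]), float(res.x[1]))
    comp, scores, preds = _evaluate(polished, fits, specs)
    if comp < best_comp:  # polish never worsens the result
        polished = best_point
        comp, scores, preds = _evaluate(best_point, fits, specs)
    return CompositeResult(polished, comp, scores, preds)
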