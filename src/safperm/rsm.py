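"""Central composite design (CCD) construction and quadratic response
surface fitting for the two-factor SAF study (pressure, CO2 flow rate).

The response model is the full second-order polynomial

    Y = b0 + b1*P + b2*Q + b11*P^2 + b22*Q^2 + b12*P*Q

with any subset of the non-intercept terms switchable off per response.
Fitting is ordinary least squares via statsmodels.  Coefficients are
always reported in natural (uncoded) units.  Standard errors and t-test
p-values are computed, by default, in a centered/scaled parametrization
of the factors (each factor shifted to its mid-range and divided by its
half-range): this is the parametrization in which commercial DOE software
reports its coefficient table, and centering changes the linear-term
t-tests because it de-aliases linear from quadratic columns.  Predictions
and the back-transformed coefficients are identical either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "TERM_NAMES",
    "ModelTermSet",
    "DesignSpec",
    "DesignPoint",
    "DesignTable",
    "QuadraticFit",
    "CALENDULA_DESIGN",
    "generate_ccd",
    "fit_quadratic",
    "predict_surface",
    "stationary_point",
    "contour_grid",
]

#: Canonical order of the polynomial terms.  ``P`` is pressure (bar),
#: ``Q`` the CO2 flow rate (g/min).
TERM_NAMES = ("intercept", "P", "Q", "P2", "Q2", "PQ")


@dataclass(frozen=True)
class ModelTermSet:
    """Which terms of the quadratic polynomial are active.

    The intercept is always included.  Named presets mirror the reduced
    models used for the SAF responses: the PV yield drops the quadratic
    flow term, the enrichment ratios drop the interaction term.
    """

    linear_p: bool = True
    linear_q: bool = True
    quad_p: bool = True
    quad_q: bool = True
    interaction: bool = True

    @property
    def active(self) -> tuple[str, ...]:
        names = ["intercept"]
        if self.linear_p:
            names.append("P")
        if self.linear_q:
            names.append("Q")
        if self.quad_p:
            names.append("P2")
        if self.quad_q:
            names.append("Q2")
        if self.interaction:
            names.append("PQ")
        return tuple(names)

    @classmethod
    def from_name(cls, name: str) -> "ModelTermSet":
        presets = {
            "full": cls(),
            "no-q2": cls(quad_q=False),
            "no_flow_sq": cls(quad_q=False),
            "no-interaction": cls(interaction=False),
            "no_interaction": cls(interaction=False),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(
                f"unknown term-set name {name!r}; expected one of {sorted(presets)}"
            ) from None


FULL = ModelTermSet()
NO_FLOW_SQ = ModelTermSet(quad_q=False)
NO_INTERACTION = ModelTermSet(interaction=False)


@dataclass(frozen=True)
class DesignSpec:
    """Factor names, coded levels and their natural-unit values for a CCD.

    ``pressure_levels`` / ``flow_levels`` map each coded level to its
    natural value.  The natural levels are taken verbatim rather than
    derived from a star distance, so slightly rounded axial points (as in
    the published design, where the printed levels imply a star distance
    of ~1.43 / ~1.39 rather than the labelled 1.44) are represented
    faithfully.
    """

    factors: tuple[str, str] = ("pressure", "co2_flow")
    coded_levels: tuple[float, ...] = (-1.44, -1.0, 0.0, 1.0, 1.44)
    pressure_levels: Mapping[float, float] = field(
        default_factory=lambda: {-1.44: 80.0, -1.0: 92.0, 0.0: 120.0, 1.0: 148.0, 1.44: 160.0}
    )
    flow_levels: Mapping[float, float] = field(
        default_factory=lambda: {-1.44: 10.0, -1.0: 17.0, 0.0: 35.0, 1.0: 53.0, 1.44: 60.0}
    )
    center_replicates: int = 5

    def __post_init__(self) -> None:
        for levels, name in ((self.pressure_levels, "pressure"), (self.flow_levels, "flow")):
            missing = [c for c in self.coded_levels if c not in levels]
            if missing:
                raise ValueError(f"missing natural {name} level(s) for coded {missing}")
            naturals = [levels[c] for c in sorted(levels)]
            if any(b <= a for a, b in zip(naturals, naturals[1:])):
                raise ValueError(f"natural {name} levels must increase with coded levels")

    @property
    def star(self) -> float:
        return max(self.coded_levels)


#: The published two-factor design: pressure 80-160 bar, flow 10-60 g/min,
#: five center replicates (13 runs total).
CALENDULA_DESIGN = DesignSpec()


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    coded: tuple[float, float]
    natural: tuple[float, float]


@dataclass(frozen=True)
class DesignTable:
    spec: DesignSpec
    rows: tuple[DesignPoint, ...]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def natural_points(self) -> list[tuple[float, float]]:
        return [row.natural for row in self.rows]


def generate_ccd(spec: DesignSpec, seed: int) -> DesignTable:
    """Build the randomized run list of a two-factor CCD.

    4 factorial points (+-1, +-1), 4 axial points on the coded star
    distance, and the requested number of center replicates; the row order
    is shuffled deterministically by ``seed`` and run ids are assigned in
    execution order.
    """
    a = spec.star
    coded_points = [(-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0)]
    coded_points += [(-a, 0.0), (a, 0.0), (0.0, -a), (0.0, a)]
    coded_points += [(0.0, 0.0)] * spec.center_replicates

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(coded_points))
    rows = []
    for run_id, idx in enumerate(order, start=1):
        cx, cq = coded_points[idx]
        natural = (spec.pressure_levels[cx], spec.flow_levels[cq])
        rows.append(DesignPoint(run_id=run_id, coded=(cx, cq), natural=natural))
    return DesignTable(spec=spec, rows=tuple(rows))


@dataclass(frozen=True)
class QuadraticFit:
    """OLS fit of the (possibly reduced) quadratic surface for one response.

    ``coefficients`` are in natural units.  ``standard_errors`` and
    ``p_values`` belong to the parametrization named by ``coding``
    (``"centered"`` or ``"natural"``); see the module docstring.
    ``r_squared`` is on the 0-100 scale; ``residual_sd`` is
    sqrt(SS_res / (n - k)).  ``domain`` is the bounding box of the
    training points, used to flag extrapolation.
    """

    response: str
    terms: ModelTermSet
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    r_squared: float
    residual_sd: float
    df_resid: int
    coding: str
    domain: tuple[tuple[float, float], tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": list(self.terms.active),
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "p_values": dict(self.p_values),
            "r_squared_pct": self.r_squared,
            "residual_sd": self.residual_sd,
            "df_resid": self.df_resid,
            "coding": self.coding,
            "domain": [list(self.domain[0]), list(self.domain[1])],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuadraticFit":
        active = set(d["terms"])
        terms = ModelTermSet(
            linear_p="P" in active,
            linear_q="Q" in active,
            quad_p="P2" in active,
            quad_q="Q2" in active,
            interaction="PQ" in active,
        )
        return cls(
            response=d["response"],
            terms=terms,
            coefficients=dict(d["coefficients"]),
            standard_errors=dict(d.get("standard_errors", {})),
            p_values=dict(d.get("p_values", {})),
            r_squared=float(d["r_squared_pct"]),
            residual_sd=float(d["residual_sd"]),
            df_resid=int(d.get("df_resid", 0)),
            coding=d.get("coding", "centered"),
            domain=(
                tuple(d.get("domain", [[80.0, 160.0], [10.0, 60.0]])[0]),
                tuple(d.get("domain", [[80.0, 160.0], [10.0, 60.0]])[1]),
            ),
        )


def _design_columns(p: np.ndarray, q: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "intercept": np.ones_like(p),
        "P": p,
        "Q": q,
        "P2": p * p,
        "Q2": q * q,
        "PQ": p * q,
    }


def _collinear_terms(X: np.ndarray, names: Sequence[str]) -> list[str]:
    full_rank = np.linalg.matrix_rank(X)
    involved = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            involved.append(name)
    return involved or list(names)


def fit_quadratic(
    data: Sequence[tuple[tuple[float, float], float]],
    terms: ModelTermSet = FULL,
    response: str = "response",
    coding: str = "centered",
) -> QuadraticFit:
    """Fit the quadratic surface to ``(natural point, response)`` pairs by OLS.

    Parameters
    ----------
    data:
        Sequence of ``((pressure, flow), value)`` observations in natural
        units.
    terms:
        Which polynomial terms to include (intercept always active).
    coding:
        ``"centered"`` (default) fits on mid-range-centered, half-range-
        scaled factors and back-transforms the coefficients to natural
        units exactly; ``"natural"`` fits the raw polynomial.  The choice
        affects only the reported standard errors and p-values.
    """
    if coding not in ("centered", "natural"):
        raise ValueError("coding must be 'centered' or 'natural'")
    points = np.asarray([pt for pt, _ in data], dtype=float)
    y = np.asarray([val for _, val in data], dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("each observation needs a (pressure, flow) point")
    n = len(y)
    active = terms.active
    k = len(active)
    if n <= k:
        raise ValueError(f"need more than {k} observations for {k} active terms, got {n}")

    p, q = points[:, 0], points[:, 1]
    if coding == "centered":
        cp, cq = (p.min() + p.max()) / 2.0, (q.min() + q.max()) / 2.0
        sp = (p.max() - p.min()) / 2.0 or 1.0
        sq = (q.max() - q.min()) / 2.0 or 1.0
    else:
        cp = cq = 0.0
        sp = sq = 1.0
    u, v = (p - cp) / sp, (q - cq) / sq

    cols = _design_columns(u, v)
    X = np.column_stack([cols[name] for name in active])
    if np.linalg.matrix_rank(X) < k:
        bad = _collinear_terms(X, active)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear terms: {bad}"
        )

    res = sm.OLS(y, X).fit()
    fitted = dict(zip(active, res.params))

    # Exact back-transform of the centered-parametrization coefficients to
    # the natural-unit polynomial; identity when coding == "natural".
    a = {name: fitted.get(name, 0.0) for name in TERM_NAMES}
    nat = {
        "P2": a["P2"] / sp**2,
        "Q2": a["Q2"] / sq**2,
        "PQ": a["PQ"] / (sp * sq),
    }
    nat["P"] = a["P"] / sp - 2 * a["P2"] * cp / sp**2 - a["PQ"] * cq / (sp * sq)
    nat["Q"] = a["Q"] / sq - 2 * a["Q2"] * cq / sq**2 - a["PQ"] * cp / (sp * sq)
    nat["intercept"] = (
        a["intercept"]
        - a["P"] * cp / sp
        - a["Q"] * cq / sq
        + a["P2"] * cp**2 / sp**2
        + a["Q2"] * cq**2 / sq**2
        + a["PQ"] * cp * cq / (sp * sq)
    )
    coefficients = {name: float(nat[name]) for name in active}

    ss_res = float(res.ssr)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 100.0 * (1.0 - ss_res / ss_tot) if ss_tot > 0 else 100.0
    s = float(np.sqrt(ss_res / res.df_resid)) if res.df_resid > 0 else 0.0

    domain = ((float(p.min()), float(p.max())), (float(q.min()), float(q.max())))
    return QuadraticFit(
        response=response,
        terms=terms,
        coefficients=coefficients,
        standard_errors={name: float(se) for name, se in zip(active, res.bse)},
        p_values={name: float(pv) for name, pv in zip(active, res.pvalues)},
        r_squared=float(r2),
        residual_sd=s,
        df_resid=int(res.df_resid),
        coding=coding,
        domain=domain,
    )


def predict_surface(fit: QuadraticFit, point: tuple[float, float]) -> float:
    """Evaluate the fitted polynomial at a natural-unit (pressure, flow) point.

    Points outside the fit's training domain are evaluated anyway but
    raise an ``extrapolation`` warning.
    """
    p, q = float(point[0]), float(point[1])
    (p_lo, p_hi), (q_lo, q_hi) = fit.domain
    if not (p_lo <= p <= p_hi and q_lo <= q <= q_hi):
        warnings.warn(
            f"point ({p}, {q}) lies outside the fitted domain "
            f"[{p_lo}, {p_hi}] x [{q_lo}, {q_hi}]; extrapolating",
            stacklevel=2,
        )
    c = fit.coefficients
    return (
        c.get("intercept", 0.0)
        + c.get("P", 0.0) * p
        + c.get("Q", 0.0) * q
        + c.get("P2", 0.0) * p * p
        + c.get("Q2", 0.0) * q * q
        + c.get("PQ", 0.0) * p * q
    )


def stationary_point(
    fit: QuadraticFit, rtol: float = 1e-10
) -> tuple[tuple[float, float], str]:
    """Solve for the stationary point of the fitted surface and classify it.

    Returns the natural-unit point and one of ``"maximum"``, ``"minimum"``,
    ``"saddle"`` or ``"degenerate"`` from the Hessian eigenvalue signs.
    """
    c = fit.coefficients
    b11, b22, b12 = c.get("P2", 0.0), c.get("Q2", 0.0), c.get("PQ", 0.0)
    if b11 == 0.0 and b22 == 0.0 and b12 == 0.0:
        raise ValueError("surface has no active quadratic terms; no stationary point")
    hessian = np.array([[2 * b11, b12], [b12, 2 * b22]])
    grad0 = np.array([c.get("P", 0.0), c.get("Q", 0.0)])
    scale = np.abs(hessian).max()
    if abs(np.linalg.det(hessian)) <= rtol * scale**2:
        # Singular Hessian: a ridge/valley, no isolated stationary point.
        return ((float("nan"), float("nan")), "degenerate")
    point = np.linalg.solve(hessian, -grad0)
    eigs = np.linalg.eigvalsh(hessian)
    if np.all(eigs < 0):
        kind = "maximum"
    elif np.all(eigs > 0):
        kind = "minimum"
    else:
        kind = "saddle"
    return ((float(point[0]), float(point[1])), kind)


def contour_grid(
    fit: QuadraticFit,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    resolution: int,
) -> np.ndarray:
    """Evaluate the surface on an evenly spaced lattice over ``bounds``.

    ``bounds`` is ``((p_lo, p_hi), (q_lo, q_hi))``.  The returned array is
    row-major with shape ``(resolution, resolution)``: rows index pressure,
    columns index flow, and both endpoints are included.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    (p_lo, p_hi), (q_lo, q_hi) = bounds
    if p_hi <= p_lo or q_hi <= q_lo:
        raise ValueError("bounds rectangle is degenerate")
    p_axis = np.linspace(p_lo, p_hi, resolution)
    q_axis = np.linspace(q_lo, q_hi, resolution)
    c = fit.coefficients
    pp, qq = np.meshgrid(p_axis, q_axis, indexing="ij")
    return (
        c.get("intercept", 0.0)
        + c.get("P", 0.0) * pp
        + c.get("Q", 0.0) * qq
        + c.get("P2", 0.0) * pp * pp
        + c.get("Q2", 0.0) * qq * qq
        + c.get("PQ", 0.0) * pp * qq
    )
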