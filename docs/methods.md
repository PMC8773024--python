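# Methods

## Mass balance

Yields are carried on the wt% (0–100) scale throughout; fractions-of-one
are never exposed, matching how SAF results are tabulated.  The overall
recovery is definitionally `Y_SAF = Y_PV + Y_DV`; `validate_mass_balance`
checks tabulated run lists against this identity with a default tolerance
of 0.05 wt% — half a unit of the last digit at which yields are printed.
Raw collector masses for the upstream extraction and maceration steps are
not part of the packaged dataset, so `extraction_yield` is exercised with
synthetic masses; the published extraction yields (8.3% supercritical,
7.2% maceration — the latter rounded to 8% elsewhere in the original
report) are context, not test oracles.

## Central composite design

The two-factor CCD has 4 factorial points (±1, ±1), 4 axial points at the
star distance, and 5 center replicates: 13 runs.  The natural levels
(pressure 80/92/120/148/160 bar, flow 10/17/35/53/60 g/min) are stored
verbatim rather than derived from the labelled star distance of 1.44,
because the printed natural levels actually imply star distances of ~1.43
(pressure) and ~1.39 (flow): the printed values win.  Run order is
shuffled by a seeded generator; the historical execution order of the
packaged dataset is preserved in its `run_order` column but is never
regenerated.

## Quadratic fitting

`fit_quadratic` is ordinary least squares (statsmodels) on the full or
reduced second-order polynomial.  Per-response term sets mirror the
published reduced models: the PV yield omits the quadratic flow term, the
enrichment ratios omit the interaction term.  No automatic stepwise
reduction is attempted — the original analysis does not describe its
reduction rule, so term selection is explicit user input.

Coefficients are always reported in natural units.  Standard errors and
two-sided t-test p-values are computed, by default, in a centered/scaled
parametrization (each factor shifted to its mid-range and divided by its
half-range).  The two parametrizations span the same model space — the
back-transform is exact and predictions are identical — but centering
de-aliases the linear from the quadratic columns and is the convention
under which DOE software reports its coefficient tables; it is the only
convention under which the published significance pattern of this dataset
reproduces (e.g. a non-significant linear pressure term in the PV-yield
model, p ≈ 0.075).  `coding="natural"` is available for cross-checking.

Reproduction accuracy: refitting the packaged 13-run table recovers the
published coefficient table to within a few percent per coefficient, and
the published p-values to ±0.001 for the two yield columns checked most
tightly.  Exact printed-precision agreement is not attainable from the
tabulated data: the responses are printed rounded to 0.1 wt%, and a
direct sensitivity analysis (|Δβ| ≤ 0.05·Σ|(XᵀX)⁻¹Xᵀ| per coefficient)
shows the published coefficients sit slightly outside even the worst-case
rounding envelope, i.e. the original fit was run on unrounded laboratory
values that were never printed.  The test suite therefore asserts 2%
agreement on the headline quantities (overall-yield intercept, R², s;
PV-yield pressure-squared coefficient) and 5% elsewhere, with exact
significance-classification agreement for every term.

`stationary_point` solves the 2×2 gradient system and classifies by
Hessian eigenvalue signs, declaring degeneracy when |det H| falls below
1e−10 relative to the squared largest Hessian entry.  `contour_grid`
provides the numeric surface evaluation backing contour plots; rendering
is out of scope.

## Desirability optimization

Individual desirabilities are Derringer–Suich ramps with weight exponent
w (default 1); the composite score is the equal-weight geometric mean.
Anchors default to the observed min/max of each response in the run table
— the original optimization was run in commercial software whose anchor
settings were not reported, so the published composite desirability
(0.673 at 153 bar, 42 g/min) is not exactly reproducible; under
observed-range anchors for {overall yield, pooled enrichment} this
implementation finds its optimum at ~152.5 bar (in striking agreement on
pressure) but at higher flow and higher D.  The reproduce report
documents both values and their difference rather than tuning anchors to
match.

The search is a deterministic 201×201 grid scan followed by a bounded
Nelder–Mead polish from the best cell (the polish result is discarded if
it ever scores below the grid best).  No stochastic optimizer is used, so
no seed is needed.  An everywhere-zero desirability field is returned
flagged as degenerate rather than raised.

## Skin permeability model

Units: resistances in s/m; permeability logs in cm/s, so
`log Kp = log₁₀(100/R)` — the convention fixed by the published pairing
of R_skin = 7.74×10⁷ s/m with log Kp = −5.89.  Model constants and
defaults:

| parameter | default | units | meaning |
|---|---|---|---|
| shunt conductance | 2×10⁻¹¹ | m/s | appendageal (follicle/gland) route |
| offset Δlog Kp | −1.12 | log₁₀ cm/s | constant empirical calibration |
| log K_D | −9 | log₁₀ m/s | desquamation (turnover) rate |
| log K_vehicle:water | 0 | — | vehicle partition shift (water) |

The desquamation comparison converts the corrected cm/s log to m/s
(subtract 2); this is the only reading under which a corrected
log Kp = −8.39 cm/s (−10.39 m/s) counts as below K_D = −9.  Deviations
against reference permeabilities are computed as reference minus
corrected prediction — the sign convention consistent with all published
deviation values.  The rate-limiting compartment is the largest combined
resistance, ties broken toward the outermost layer (the barrier met
first); the preferred pathway per compartment is the lower-resistance
arm, ties toward intercellular.  Blocked pathways are represented as
infinite resistance and accepted in input files as blank cells or `inf`.

Per-layer barrier strengths are reported as layer log-permeabilities
log₁₀(100/Rᵢ); the tabulated per-layer "LogR" values in the original
report are internally inconsistent (they match neither the printed s/m
resistances nor the prose) and are deliberately not reproduced, while the
prose values (−5.61, −5.51, −7.06) do match the layer log-permeability.

Since published resistances carry three significant figures, recomputed
intermediates can land one unit of the last printed digit away from the
printed ones (e.g. the caffeic-acid SG combination: 1.211×10⁷ recomputed
vs 1.22×10⁷ printed); tests assert exactly that tolerance.

## Synthetic data

`simulate_saf_table` draws responses as quadratic mean + independent
homoscedastic Gaussian noise on the CCD — precisely the implicit OLS
measurement model; no heteroscedastic option is provided.  Negative
draws are clipped to zero (yields are mass fractions) and flagged.  The
default design and, in the parameter-recovery tests, the published
overall-yield coefficients with σ = 2.66 wt% (the fitted residual sd)
define the simulated study conditions.  `simulate_profile` draws
per-compartment pathway resistances log-uniformly over wide default
ranges (10⁶–10¹⁷ s/m intercellular, 10⁵–10¹² s/m transcellular) spanning
the orders of magnitude seen in the packaged profiles.

What passing these tests shows — and does not: the generators emulate
idealized versions of the data (exact polynomial truth, Gaussian errors,
independent layers), so parameter-recovery and invariance results
demonstrate correctness of the estimation and network machinery, not
robustness to real-data pathologies (heteroscedastic yields, correlated
layer resistances, model misfit).

Monte-Carlo sizes (200–500 replicates at n = 13, 1000 random profiles)
were chosen to keep Monte-Carlo standard errors small relative to the
assertion bands while the whole suite runs in seconds.

## Known limitations

- Only the epidermal stack is modelled: no dermis, blood compartment or
  finite-dose kinetics.
- Resistances are inputs; nothing here computes them from molecular
  structure.
- The desirability optimum is anchor-dependent by construction; absent
  the original anchor settings, published and recomputed optima agree on
  pressure but not on flow or D (documented in the reproduce report).
- No lack-of-fit ANOVA or PRESS statistics: the published analysis
  prints none, so there is nothing to validate them against.
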