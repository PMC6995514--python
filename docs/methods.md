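# Methods

## Model and procedure

The pipeline reproduces the standard response-surface-methodology (RSM)
workflow for a two-stage medium optimization:

1. One-factor-at-a-time screening runs are summarized by percent conversion
   (100 · product mass / cell dry weight) and ranked within role (carbon or
   nitrogen source). The default selection criterion is **PHA mass**, not
   percent conversion; the two disagree on the bundled data (pulse peel wins
   by mass, yeast extract by conversion), and the bundled study selected by
   mass.
2. A central composite design (CCD) over the two selected source
   concentrations provides the runs for an ordinary-least-squares fit of the
   full second-order polynomial. The OLS model assumes i.i.d. homoscedastic
   Gaussian errors; all inference (coefficient t tests with the residual
   degrees of freedom, whole-model F against the corrected total) is
   conditional on that assumption.
3. The fitted polynomial is the fitness function of a real-coded genetic
   algorithm searching the design box. For a concave quadratic the analytic
   stationary point (solve ∇f = 0, classify by Hessian eigenvalues) is the
   exact answer, and the package computes it; the GA route exists because it
   is the method of record for this workflow, and the analytic solution
   serves as its oracle.

## Design conventions

- Coded units: x = (natural − center)/step. The bundled CCD uses carbon
  center 4, step 2 and nitrogen center 0.2, step 0.1 g/100 mL with axial
  distance α = 2, which yields the five observed levels per factor
  ({0,2,4,6,8} and {0,0.1,0.2,0.3,0.4}).
- Canonical generator order is factorial corners (lexicographic, low level
  first), axial points (factor order, − before +), then center replicates.
  The bundled experiment table carries its own published run order
  (factorial, center, carbon axials, nitrogen axials, center) explicitly, so
  golden tests are order-exact while the generator stays deterministic.
  Designs are unblocked and unrandomized; a seeded run-order shuffle is
  available (`randomize_runs`) but never applied implicitly.
- General k is supported (2^k + 2k + n_center runs); the worked example uses
  k = 2.

## Numerical choices

- The regression is solved on the **coded** model matrix and mapped to
  natural units through the exact change-of-variables matrix on the
  quadratic monomial basis (natural covariance = TᵀCov_coded T). The
  natural-unit matrix for the bundled design is poorly scaled (intercept
  column versus nitrogen², four orders of magnitude), and the coded solve
  keeps the Gram matrix well conditioned; predictions from the two
  coefficient vectors agree to ~1e−10 and the natural coefficients match a
  direct pseudo-inverse solve to 1e−8 (both tested).
- Rank deficiency is detected by SVD rank and reported by naming the
  collinear columns found through column-pivoted QR.
- Stationary-point analysis refuses Hessians with condition number above
  1e12 (ridge/degenerate surfaces) rather than returning an unstable solve.
- Golden-test tolerances: published values are compared at their print
  precision plus one unit in the last printed digit (the published tables
  are themselves roundings of a slightly different computation); internal
  identities at 1e−8 relative or better.

## The two published coefficient sets and the ANOVA inconsistency

The bundled study printed two different coefficient vectors for the same
fit. The regression *table* is the exact OLS solution of the design data
(verified here to all printed digits) and is what `fit_quadratic`
reproduces. The separately printed polynomial *equation* (kept as
`datasets.published_polynomial()`) differs; its analytic maximum is 38.24 at
(5.090, 0.248), versus 37.54 at (5.057, 0.226) for the table fit. The
study's reported GA optimum matches the equation's carbon coordinate only,
so that is the coordinate the acceptance run targets; its reported nitrogen
(0.243) and maximum (39.16) follow from neither coefficient set and are not
targeted.

Similarly, the published ANOVA's sums of squares (model 896.024, residual
36.349) are internally consistent — their identities give F = 19.72049,
R = 98.03%, R² = 96.10% — but are inconsistent with the published per-run
residuals (squared sum 46.147, giving F = 15.36, R² = 95.05%). The package
implements both routes (`AnovaTable.from_sums` for identity checks on
printed tables, `anova` for data) and reports both in the analysis drivers
rather than choosing.

## Genetic algorithm

Operators follow the classical real-coded suite: uniform creation on the
init ranges; rank fitness scaling with raw score 1/√rank rescaled to sum to
the parent count (stable ties by input index); stochastic-uniform selection
(one uniform spin, equally spaced pointers, so every individual is selected
between ⌊e⌋ and ⌈e⌉ times); scattered crossover (independent fair binary
mask per gene); Gaussian mutation with per-gene SD = scale · init-range
width · (1 − shrink · generation/generations), clipped to bounds; elitism.
The engine minimizes the negated objective internally (the convention of
the solver family this replicates); the public API is maximization.
Termination: generation limit, stall (no best improvement beyond
`function_tolerance`, default 1e−6, for `stall_generations`), stall time,
wall-clock limit, or fitness limit.

Replication defaults: population 200, elite count 2, crossover fraction 1,
100 generations, stall limits 50 generations / 20 s, migration interval 20,
fraction 0.2, forward — with a single population migration is a no-op; in
multi-subpopulation mode the best fraction migrates along a forward ring
(both directions optional). Init ranges and bounds both default to the
natural design box ([0, 8] × [0, 0.4] g/100 mL for the worked example, its
coded ±2 hull), since the published init range values were not stated and
the optimum should be interpretable inside the explored space.

Crossover fraction 1 means **no mutation children**: gene values are only
ever recombined from the initial uniform draws, so a single run's precision
is limited by the initial sampling density (~box width / population).
Restarts recover precision — the acceptance protocol's best-of-25 restarts
gives an effective 5000 draws per coordinate, well inside ±0.02 of the true
maximizer — and that faithful setting is used wherever the replication
configuration is called for. For general use a fraction below 1 keeps the
shrinking mutation active and lets single runs converge to ~1e−2; the
engine-accuracy tests use fraction 0.7.

## Synthetic data generator

`make_truth` draws a quadratic truth surface over a declared box: the
Hessian is negative definite by construction (−L·R·L with R a random
correlation matrix and L diagonal, scaled so the response drops by 30–90%
of its peak from the optimum to the box edge), the stationary point is
rejection-sampled into the interior (10% margin), and the peak value is
uniform on [25, 40] response units — magnitudes mirroring the worked
example's surface. Responses are the polynomial value plus i.i.d.
N(0, noise_sd²); default noise_sd = 2.0, the scale suggested by the worked
example's residual mean square (≈ 11.5, i.e. σ̂ ≈ 3.4) while keeping the
10-run design informative. Screening tables draw cell dry weight uniform on
[5, 25] g/L and conversion fraction on [0.4, 0.85], spanning the bundled
screening campaign's range.

This emulates exactly the assumptions the OLS/ANOVA machinery makes —
homoscedastic Gaussian noise around a true quadratic, no run-order drift,
no replicate-specific variance structure — so passing recovery tests
validate the *statistics*, not the biology: real fermentation responses can
be heteroscedastic, curved beyond second order, and non-stationary across
runs, and nothing here checks robustness to that.

## Problem sizes

All golden computations are desk scale: 10-run designs, 25 GA restarts of
≤100 generations × 200 individuals, Monte-Carlo checks of 2000–4000
vectorized OLS replicates, and an 8-replicate noise ladder; the full test
suite and the acceptance run each finish in seconds on one CPU.

## Known limitations

- Whole-model ANOVA only; no lack-of-fit/pure-error split is computed by
  default (the bundled design has just two center replicates).
- No Box–Behnken, Plackett–Burman, D-optimal, blocked or split-plot
  designs; no mixture constraints, desirability indices, or Box–Cox
  transforms.
- The GA implements the plain real-coded suite: no constraint handling
  beyond box clipping, no hybrid local search, no adaptive operator rates.
- Extrapolation beyond the design hull is allowed and only flagged
  (`QuadraticFit.in_hull`), because the search box here equals the hull.
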