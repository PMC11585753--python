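# Methods

Conventions and numerical choices behind `growthcurves`. Units throughout:
age in days, weight in kg, AGR in kg/day.

## Models

Each `ModelSpec` bundles the prediction function, analytic first and second
time derivatives, an asymptote rule, an initial-weight rule (value at t = 0),
a closed-form inflection age where one exists, starting-value heuristics, and
an analytic parameter Jacobian where it is cheap to write down. Derivatives
were derived symbolically and are cross-checked against central finite
differences in the test suite for all eleven models.

Closed-form inflection ages:

| model | inflection age |
|---|---|
| monomolecular | `b / k` |
| logistic | `ln(b) / k` |
| von_bertalanffy | `ln(3b) / k` |
| richards | `ln(b/m) / k` |
| bridges, janoschek | `((m − 1)/(k m))^(1/m)` |
| weibull | `IP` (carried as a parameter) |
| sinusoidal | `t_n = b (n π − c) / (2π)`, rising-limb members |

`inflection_time(spec, params, window)` returns the closed form when it is
admissible (inside the window, with positive AGR there); otherwise it scans
the second derivative on a 2049-point grid over the window and bisects the
first sign change on the rising limb. Models whose curvature never changes
sign (monotone-concave fits, zero-amplitude sinusoids) report no inflection.

Specific form choices, all taken deliberately and individually flagged:

- **monomolecular** is implemented verbatim as `a/(1 + e^(b−kt))`, which is
  the logistic under `b_logistic = e^(b_mono)`. The packaged per-dataset
  estimates satisfy that mapping (e^2.9920 ≈ 19.9255, e^2.6014 ≈ 13.4828,
  e^2.4877 ≈ 12.0333), which is why the two models' fit-statistics rows are
  identical for every data set.
- **bridges** keeps the multiplier `a` on the saturating term:
  `W₀ + a(1 − e^(−k t^m))`; **janoschek** is the same curve with
  `a_janoschek = W₀ + a_bridges`.
- **schumacher** and **morgan** are literal readings of typographically
  ambiguous printed formulas. As implemented they are not the canonical
  Schumacher / Morgan–Mercer–Flodin growth functions (neither has a finite
  nonzero asymptote in these readings); their specs are flagged with
  `dialect="literal-typographic"` and carry no derived-quantity rules beyond
  the generic ones.
- **chanter** defaults to the "ratio" dialect
  `W₀ b / (W₀ + (b − W₀) e^E)` with `E = −(μ/d)(1 − e^(−dt))`; a "product"
  dialect is available via `build_registry(chanter_exponent="product")`.
- **weibull** is `a − (a − b) e^(−((k−1)/k)(t/IP)^k)`. Its second derivative
  vanishes exactly at `t = IP` for all `k ∉ {0, 1}`, so the inflection age is
  read directly off the fitted `IP` parameter. The asymptote is `a` whenever
  the exponential term decays (`(k−1)/k > 0`, i.e. `k < 0` or `k > 1`);
  negative fitted `a` values are legitimate outputs of the algebra and are
  reported as-is, signalling that the fit has no biologically meaningful
  mature weight.
- **sinusoidal** `y₀ + a sin(2πt/b + c)` is periodic, so "asymptote" is a
  convention, not a limit: the package defines the final weight as the
  rising-limb maximum `y₀ + a` (for `a > 0`), and the inflection age as the
  smallest rising-limb curvature root in the analysis window. The phase `c`
  is identified only modulo 2π.

Powers `t^m` with real `m` are computed as `exp(m ln t)` with explicit
handling at `t = 0` (0 for m > 0, 1 for m = 0, domain error for m < 0).
Predictions that overflow to non-finite values raise `ModelDomainError`
rather than propagating NaNs into the fitter.

## Fitting

`fit` is a damped Gauss-Newton iteration (Levenberg additive damping):
solve `(JᵀJ + λI) δ = Jᵀr`, accept the step if RSS decreases (then λ ← λ/10),
otherwise retry with λ ← 10λ up to 60 times per iteration; λ is initialised
at 1e−3 and capped at 1e12, beyond which the normal equations are declared
singular. Convergence is declared on a relative RSS change below
`rel_rss_tolerance` (1e−10) or a step norm below `step_tolerance` (1e−12).
Parameter Jacobians are analytic where provided (sinusoidal, logistic,
monomolecular, von Bertalanffy) and central finite differences with relative
step `1e−6·|θ|` otherwise.

`multistart_fit` draws `multistart_count` (default 12) starting vectors from
each model's heuristic — asymptote ≈ 1.1 × max observed weight, rate and
shape parameters from data-scale rules — jittered log-normally (σ = 0.2) for
sign-constrained parameters and additively otherwise, from a seeded
generator. The winner is the lowest-RSS converged solution (falling back to
lowest-RSS overall), with a lexicographic parameter tie-break so results are
bit-reproducible for a given seed. The fitter is validated against a dense
2-parameter grid-search oracle in the tests.

## Goodness-of-fit battery

For a fit with `n` observations, `p` parameters and residual sum of squares
RSS:

- `R² = 1 − RSS/TSS`, `Radj² = 1 − [(n−1)/(n−p)](1 − R²)`.
- **RMSE** has two denominator modes because both circulate in the
  comparison-table literature: `"table"` (default) is `√(RSS/(n−p))`,
  `"printed"` is `√(RSS/(n−p−1))`. The packaged reference statistics are
  internally consistent only under the `n−p` form (back-computing RSS from
  the reference AIC reproduces the reference RMSE with `n−p`, not `n−p−1`),
  which is why `"table"` is the default.
- **AIC = n ln(RSS) + 2p** and **BIC = n ln(RSS/n) + p ln(n)**. The AIC
  deliberately follows the RSS form without dividing by n, matching the
  convention of the reference tables; since both criteria are used only to
  rank models on the same data, the constant offset is harmless. For any
  RSS the pair then satisfies `AIC − BIC = n ln n + 2p − p ln n`, an
  identity the test suite verifies against every packaged reference pair.
  Both are undefined (reported as unavailable) for an exactly interpolating
  fit.
- **Durbin–Watson** is computed in age order; classification against 5%
  Savin–White bounds is built in only for n = 12 with one regressor
  (dL = 0.971, dU = 1.331) — other designs must pass `bounds=(dL, dU)`
  explicitly rather than silently extrapolating.
- **Shapiro–Wilk** comes from scipy (Royston's approximation) and is pinned
  in the tests against an independent reference implementation.
- **White's test** uses the single-regressor auxiliary design: squared
  residuals regressed on `(1, t, t²)`, statistic `n·R²_aux` against χ²(2).
  It is implemented directly (the auxiliary regression is three lines) and
  cross-checked against statsmodels' `het_white`; its empirical type-I error
  at n = 12 is verified to sit within 0.05 ± 0.02 over 1000 seeded
  homoscedastic replicates.

`rank_models` orders by one criterion (lower-better for AIC/BIC/RMSE,
higher-better for Radj²) with model-name tie-breaks.

## Synthetic data generator

`SimulationDesign` generates monthly weighing schedules at a mean month of
30.4375 days (so 12 months = 365.25 days), adds i.i.d. Gaussian noise
(default sd 0.5 kg — the residual scale implied by the reference fits), and
is seeded for exact reproducibility. Its scope is deliberately narrow: it
models homoscedastic additive noise on a single animal-average trajectory.
It does not model between-animal variation, age-dependent variance,
measurement rounding, or unequal weighing intervals; recovery results should
be read as best-case fitter performance under the stated noise model, not as
field expectations.

## Packaged reference estimates

`growthcurves/data/reference_estimates.csv` holds per-dataset published
parameter estimates used by the examples, the acceptance script and the
tests. Cells whose printed source values are typographically corrupted
(Schumacher and Morgan scale cells, the Chanter b cell, the Weibull
initial-weight cell for data sets 2–3, and the data set 3 sinusoidal
amplitude/phase signs) are omitted rather than guessed;
`reference_params` raises on incomplete sets while `reference_values`
returns what exists.

## Known limitations

- The raw weighing records behind the reference fits are not distributed, so
  full refits can only be validated against synthetic stand-ins generated at
  the documented design (12 monthly points, 0.5 kg noise), not against the
  original data.
- The Durbin–Watson *narrative* labels attached to some reference rows are
  not reproducible from the printed statistics alone and are not modelled;
  the package classifies strictly by the bounds rule.
- The Gauss-Newton fitter has no box constraints; sign conventions are
  maintained by the starting heuristics rather than projection, and a
  multistart can legitimately converge to sign-flipped equivalent optima
  (e.g. sinusoidal `(a, c) → (−a, c + π)`).
- Schumacher and Morgan, as literal readings, lack asymptotes; derived
  mature-weight summaries are unavailable for them.
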