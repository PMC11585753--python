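# growthcurves

Nonlinear growth-curve modelling for longitudinal body-weight data, built
around the model-comparison workflow used in livestock growth studies (the
packaged reference estimates come from ostrich weight records): fit a battery
of candidate growth functions to an (age, weight) series, score them with a
standard goodness-of-fit battery, rank them, and derive the biological
quantities of interest — asymptotic (mature) weight, age at the inflection
point, and the absolute growth rate (AGR) profile.

## The model registry

Eleven growth functions of age `t` (days) returning weight (kg):

| name | form | parameters |
|---|---|---|
| `monomolecular` | `a / (1 + e^(b − k t))` | a, b, k |
| `logistic` | `a / (1 + b e^(−k t))` | a, b, k |
| `von_bertalanffy` | `a (1 − b e^(−k t))³` | a, b, k |
| `richards` | `a (1 − b e^(−k t))^(1/m)` | a, b, k, m |
| `bridges` | `W₀ + a (1 − e^(−k t^m))` | W₀, a, k, m |
| `janoschek` | `a − (a − W₀) e^(−k t^m)` | a, W₀, k, m |
| `schumacher` | `a b^(2k) / (t + b)² · e^(b k t / (t + b))` | a, b, k |
| `morgan` | `a b^k k t^(k−1) / (t^k + b^k)²` | a, b, k |
| `chanter` | `W₀ b / (W₀ + (b − W₀) e^E)`, `E = −(μ/d)(1 − e^(−d t))` | W₀, b, d, μ |
| `weibull` | `a − (a − b) e^(−((k−1)/k)(t/IP)^k)` | a, b, k, IP |
| `sinusoidal` | `y₀ + a sin(2π t / b + c)` | y₀, a, b, c |

The `monomolecular` form as written is a reparameterization of the logistic
(`b_logistic = e^(b_mono)`), and `janoschek` is a reparameterization of
`bridges` — the registry keeps all four because published comparison tables
list them separately, and their pairwise-identical fit statistics are a
useful internal consistency check. The `schumacher` and `morgan` entries are
literal readings of ambiguous printed formulas and are flagged non-canonical
in their specs. Every model carries its analytic first and second time
derivatives, its asymptote and initial-weight rules, closed-form inflection
ages where they exist, and starting-value heuristics.

## Worked example

Fit and rank every model on a year of monthly weighings
(`examples/compare_models_on_a_series.py` — the series there is synthetic so
the example is self-contained):

```python
import growthcurves as gc

params = gc.reference_params(1, "sinusoidal")
design = gc.SimulationDesign("sinusoidal", params, noise_sd=0.5, seed=7)
data = gc.simulate_trajectory(design)

settings = gc.FitSettings(seed=0)
reports = [
    gc.gof_report(gc.multistart_fit(spec, data, settings), data)
    for spec in gc.list_models()
]
for rank, rep in enumerate(gc.rank_models(reports, "aic"), start=1):
    print(f"{rank:2d}. {rep.model_name:16s} AIC {rep.aic:9.4f}  "
          f"RMSE {rep.rmse:.4f}  adj R^2 {rep.r2_adj:.4f}")
```

```
 1. sinusoidal       AIC    7.8578  RMSE 0.3515  adj R^2 0.9999
 2. morgan           AIC   19.6956  RMSE 0.5898  adj R^2 0.9997
 3. janoschek        AIC   24.0094  RMSE 0.6889  adj R^2 0.9996
 4. weibull          AIC   24.0094  RMSE 0.6889  adj R^2 0.9996
 5. bridges          AIC   24.0094  RMSE 0.6889  adj R^2 0.9996
 ...
11. logistic         AIC   44.1813  RMSE 1.6360  adj R^2 0.9978
```

Note the identical janoschek/bridges rows and (further down) identical
monomolecular/logistic rows — the reparameterized pairs land on the same
curve, as they must.

Derived analytics from fitted parameters
(`examples/growth_analytics_from_estimates.py`):

```python
summary = gc.summarize(gc.get_model("sinusoidal"),
                       gc.reference_params(1, "sinusoidal"), (0.0, 366.0))
```

```
data set 1 (sinusoidal):
  asymptotic weight :  100.7184 kg
  inflection age    :    174.42 d (~ day 174)
  AGR at inflection :    0.3827 kg/day
```

`examples/parameter_recovery_experiment.py` shows the simulation side:
replicate noisy series from known parameters, refit, and report bias/RMSE.

## Command line

A thin CLI wraps the same pipeline:

```sh
growthcurves fit --input weights.csv --age-unit months --criterion aic --out results/
growthcurves simulate --model sinusoidal --params-file p.csv --sd 0.5 --seed 7 --out sim.csv
growthcurves recover --model sinusoidal --params-file p.csv --replicates 200 --sd 0.5 --seed 7
```

`fit` writes `parameters.csv`, `gof.csv`, `gof_long.csv`, `ranking.csv`, and
the AGR profile + growth summary for the best-ranked model. Ages may be given
in days or months (`--age-unit`, mean month = 30.4375 days). `--rmse-mode
{table,printed}` selects the RMSE denominator (`n−p` vs `n−p−1`); see
`docs/methods.md` for why both exist.

## Layout

- `src/growthcurves/` — the library (`models`, `fitting`, `gof`, `analysis`,
  `simulate`, `io`, `cli`, `reference`)
- `src/growthcurves/data/reference_estimates.csv` — packaged per-dataset
  reference parameter estimates
- `examples/` — short narrative scripts, each runnable as-is
- `docs/methods.md` — modelling and statistical conventions, numerical
  choices, and known limitations
- `tests/` — unit, property and acceptance suites
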