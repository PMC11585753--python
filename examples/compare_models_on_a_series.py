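"""Fit and rank all 11 growth models on a 12-point monthly weighing series.

The series here is synthetic (generated from the packaged sinusoidal
estimates with 0.5 kg residual noise), so the example is fully
self-contained; point ``read_dataset`` at your own CSV to analyse real data.
"""

import growthcurves as gc

# A year of monthly weighings from a known curve, noise sd 0.5 kg.
params = gc.reference_params(1, "sinusoidal")
design = gc.SimulationDesign("sinusoidal", params, noise_sd=0.5, seed=7)
data = gc.simulate_trajectory(design)

# Fit every model in the registry and build the goodness-of-fit table.
settings = gc.FitSettings(seed=0)
reports = []
for spec in gc.list_models():
    try:
        result = gc.multistart_fit(spec, data, settings)
    except gc.FitError as exc:
        print(f"{spec.name:16s}  fit failed: {exc}")
        continue
    reports.append(gc.gof_report(result, data))

print("\nranking by AIC (lower is better):")
for rank, rep in enumerate(gc.rank_models(reports, "aic"), start=1):
    print(f"  {rank:2d}. {rep.model_name:16s} AIC {rep.aic:9.4f}  "
          f"RMSE {rep.rmse:.4f}  adj R^2 {rep.r2_adj:.4f}")

best = gc.rank_models(reports, "aic")[0].model_name
print(f"\nbest model: {best}")
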