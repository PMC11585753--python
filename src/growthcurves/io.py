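"""CSV input, run configuration and the end-to-end fitting pipeline.

``run_pipeline`` ties the stages together the way a growth-curve study is
reported: fit every requested model to a longitudinal (age, weight) series,
assemble the goodness-of-fit table, rank models under each criterion, and
write the derivative-based growth summary for the best model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as gm
from ._exceptions import FitError, GrowthCurvesError, ModelDomainError
from .analysis import agr_profile, summarize
from .fitting import FitSettings, multistart_fit
from .gof import gof_report, rank_models, reports_to_long, reports_to_wide
from .models import MODEL_NAMES, GrowthDataset, get_model
from .simulate import DAYS_PER_MONTH

__all__ = ["RunConfig", "read_dataset", "run_pipeline", "load_config"]

log = logging.getLogger("growthcurves")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input: str | Path = ""
    age_column: str = "age"
    weight_column: str = "weight"
    age_unit: str = "days"  # "days" or "months"
    days_per_month: float = DAYS_PER_MONTH
    models: list[str] = field(default_factory=lambda: ["all"])
    fit_settings: FitSettings = field(default_factory=FitSettings)
    rmse_mode: str = "table"
    dw_bounds: tuple[float, float] | None = None
    criterion: str = "aic"
    output_dir: str | Path = "growthcurves-out"
    seed: int = 0

    def model_names(self) -> list[str]:
        names = list(MODEL_NAMES) if self.models == ["all"] else list(self.models)
        for name in names:
            get_model(name)  # validate against the registry
        return names

    def validate(self) -> None:
        if self.age_unit not in ("days", "months"):
            raise ValueError("age_unit must be 'days' or 'months'")
        self.model_names()


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    fs = raw.pop("fit_settings", {})
    cfg = RunConfig(**raw)
    cfg.fit_settings = FitSettings(**fs) if isinstance(fs, dict) else fs
    cfg.validate()
    return cfg


def read_dataset(path: str | Path, config: RunConfig | None = None) -> GrowthDataset:
    """Read a (age, weight) CSV into a :class:`GrowthDataset`.

    Ages are converted to days according to the config, rows sorted by age;
    duplicate ages, missing columns, non-numeric cells and n < 2 are rejected
    with distinct messages.
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    for col in (config.age_column, config.weight_column):
        if col not in df.columns:
            raise GrowthCurvesError(
                f"missing column {col!r} in {path.name} (found: {list(df.columns)})"
            )
    sub = df[[config.age_column, config.weight_column]]
    try:
        ages = pd.to_numeric(sub[config.age_column], errors="raise").to_numpy(float)
        weights = pd.to_numeric(sub[config.weight_column], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise GrowthCurvesError(f"non-numeric cell in {path.name}: {exc}") from exc
    if config.age_unit == "months":
        ages = ages * config.days_per_month
    if len(ages) < 2:
        raise GrowthCurvesError("dataset has fewer than two observations (n < 2)")
    if len(np.unique(ages)) != len(ages):
        raise GrowthCurvesError("duplicate ages in dataset")
    order = np.argsort(ages)
    if not np.all(order == np.arange(len(ages))):
        log.warning("input rows were not sorted by age; sorting")
        ages, weights = ages[order], weights[order]
    return GrowthDataset(ages=ages, weights=weights, label=path.stem)


def run_pipeline(config: RunConfig) -> dict:
    """Fit all configured models to the input series and write artifacts.

    Writes ``parameters.csv`` (parameters x models), ``gof.csv``
    (statistics x models), ``ranking.csv``, and ``agr_profile.csv`` /
    ``growth_summary.csv`` for the best model under the configured criterion,
    plus a run log.  Per-model fit failures are recorded and skipped; at
    least one model must succeed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    log.info("pipeline start: input=%s seed=%d settings=%s",
             config.input, config.seed, config.fit_settings)

    data = read_dataset(config.input, config)
    fits, reports, failures = {}, [], {}
    for name in config.model_names():
        spec = get_model(name)
        try:
            res = multistart_fit(spec, data, config.fit_settings)
            fits[name] = res
            reports.append(
                gof_report(res, data, rmse_mode=config.rmse_mode, dw_bounds=config.dw_bounds)
            )
            log.info("fitted %s: rss=%.6g converged=%s", name, res.rss, res.converged)
        except (FitError, ModelDomainError, ValueError) as exc:
            failures[name] = str(exc)
            log.warning("fit failed for %s: %s", name, exc)
    if not fits:
        raise GrowthCurvesError(f"every model failed to fit: {failures}")

    # parameters.csv: rows = parameter symbols, columns = models
    all_syms = sorted({s for name in fits for s in get_model(name).parameter_symbols})
    param_tbl = pd.DataFrame(
        {
            name: {s: fits[name].estimates.values.get(s, np.nan) for s in all_syms}
            for name in fits
        },
        index=all_syms,
    )
    param_tbl.to_csv(out / "parameters.csv", index_label="parameter")

    reports_to_wide(reports).to_csv(out / "gof.csv", index_label="statistic")
    reports_to_long(reports, dataset_label=data.label).to_csv(
        out / "gof_long.csv", index=False
    )

    rank_rows = []
    for crit in ("aic", "bic", "rmse", "r2_adj"):
        for rank, rep in enumerate(rank_models(reports, crit), start=1):
            rank_rows.append(
                {"criterion": crit, "rank": rank, "model": rep.model_name,
                 "value": getattr(rep, crit)}
            )
    pd.DataFrame(rank_rows).to_csv(out / "ranking.csv", index=False)

    best = rank_models(reports, config.criterion)[0].model_name
    spec = get_model(best)
    params = fits[best].estimates
    window = (0.0, 1.2 * float(data.ages[-1]))
    summary = summarize(spec, params, window)
    profile = agr_profile(spec, params, 0.0, window[1], step=1.0)
    pd.DataFrame({"age_days": profile.times, "agr_kg_per_day": profile.agr_values}).to_csv(
        out / "agr_profile.csv", index=False
    )
    pd.DataFrame([{
        "model": summary.model_name,
        "inflection_day": summary.inflection_day,
        "agr_at_inflection": summary.agr_at_inflection,
        "asymptotic_weight": summary.asymptotic_weight,
        "initial_weight": summary.initial_weight,
    }]).to_csv(out / "growth_summary.csv", index=False)

    run_meta = {
        "input": str(config.input),
        "seed": config.seed,
        "criterion": config.criterion,
        "best_model": best,
        "failures": failures,
    }
    (out / "run.json").write_text(json.dumps(run_meta, indent=2))
    log.info("pipeline done: best model by %s = %s", config.criterion, best)
    return {"fits": fits, "reports": reports, "best_model": best,
            "summary": summary, "failures": failures, "output_dir": out}


def _setup_logging(logfile: Path) -> None:
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "baseFilename", None) == str(logfile.resolve())
               for h in log.handlers):
        handler = logging.FileHandler(logfile)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(logging.INFO)
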