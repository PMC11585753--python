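"""Published parameter estimates for three ostrich monthly body-weight series.

The package ships the unambiguous columns of the published parameter table
for the three ostrich data sets (monthly weighings from one to twelve months
of age, reported in the ostrich-nutrition e-bulletin literature).  They are
used by the demos and the derived-quantity checks: asymptotic weights,
inflection ages and model-equivalence identities can all be computed from
these estimates without refitting.

Some published cells are typographically garbled (Schumacher/Morgan/Chanter
scale parameters; the signs of the data set 3 sinusoidal period and phase)
and are deliberately absent, so some (dataset, model) entries are partial.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .models import ParameterVector, get_model

__all__ = ["load_reference_estimates", "reference_params", "available_reference_models"]


def load_reference_estimates() -> pd.DataFrame:
    """Long-format table of published estimates.

    Returns a DataFrame with columns ``dataset`` (1-3), ``model``,
    ``parameter`` and ``value``.
    """
    with resources.files("growthcurves.data").joinpath("reference_estimates.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def reference_params(dataset: int, model: str) -> ParameterVector:
    """Complete published parameter vector for one (dataset, model) pair.

    Raises ``KeyError`` if the pair is absent and ``ValueError`` if only a
    partial (garbled-source) set of parameters is available.
    """
    df = load_reference_estimates()
    sub = df[(df["dataset"] == dataset) & (df["model"] == model)]
    if sub.empty:
        raise KeyError(f"no published estimates for dataset {dataset}, model {model!r}")
    values = dict(zip(sub["parameter"], sub["value"]))
    spec = get_model(model)
    if set(values) != set(spec.parameter_symbols):
        raise ValueError(
            f"published estimates for dataset {dataset}, model {model!r} are "
            f"partial ({sorted(values)}); the missing cells are garbled in the source"
        )
    return spec.make_params(values)


def reference_values(dataset: int, model: str) -> dict[str, float]:
    """Raw published values for one pair, possibly partial."""
    df = load_reference_estimates()
    sub = df[(df["dataset"] == dataset) & (df["model"] == model)]
    if sub.empty:
        raise KeyError(f"no published estimates for dataset {dataset}, model {model!r}")
    return dict(zip(sub["parameter"], sub["value"]))


def available_reference_models(dataset: int) -> list[str]:
    """Model names with at least one published estimate for a data set."""
    df = load_reference_estimates()
    return sorted(df.loc[df["dataset"] == dataset, "model"].unique())
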