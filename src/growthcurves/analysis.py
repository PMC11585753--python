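"""Derivative-based growth analytics from a fitted model.

Once a best-fitting model is chosen, the biologically interesting numbers
come from its derivatives: the absolute growth rate (AGR, kg/day) is the
first time-derivative of the weight curve, the inflection point is the age
where the second derivative crosses zero (growth switches from accelerating
to decelerating, and AGR peaks), and the asymptotic and initial weights come
from the model-specific closed-form rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models as gm
from .models import ModelSpec

__all__ = ["AGRProfile", "GrowthSummary", "agr_profile", "summarize"]


@dataclass(frozen=True)
class AGRProfile:
    """Absolute growth rate evaluated on an age grid."""

    times: np.ndarray
    agr_values: np.ndarray

    def peak_time(self) -> float:
        """Age of the largest AGR value on the grid."""
        return float(self.times[int(np.argmax(self.agr_values))])


@dataclass(frozen=True)
class GrowthSummary:
    """Headline growth analytics for one model and parameter set.

    ``inflection_day`` and ``agr_at_inflection`` are ``None`` when the model
    has no admissible inflection in the analysis window; ``asymptotic_weight``
    is ``None`` for models with no defined mature weight.
    """

    model_name: str
    inflection_day: float | None
    agr_at_inflection: float | None
    asymptotic_weight: float | None
    initial_weight: float


def agr_profile(
    spec: ModelSpec, params, t_start: float, t_end: float, step: float = 1.0
) -> AGRProfile:
    """AGR on the inclusive grid t_start, t_start+step, ..., t_end."""
    if not (0 <= t_start < t_end):
        raise ValueError("need 0 <= t_start < t_end")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(np.floor((t_end - t_start) / step + 1e-9))
    times = t_start + step * np.arange(n_steps + 1)
    if times[-1] < t_end - 1e-9:
        times = np.append(times, t_end)
    values = np.atleast_1d(np.asarray(gm.agr(spec, params, times), dtype=float))
    return AGRProfile(times=times, agr_values=values)


def summarize(
    spec: ModelSpec, params, window: tuple[float, float], grid_step: float = 1.0
) -> GrowthSummary:
    """Compute the growth summary over an analysis window (days)."""
    ip = gm.inflection_time(spec, params, window)
    return GrowthSummary(
        model_name=spec.name,
        inflection_day=ip,
        agr_at_inflection=None if ip is None else float(gm.agr(spec, params, ip)),
        asymptotic_weight=gm.asymptotic_weight(spec, params),
        initial_weight=gm.initial_weight(spec, params),
    )
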