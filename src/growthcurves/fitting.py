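"""Gauss-Newton nonlinear least squares for growth-curve models.

The engine linearizes the model through its Jacobian at each iterate and
solves the normal equations for the step.  A Levenberg-style additive damping
term stabilizes steps that would otherwise increase the residual sum of
squares: the damping factor is multiplied by 10 after a rejected step and
divided by 10 after an accepted one, so near the optimum the iteration
reduces to the plain Gauss-Newton method and the stationary points are
unchanged.  Data-driven starting values plus seeded multistart jitter guard
against local minima; parameters are unbounded by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import FitError, ModelDomainError, SingularNormalEquationsError
from .models import GrowthDataset, ModelSpec, ParameterVector

__all__ = [
    "FitSettings",
    "FitResult",
    "jacobian",
    "default_starts",
    "fit",
    "multistart_fit",
    "restrict",
]


@dataclass(frozen=True)
class FitSettings:
    """Tunable knobs of the least-squares iteration.

    ``rel_rss_tolerance`` declares convergence when the relative RSS change
    over one accepted step falls below it; ``step_tolerance`` stops the
    damped inner loop when the step norm collapses.
    """

    max_iterations: int = 500
    rel_rss_tolerance: float = 1e-10
    step_tolerance: float = 1e-12
    damping_enabled: bool = True
    multistart_count: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rel_rss_tolerance <= 0 or self.step_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model x dataset fit."""

    model_name: str
    estimates: ParameterVector
    rss: float
    residuals: np.ndarray
    n: int
    p: int
    converged: bool
    iterations: int
    start_used: ParameterVector
    rss_trace: tuple[float, ...] = field(default=(), repr=False)


def _predict_arr(spec: ModelSpec, values: dict, ages: np.ndarray) -> np.ndarray:
    out = spec.predict(values, ages)
    return np.atleast_1d(np.asarray(out, dtype=float))


def jacobian(spec: ModelSpec, params, ages) -> np.ndarray:
    """Matrix of partial derivatives dy/dtheta, rows = ages, columns in
    ``spec.parameter_symbols`` order.

    Uses the model's analytic parameter Jacobian when available, otherwise
    central finite differences with per-parameter relative steps.
    """
    ages = np.asarray(ages, dtype=float)
    values = _as_values(spec, params)
    if spec.param_jacobian is not None:
        J = np.asarray(spec.param_jacobian(values, ages), dtype=float)
    else:
        J = np.empty((ages.size, spec.p))
        for j, sym in enumerate(spec.parameter_symbols):
            v = values[sym]
            h = 1e-6 * abs(v) if v != 0 else 1e-6  # relative step: parameter scales span 1e-5..1e3
            up = dict(values, **{sym: values[sym] + h})
            dn = dict(values, **{sym: values[sym] - h})
            J[:, j] = (_predict_arr(spec, up, ages) - _predict_arr(spec, dn, ages)) / (2 * h)
    if not np.all(np.isfinite(J)):
        raise ModelDomainError(f"{spec.name}: non-finite Jacobian")
    return J


def default_starts(
    spec: ModelSpec, data: GrowthDataset, settings: FitSettings | None = None
) -> list[ParameterVector]:
    """Deterministic data-driven starts plus seeded multistart jitter.

    The base heuristics put the asymptote near 1.1x the largest observed
    weight, initial-weight-type parameters at the first observation, and the
    rate at the log-slope of the endpoints (the sinusoidal heuristic uses
    mid-range offset, half-range amplitude, periods of 2-4x the observation
    span and a phase solved from the first point).  Jittered copies perturb
    positive-scale parameters log-normally (sigma ~ 20%) and offsets/phases
    additively.
    """
    settings = settings or FitSettings()
    if data.n < spec.p:
        raise FitError(
            f"{spec.name}: {data.n} observations cannot identify {spec.p} parameters"
        )
    bases = [spec.make_params(v) for v in spec.start_heuristic(data)]
    rng = np.random.default_rng(settings.seed)
    out = list(bases)
    scale = float(np.std(data.weights)) or 1.0
    i = 0
    while len(out) < len(bases) + settings.multistart_count:
        base = bases[i % len(bases)]
        vals = {}
        for sym in spec.parameter_symbols:
            v = base[sym]
            if sym in spec.positive_params and v > 0:
                vals[sym] = v * math.exp(rng.normal(0.0, 0.2))
            else:
                sd = 0.2 * abs(v) if v != 0 else 0.1 * scale
                vals[sym] = v + rng.normal(0.0, sd)
        out.append(spec.make_params(vals))
        i += 1
    return out


def fit(
    spec: ModelSpec,
    data: GrowthDataset,
    settings: FitSettings | None = None,
    start: ParameterVector | None = None,
) -> FitResult:
    """Fit one model to one dataset by damped Gauss-Newton iteration.

    Raises ``SingularNormalEquationsError`` when even heavy damping cannot
    produce a solvable step, and propagates ``ModelDomainError`` when the
    model is undefined at the starting point.
    """
    settings = settings or FitSettings()
    if data.n < spec.p:
        raise FitError(
            f"{spec.name}: {data.n} observations cannot identify {spec.p} parameters"
        )
    if start is None:
        start = default_starts(spec, data, settings)[0]
    theta = np.array([start[s] for s in spec.parameter_symbols], dtype=float)
    ages, w = data.ages, data.weights

    def residuals_of(vec: np.ndarray) -> np.ndarray:
        values = dict(zip(spec.parameter_symbols, vec))
        return w - _predict_arr(spec, values, ages)

    r = residuals_of(theta)
    rss = float(r @ r)
    trace = [rss]
    lam = 1e-3 if settings.damping_enabled else 0.0
    converged = False
    iterations = 0

    for iterations in range(1, settings.max_iterations + 1):
        values = dict(zip(spec.parameter_symbols, theta))
        try:
            J = jacobian(spec, values, ages)
        except ModelDomainError:
            break
        A = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(60):  # inner damping loop
            try:
                step = np.linalg.solve(A + lam * np.eye(spec.p), g)
            except np.linalg.LinAlgError:
                step = None
            if step is None or not np.all(np.isfinite(step)):
                if not settings.damping_enabled:
                    raise SingularNormalEquationsError(
                        f"{spec.name}: singular normal equations"
                    )
                lam = max(lam, 1e-12) * 10.0
                if lam > 1e12:
                    raise SingularNormalEquationsError(
                        f"{spec.name}: normal equations unsolvable even with heavy damping"
                    )
                continue
            if float(np.linalg.norm(step)) < settings.step_tolerance:
                converged = True  # step collapsed: stationary point reached
                accepted = False
                break
            candidate = theta + step
            try:
                r_new = residuals_of(candidate)
            except ModelDomainError:
                r_new = None
            if r_new is not None and np.all(np.isfinite(r_new)):
                with np.errstate(over="ignore"):
                    rss_new = float(r_new @ r_new)
                if rss_new <= rss:
                    theta, r, prev_rss, rss = candidate, r_new, rss, rss_new
                    trace.append(rss)
                    if settings.damping_enabled:
                        lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
            if not settings.damping_enabled:
                # raw Gauss-Newton: take the step anyway only if finite
                if r_new is not None and np.all(np.isfinite(r_new)):
                    theta, r, prev_rss, rss = candidate, r_new, rss, float(r_new @ r_new)
                    trace.append(rss)
                    accepted = True
                break
            lam = max(lam, 1e-12) * 10.0
            if lam > 1e12:
                break
        if not accepted:
            break
        denom = max(prev_rss, np.finfo(float).tiny)
        if abs(prev_rss - rss) / denom < settings.rel_rss_tolerance:
            converged = True
            break

    estimates = spec.make_params(dict(zip(spec.parameter_symbols, theta)))
    return FitResult(
        model_name=spec.name,
        estimates=estimates,
        rss=rss,
        residuals=r.copy(),
        n=data.n,
        p=spec.p,
        converged=converged,
        iterations=iterations,
        start_used=start,
        rss_trace=tuple(trace),
    )


def multistart_fit(
    spec: ModelSpec, data: GrowthDataset, settings: FitSettings | None = None
) -> FitResult:
    """Run :func:`fit` from every default start and keep the best result.

    Converged results are preferred; among (near-)equal-RSS candidates the
    lexicographically smallest parameter vector wins, making the outcome
    deterministic for a given seed.  Raises ``FitError`` if every start fails.
    """
    settings = settings or FitSettings()
    results: list[FitResult] = []
    errors: list[Exception] = []
    for start in default_starts(spec, data, settings):
        try:
            results.append(fit(spec, data, settings, start))
        except (FitError, ModelDomainError) as exc:
            errors.append(exc)
    if not results:
        raise FitError(
            f"{spec.name}: all starts failed ({'; '.join(map(str, errors))})"
        )

    def sort_key(res: FitResult):
        vec = tuple(res.estimates[s] for s in spec.parameter_symbols)
        return (not res.converged, res.rss, vec)

    return min(results, key=sort_key)


def restrict(spec: ModelSpec, fixed: dict[str, float]) -> ModelSpec:
    """A lower-dimensional view of ``spec`` with some parameters frozen.

    Useful for profiling the RSS surface over parameter pairs and for
    comparing the fitter against exhaustive grid search.
    """
    free = tuple(s for s in spec.parameter_symbols if s not in fixed)
    if not free:
        raise ValueError("at least one parameter must remain free")

    def full(values: dict) -> dict:
        return {**fixed, **values}

    return replace(
        spec,
        name=f"{spec.name}[restricted]",
        parameter_symbols=free,
        predict=lambda v, t: spec.predict(full(v), t),
        d1=lambda v, t: spec.d1(full(v), t),
        d2=lambda v, t: spec.d2(full(v), t),
        param_jacobian=None,
        closed_form_ip=None,
        asymptote=None,
        initial_weight=lambda v: spec.initial_weight(full(v)),
        start_heuristic=lambda data: [
            {s: st[s] for s in free} for st in spec.start_heuristic(data)
        ],
        positive_params=frozenset(spec.positive_params & set(free)),
    )


def _as_values(spec: ModelSpec, params) -> dict[str, float]:
    if isinstance(params, ParameterVector):
        return dict(params.values)
    return {k: float(v) for k, v in params.items()}
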