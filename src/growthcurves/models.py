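"""Registry of eleven nonlinear growth functions for body-weight-vs-age data.

Each model maps age ``t`` (days) to body weight ``y`` (kg).  A
:class:`ModelSpec` bundles the functional form with its analytic first and
second time-derivatives (absolute growth rate and curvature), rules for the
derived quantities practitioners report — asymptotic (mature) weight, initial
weight, and the inflection point where growth is fastest — and a start-value
heuristic for nonlinear least squares.

The eleven forms, with their estimated parameters:

====================  =======================================================
monomolecular         ``y = a / (1 + exp(b - k t))``            (a, b, k)
bridges               ``y = W0 + a (1 - exp(-k t^m))``          (W0, a, k, m)
janoschek             ``y = a - (a - W0) exp(-k t^m)``          (a, W0, k, m)
logistic              ``y = a / (1 + b exp(-k t))``             (a, b, k)
von_bertalanffy       ``y = a (1 - b exp(-k t))^3``             (a, b, k)
richards              ``y = a (1 - b exp(-k t))^(1/m)``         (a, b, k, m)
schumacher            ``y = a b^(2k) (t+b)^-2 exp(b k t/(t+b))``(a, b, k)
morgan                ``y = a b^k k t^(k-1) / (t^k + b^k)^2``   (a, b, k)
chanter               ``y = W0 b / (W0 + (b-W0) exp(E))``       (W0, b, d, mu)
weibull               ``y = a - (a-b) exp(-((k-1)/k)(t/IP)^k)`` (a, b, k, IP)
sinusoidal            ``y = y0 + a sin(2 pi t / b + c)``        (y0, a, b, c)
====================  =======================================================

where Chanter's exponent is ``E = -(mu/d) (1 - exp(-d t))`` by default (a
``chanter_exponent="product"`` dialect with ``E = -(mu d)(1 - exp(-d t))`` is
also available).  The monomolecular form here is an exact reparameterization
of the logistic (``b_logistic = exp(b_monomolecular)``), and Bridges is an
exact reparameterization of Janoschek (``a_janoschek = W0 + a_bridges``);
both equivalences are exposed because fitted statistics coincide pairwise.
The Schumacher and Morgan forms are literal typographic readings, flagged
non-canonical: the Morgan form as written decays at large age and is not a
trustworthy sigmoid.

The sinusoidal model is periodic with period ``b``; used over the rising limb
of one cycle it acts as a growth curve with amplitude ``a``, vertical offset
``y0`` and phase ``c``.  Its mature (final) weight is defined as ``a + y0``
(the upper envelope) and its initial weight as ``y0 + a sin(c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._exceptions import ModelDomainError

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "GrowthDataset",
    "build_registry",
    "list_models",
    "get_model",
    "MODEL_NAMES",
]

TWO_PI = 2.0 * math.pi

MODEL_NAMES = (
    "monomolecular",
    "bridges",
    "janoschek",
    "logistic",
    "von_bertalanffy",
    "richards",
    "schumacher",
    "morgan",
    "chanter",
    "weibull",
    "sinusoidal",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterVector:
    """A complete, finite parameter assignment for one model.

    Parameters
    ----------
    model_name:
        Registry name of the model the values belong to.
    values:
        Mapping from parameter symbol to value.  Weights in kg, ages and
        periods in days, rates in 1/day, shape parameters dimensionless.
    """

    model_name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        for key, val in self.values.items():
            if not math.isfinite(float(val)):
                raise ValueError(f"parameter {key!r} is not finite: {val!r}")

    def as_array(self, symbols: Sequence[str]) -> np.ndarray:
        return np.array([float(self.values[s]) for s in symbols], dtype=float)

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])


@dataclass(frozen=True)
class GrowthDataset:
    """Ordered (age, weight) observations for one animal group.

    Ages are in days and must be strictly increasing; weights are in kg.
    """

    ages: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if ages.ndim != 1 or weights.ndim != 1:
            raise ValueError("ages and weights must be one-dimensional")
        if ages.shape != weights.shape:
            raise ValueError("ages and weights must have equal length")
        if ages.size < 2:
            raise ValueError("a growth dataset needs at least two observations")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if not np.all(np.isfinite(weights)) or not np.all(np.isfinite(ages)):
            raise ValueError("ages and weights must be finite")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", weights)

    @property
    def n(self) -> int:
        return int(self.ages.size)


@dataclass(frozen=True)
class ModelSpec:
    """One registry entry: a growth function and everything derived from it.

    ``predict``, ``d1`` and ``d2`` take ``(params: dict, t: array)`` and
    return arrays; ``d1``/``d2`` are the analytic first and second
    time-derivatives (kg/day, kg/day^2).  ``param_jacobian`` is optional; the
    fitting engine falls back to finite differences when it is ``None``.
    ``asymptote`` returns the mature-weight rule (``None`` when the model has
    no defined asymptotic weight), ``closed_form_ip`` the analytic inflection
    age when one exists, and ``start_heuristic`` a list of data-driven
    starting parameter dictionaries for least squares.
    """

    name: str
    parameter_symbols: tuple[str, ...]
    predict: Callable
    d1: Callable
    d2: Callable
    asymptote: Callable | None
    initial_weight: Callable
    start_heuristic: Callable
    closed_form_ip: Callable | None = None
    param_jacobian: Callable | None = None
    positive_params: frozenset[str] = frozenset()
    dialect: str | None = None

    @property
    def p(self) -> int:
        return len(self.parameter_symbols)

    def make_params(self, values: Mapping[str, float]) -> ParameterVector:
        """Validate a value mapping against this spec and wrap it."""
        missing = set(self.parameter_symbols) - set(values)
        extra = set(values) - set(self.parameter_symbols)
        if missing or extra:
            raise ValueError(
                f"{self.name}: parameter mismatch (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
        return ParameterVector(self.name, values)


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------


def _asarray_t(t) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    return arr, np.ndim(t) == 0


def _maybe_scalar(out: np.ndarray, scalar: bool):
    return float(out[0]) if scalar else out


def _check_finite(name: str, out: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(out)):
        raise ModelDomainError(f"{name}: form is undefined (non-finite) at the given inputs")
    return out


def _powt(t: np.ndarray, m: float) -> np.ndarray:
    """``t**m`` via exp(m ln t) for t > 0 with explicit t = 0 handling."""
    if np.any(t < 0):
        raise ModelDomainError("negative age in power-law term")
    out = np.empty_like(t)
    pos = t > 0
    out[pos] = np.exp(m * np.log(t[pos]))
    if np.any(~pos):
        if m > 0:
            out[~pos] = 0.0
        elif m == 0:
            out[~pos] = 1.0
        else:
            raise ModelDomainError("t^m with m < 0 is undefined at t = 0")
    return out


def _wrap(fn, name):
    """Vectorize over t, preserve scalar in/out, reject non-finite output."""

    def wrapped(params, t):
        arr, scalar = _asarray_t(t)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out = np.asarray(fn(params, arr), dtype=float)
        _check_finite(name, out)
        return _maybe_scalar(out, scalar)

    return wrapped


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------
# Each block defines predict / d1 / d2 (time derivatives), derived-quantity
# rules and the start heuristic, then registers a ModelSpec builder.


def _log_slope(data: GrowthDataset) -> float:
    """Crude maturation-rate guess from the log-slope of the endpoints."""
    t, w = data.ages, data.weights
    span = t[-1] - t[0]
    if w[0] > 0 and w[-1] > w[0]:
        return float(np.log(w[-1] / w[0]) / span)
    return 1.0 / span


def _amax(data: GrowthDataset) -> float:
    return 1.1 * float(np.max(data.weights))


# --- monomolecular (printed form; a logistic reparameterization) -----------


def _mono_predict(p, t):
    s = np.exp(p["b"] - p["k"] * t)
    return p["a"] / (1.0 + s)


def _mono_d1(p, t):
    s = np.exp(p["b"] - p["k"] * t)
    return p["a"] * p["k"] * s / (1.0 + s) ** 2


def _mono_d2(p, t):
    s = np.exp(p["b"] - p["k"] * t)
    return p["a"] * p["k"] ** 2 * s * (s - 1.0) / (1.0 + s) ** 3


def _mono_jac(p, t):
    s = np.exp(p["b"] - p["k"] * t)
    D = 1.0 + s
    return np.column_stack([1.0 / D, -p["a"] * s / D**2, p["a"] * t * s / D**2])


def _mono_ip(p):
    return p["b"] / p["k"] if p["k"] != 0 else None


def _mono_starts(data):
    a = _amax(data)
    k = _log_slope(data)
    w1, t1 = data.weights[0], data.ages[0]
    frac = min(max(w1 / a, 1e-6), 1 - 1e-6)
    b = math.log(1.0 / frac - 1.0) + k * t1
    return [{"a": a, "b": b, "k": k}, {"a": a, "b": b, "k": 2 * k}]


# --- logistic ---------------------------------------------------------------


def _logi_predict(p, t):
    s = p["b"] * np.exp(-p["k"] * t)
    return p["a"] / (1.0 + s)


def _logi_d1(p, t):
    s = p["b"] * np.exp(-p["k"] * t)
    return p["a"] * p["k"] * s / (1.0 + s) ** 2


def _logi_d2(p, t):
    s = p["b"] * np.exp(-p["k"] * t)
    return p["a"] * p["k"] ** 2 * s * (s - 1.0) / (1.0 + s) ** 3


def _logi_jac(p, t):
    e = np.exp(-p["k"] * t)
    s = p["b"] * e
    D = 1.0 + s
    return np.column_stack([1.0 / D, -p["a"] * e / D**2, p["a"] * t * s / D**2])


def _logi_ip(p):
    if p["b"] > 0 and p["k"] != 0:
        return math.log(p["b"]) / p["k"]
    return None


def _logi_starts(data):
    a = _amax(data)
    k = _log_slope(data)
    w1, t1 = data.weights[0], data.ages[0]
    frac = min(max(w1 / a, 1e-6), 1 - 1e-6)
    b = (1.0 / frac - 1.0) * math.exp(k * t1)
    return [{"a": a, "b": b, "k": k}, {"a": a, "b": b, "k": 2 * k}]


# --- bridges / janoschek ----------------------------------------------------


def _bridges_predict(p, t):
    return p["W0"] + p["a"] * (1.0 - np.exp(-p["k"] * _powt(t, p["m"])))


def _bridges_d1(p, t):
    m, k = p["m"], p["k"]
    u = k * _powt(t, m)
    return p["a"] * np.exp(-u) * k * m * _powt(t, m - 1.0)


def _bridges_d2(p, t):
    m, k = p["m"], p["k"]
    u = k * _powt(t, m)
    base = k * m * _powt(t, m - 1.0)
    return p["a"] * np.exp(-u) * (k * m * (m - 1.0) * _powt(t, m - 2.0) - base**2)


def _bridges_ip(p):
    k, m = p["k"], p["m"]
    if m > 1 and k > 0:
        return ((m - 1.0) / (k * m)) ** (1.0 / m)
    return None


def _power_rate_starts(data, m_values):
    """Shared (k, m) heuristic for Bridges/Janoschek power-exponent forms."""
    w1 = data.weights[0]
    a = _amax(data) - w1
    out = []
    for m in m_values:
        frac = min(max((data.weights[-1] - w1) / a, 1e-3), 1 - 1e-3)
        k = -math.log(1.0 - frac) / data.ages[-1] ** m
        out.append((a, w1, k, m))
    return out


def _bridges_starts(data):
    return [
        {"W0": w0, "a": a, "k": k, "m": m}
        for (a, w0, k, m) in _power_rate_starts(data, (1.0, 2.0))
    ]


def _jano_predict(p, t):
    return p["a"] - (p["a"] - p["W0"]) * np.exp(-p["k"] * _powt(t, p["m"]))


def _jano_d1(p, t):
    q = {"a": p["a"] - p["W0"], "k": p["k"], "m": p["m"], "W0": 0.0}
    return _bridges_d1(q, t)


def _jano_d2(p, t):
    q = {"a": p["a"] - p["W0"], "k": p["k"], "m": p["m"], "W0": 0.0}
    return _bridges_d2(q, t)


def _jano_starts(data):
    return [
        {"a": a + w0, "W0": w0, "k": k, "m": m}
        for (a, w0, k, m) in _power_rate_starts(data, (1.0, 2.0))
    ]


# --- von Bertalanffy / Richards --------------------------------------------


def _vb_predict(p, t):
    w = 1.0 - p["b"] * np.exp(-p["k"] * t)
    return p["a"] * w**3


def _vb_d1(p, t):
    e = p["b"] * np.exp(-p["k"] * t)
    w = 1.0 - e
    return 3.0 * p["a"] * p["k"] * w**2 * e


def _vb_d2(p, t):
    e = p["b"] * np.exp(-p["k"] * t)
    w = 1.0 - e
    return 3.0 * p["a"] * p["k"] ** 2 * e * w * (3.0 * e - 1.0)


def _vb_jac(p, t):
    e = np.exp(-p["k"] * t)
    w = 1.0 - p["b"] * e
    return np.column_stack(
        [w**3, -3.0 * p["a"] * w**2 * e, 3.0 * p["a"] * w**2 * p["b"] * t * e]
    )


def _vb_ip(p):
    if p["b"] > 0 and p["k"] != 0:
        return math.log(3.0 * p["b"]) / p["k"]
    return None


def _vb_starts(data):
    a = _amax(data)
    k = _log_slope(data)
    w1, t1 = data.weights[0], data.ages[0]
    frac = min(max(w1 / a, 1e-6), 1 - 1e-6)
    b = (1.0 - frac ** (1.0 / 3.0)) * math.exp(k * t1)
    return [{"a": a, "b": b, "k": k}, {"a": a, "b": b, "k": k / 2.0}]


def _rich_predict(p, t):
    w = 1.0 - p["b"] * np.exp(-p["k"] * t)
    if np.any(w <= 0):
        raise ModelDomainError("richards: base (1 - b e^{-kt}) must be positive")
    return p["a"] * w ** (1.0 / p["m"])


def _rich_d1(p, t):
    e = p["b"] * np.exp(-p["k"] * t)
    w = 1.0 - e
    return (p["a"] * p["k"] / p["m"]) * e * w ** (1.0 / p["m"] - 1.0)


def _rich_d2(p, t):
    m = p["m"]
    e = p["b"] * np.exp(-p["k"] * t)
    w = 1.0 - e
    return (p["a"] * p["k"] ** 2 / m) * e * w ** (1.0 / m - 2.0) * ((1.0 / m - 1.0) * e - w)


def _rich_ip(p):
    # curvature root at b e^{-kt} = m, i.e. t = ln(b/m)/k
    if p["b"] > 0 and p["m"] > 0 and p["k"] != 0:
        return math.log(p["b"] / p["m"]) / p["k"]
    return None


def _rich_starts(data):
    a = _amax(data)
    k = _log_slope(data)
    w1, t1 = data.weights[0], data.ages[0]
    out = []
    for m in (0.1, 1.0 / 3.0, 1.0):
        frac = min(max(w1 / a, 1e-6), 1 - 1e-6)
        b = (1.0 - frac**m) * math.exp(k * t1)
        out.append({"a": a, "b": b, "k": k, "m": m})
    return out


# --- schumacher / morgan (literal typographic readings; non-canonical) ------


def _schu_predict(p, t):
    a, b, k = p["a"], p["b"], p["k"]
    if np.any(t + b <= 0):
        raise ModelDomainError("schumacher: t + b must be positive")
    return a * b ** (2.0 * k) * (t + b) ** (-2.0) * np.exp(b * k * t / (t + b))


def _schu_logderivs(p, t):
    b, k = p["b"], p["k"]
    g1 = -2.0 / (t + b) + b**2 * k / (t + b) ** 2
    g2 = 2.0 / (t + b) ** 2 - 2.0 * b**2 * k / (t + b) ** 3
    return g1, g2


def _schu_d1(p, t):
    y = _schu_predict(p, t)
    g1, _ = _schu_logderivs(p, t)
    return y * g1


def _schu_d2(p, t):
    y = _schu_predict(p, t)
    g1, g2 = _schu_logderivs(p, t)
    return y * (g1**2 + g2)


def _schu_starts(data):
    span = data.ages[-1] - data.ages[0]
    wmax = float(np.max(data.weights))
    return [
        {"a": wmax, "b": span / 3.0, "k": 1.0},
        {"a": wmax, "b": span, "k": 0.1},
    ]


def _morgan_predict(p, t):
    a, b, k = p["a"], p["b"], p["k"]
    tk = _powt(t, k)
    bk = b**k if b > 0 else None
    if bk is None:
        raise ModelDomainError("morgan: b must be positive")
    return a * bk * k * _powt(t, k - 1.0) / (tk + bk) ** 2


def _morgan_logderivs(p, t):
    b, k = p["b"], p["k"]
    tk = _powt(t, k)
    bk = b**k
    h1 = (k - 1.0) / t - 2.0 * k * _powt(t, k - 1.0) / (tk + bk)
    h2 = -(k - 1.0) / t**2 - 2.0 * k * (
        (k - 1.0) * _powt(t, k - 2.0) * (tk + bk) - k * _powt(t, 2.0 * k - 2.0)
    ) / (tk + bk) ** 2
    return h1, h2


def _morgan_d1(p, t):
    y = _morgan_predict(p, t)
    h1, _ = _morgan_logderivs(p, t)
    return y * h1


def _morgan_d2(p, t):
    y = _morgan_predict(p, t)
    h1, h2 = _morgan_logderivs(p, t)
    return y * (h1**2 + h2)


def _morgan_starts(data):
    span = data.ages[-1] - data.ages[0]
    wmax = float(np.max(data.weights))
    return [
        {"a": wmax * span, "b": span / 2.0, "k": 2.0},
        {"a": wmax * span, "b": span, "k": 3.0},
    ]


# --- chanter ----------------------------------------------------------------


def _chanter_exponent(p, t, dialect):
    if dialect == "ratio":
        return -(p["mu"] / p["d"]) * (1.0 - np.exp(-p["d"] * t))
    return -(p["mu"] * p["d"]) * (1.0 - np.exp(-p["d"] * t))


def _make_chanter(dialect):
    def predict(p, t):
        E = _chanter_exponent(p, t, dialect)
        D = p["W0"] + (p["b"] - p["W0"]) * np.exp(E)
        if np.any(D == 0):
            raise ModelDomainError("chanter: zero denominator")
        return p["W0"] * p["b"] / D

    def _parts(p, t):
        E = _chanter_exponent(p, t, dialect)
        scale = (p["mu"] / p["d"]) if dialect == "ratio" else (p["mu"] * p["d"])
        E1 = -scale * p["d"] * np.exp(-p["d"] * t)
        E2 = scale * p["d"] ** 2 * np.exp(-p["d"] * t)
        eE = np.exp(E)
        D = p["W0"] + (p["b"] - p["W0"]) * eE
        D1 = (p["b"] - p["W0"]) * eE * E1
        D2 = (p["b"] - p["W0"]) * eE * (E1**2 + E2)
        return D, D1, D2

    def d1(p, t):
        D, D1, _ = _parts(p, t)
        return -p["W0"] * p["b"] * D1 / D**2

    def d2(p, t):
        D, D1, D2 = _parts(p, t)
        return -p["W0"] * p["b"] * (D2 * D - 2.0 * D1**2) / D**3

    def asymptote(p):
        scale = (p["mu"] / p["d"]) if dialect == "ratio" else (p["mu"] * p["d"])
        D = p["W0"] + (p["b"] - p["W0"]) * math.exp(-scale)
        return p["W0"] * p["b"] / D

    return predict, d1, d2, asymptote


def _chanter_starts(data):
    w1 = max(float(data.weights[0]), 1e-3)
    b = _amax(data)
    span = data.ages[-1] - data.ages[0]
    return [
        {"W0": w1, "b": b, "d": 2.0 / span, "mu": 0.02},
        {"W0": w1, "b": b, "d": 0.01, "mu": 0.04},
    ]


# --- weibull ----------------------------------------------------------------


def _weib_q(p):
    if p["k"] == 0:
        raise ModelDomainError("weibull: k must be nonzero")
    return (p["k"] - 1.0) / p["k"]


def _weib_predict(p, t):
    q = _weib_q(p)
    u = _powt(np.asarray(t, dtype=float) / p["IP"], p["k"])
    return p["a"] - (p["a"] - p["b"]) * np.exp(-q * u)


def _weib_d1(p, t):
    q = _weib_q(p)
    k, IP = p["k"], p["IP"]
    u = _powt(t / IP, k)
    u1 = k * _powt(t, k - 1.0) / IP**k
    return (p["a"] - p["b"]) * q * u1 * np.exp(-q * u)


def _weib_d2(p, t):
    q = _weib_q(p)
    k, IP = p["k"], p["IP"]
    u = _powt(t / IP, k)
    u1 = k * _powt(t, k - 1.0) / IP**k
    u2 = k * (k - 1.0) * _powt(t, k - 2.0) / IP**k
    return (p["a"] - p["b"]) * q * np.exp(-q * u) * (u2 - q * u1**2)


def _weib_ip(p):
    # the curvature root of this form is exactly t = IP for any k != 0, 1
    if p["k"] not in (0.0, 1.0) and p["IP"] > 0:
        return float(p["IP"])
    return None


def _weib_starts(data):
    a = _amax(data)
    w1 = float(data.weights[0])
    gains = np.diff(data.weights) / np.diff(data.ages)
    ip = float(data.ages[int(np.argmax(gains))]) if np.any(gains > 0) else float(
        0.5 * (data.ages[0] + data.ages[-1])
    )
    return [
        {"a": a, "b": w1, "k": 1.5, "IP": ip},
        {"a": a, "b": w1, "k": 2.5, "IP": ip},
    ]


# --- sinusoidal -------------------------------------------------------------


def _sin_theta(p, t):
    return TWO_PI * t / p["b"] + p["c"]


def _sin_predict(p, t):
    return p["y0"] + p["a"] * np.sin(_sin_theta(p, t))


def _sin_d1(p, t):
    return p["a"] * (TWO_PI / p["b"]) * np.cos(_sin_theta(p, t))


def _sin_d2(p, t):
    return -p["a"] * (TWO_PI / p["b"]) ** 2 * np.sin(_sin_theta(p, t))


def _sin_jac(p, t):
    th = _sin_theta(p, t)
    return np.column_stack(
        [
            np.ones_like(t),
            np.sin(th),
            p["a"] * np.cos(th) * (-TWO_PI * t / p["b"] ** 2),
            p["a"] * np.cos(th),
        ]
    )


def _sin_ip(p, window=None):
    """Smallest curvature zero on a rising limb: theta = 2 n pi, n integer."""
    lo, hi = window if window is not None else (0.0, math.inf)
    b, c = p["b"], p["c"]
    if b == 0 or p["a"] == 0:
        return None
    # t_n = b (n pi - c) / (2 pi); rising (cos > 0, a > 0) needs even n
    n0 = math.ceil((TWO_PI * lo / b + c) / math.pi)
    for n in range(n0 - 2, n0 + 8):
        if p["a"] > 0 and n % 2 != 0:
            continue
        if p["a"] < 0 and n % 2 == 0:
            continue
        t = b * (n * math.pi - c) / TWO_PI
        if lo < t <= hi:
            return t
    return None


def _sin_starts(data):
    w = data.weights
    t = data.ages
    span = float(t[-1] - t[0])
    y0 = 0.5 * (float(np.max(w)) + float(np.min(w)))
    a = 0.5 * (float(np.max(w)) - float(np.min(w)))
    if a == 0:
        a = max(abs(y0), 1.0) * 0.01
    out = []
    for mult in (2.0, 3.0, 4.0):
        b = mult * span
        x = min(max((w[0] - y0) / a, -1.0), 1.0)
        c = math.asin(x) - TWO_PI * t[0] / b
        out.append({"y0": y0, "a": a, "b": b, "c": c})
    return out


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def build_registry(chanter_exponent: str = "ratio") -> dict[str, ModelSpec]:
    """Build the full model registry.

    Parameters
    ----------
    chanter_exponent:
        ``"ratio"`` (default) uses the internally consistent Chanter exponent
        ``-(mu/d)(1 - e^{-dt})``; ``"product"`` uses the literal reading
        ``-(mu d)(1 - e^{-dt})``.
    """
    if chanter_exponent not in ("ratio", "product"):
        raise ValueError("chanter_exponent must be 'ratio' or 'product'")
    ch_pred, ch_d1, ch_d2, ch_asym = _make_chanter(chanter_exponent)

    specs = [
        ModelSpec(
            name="monomolecular",
            parameter_symbols=("a", "b", "k"),
            predict=_wrap(_mono_predict, "monomolecular"),
            d1=_wrap(_mono_d1, "monomolecular"),
            d2=_wrap(_mono_d2, "monomolecular"),
            asymptote=lambda p: p["a"],
            initial_weight=lambda p: _mono_predict(p, np.array([0.0]))[0],
            closed_form_ip=lambda p, window=None: _mono_ip(p),
            param_jacobian=_mono_jac,
            start_heuristic=_mono_starts,
            positive_params=frozenset({"a", "k"}),
        ),
        ModelSpec(
            name="bridges",
            parameter_symbols=("W0", "a", "k", "m"),
            predict=_wrap(_bridges_predict, "bridges"),
            d1=_wrap(_bridges_d1, "bridges"),
            d2=_wrap(_bridges_d2, "bridges"),
            asymptote=lambda p: p["W0"] + p["a"],
            initial_weight=lambda p: p["W0"] if p["m"] > 0 else _raise_t0("bridges"),
            closed_form_ip=lambda p, window=None: _bridges_ip(p),
            start_heuristic=_bridges_starts,
            positive_params=frozenset({"a", "k", "m"}),
        ),
        ModelSpec(
            name="janoschek",
            parameter_symbols=("a", "W0", "k", "m"),
            predict=_wrap(_jano_predict, "janoschek"),
            d1=_wrap(_jano_d1, "janoschek"),
            d2=_wrap(_jano_d2, "janoschek"),
            asymptote=lambda p: p["a"],
            initial_weight=lambda p: p["W0"] if p["m"] > 0 else _raise_t0("janoschek"),
            closed_form_ip=lambda p, window=None: _bridges_ip(p),
            start_heuristic=_jano_starts,
            positive_params=frozenset({"a", "k", "m"}),
        ),
        ModelSpec(
            name="logistic",
            parameter_symbols=("a", "b", "k"),
            predict=_wrap(_logi_predict, "logistic"),
            d1=_wrap(_logi_d1, "logistic"),
            d2=_wrap(_logi_d2, "logistic"),
            asymptote=lambda p: p["a"],
            initial_weight=lambda p: _logi_predict(p, np.array([0.0]))[0],
            closed_form_ip=lambda p, window=None: _logi_ip(p),
            param_jacobian=_logi_jac,
            start_heuristic=_logi_starts,
            positive_params=frozenset({"a", "b", "k"}),
        ),
        ModelSpec(
            name="von_bertalanffy",
            parameter_symbols=("a", "b", "k"),
            predict=_wrap(_vb_predict, "von_bertalanffy"),
            d1=_wrap(_vb_d1, "von_bertalanffy"),
            d2=_wrap(_vb_d2, "von_bertalanffy"),
            asymptote=lambda p: p["a"],
            initial_weight=lambda p: _vb_predict(p, np.array([0.0]))[0],
            closed_form_ip=lambda p, window=None: _vb_ip(p),
            param_jacobian=_vb_jac,
            start_heuristic=_vb_starts,
            positive_params=frozenset({"a", "b", "k"}),
        ),
        ModelSpec(
            name="richards",
            parameter_symbols=("a", "b", "k", "m"),
            predict=_wrap(_rich_predict, "richards"),
            d1=_wrap(_rich_d1, "richards"),
            d2=_wrap(_rich_d2, "richards"),
            asymptote=lambda p: p["a"],
            initial_weight=lambda p: _rich_predict(p, np.array([0.0]))[0],
            closed_form_ip=lambda p, window=None: _rich_ip(p),
            start_heuristic=_rich_starts,
            positive_params=frozenset({"a", "b", "k", "m"}),
        ),
        ModelSpec(
            name="schumacher",
            parameter_symbols=("a", "b", "k"),
            predict=_wrap(_schu_predict, "schumacher"),
            d1=_wrap(_schu_d1, "schumacher"),
            d2=_wrap(_schu_d2, "schumacher"),
            asymptote=None,
            initial_weight=lambda p: _schu_predict(p, np.array([0.0]))[0],
            start_heuristic=_schu_starts,
            positive_params=frozenset({"a", "b"}),
            dialect="literal-typographic",
        ),
        ModelSpec(
            name="morgan",
            parameter_symbols=("a", "b", "k"),
            predict=_wrap(_morgan_predict, "morgan"),
            d1=_wrap(_morgan_d1, "morgan"),
            d2=_wrap(_morgan_d2, "morgan"),
            asymptote=None,
            initial_weight=lambda p: _morgan_predict(p, np.array([0.0]))[0],
            start_heuristic=_morgan_starts,
            positive_params=frozenset({"a", "b", "k"}),
            dialect="literal-typographic",
        ),
        ModelSpec(
            name="chanter",
            parameter_symbols=("W0", "b", "d", "mu"),
            predict=_wrap(ch_pred, "chanter"),
            d1=_wrap(ch_d1, "chanter"),
            d2=_wrap(ch_d2, "chanter"),
            asymptote=ch_asym,
            initial_weight=lambda p: ch_pred(p, np.array([0.0]))[0],
            start_heuristic=_chanter_starts,
            positive_params=frozenset({"W0", "b", "d", "mu"}),
            dialect=f"chanter-exponent-{chanter_exponent}",
        ),
        ModelSpec(
            name="weibull",
            parameter_symbols=("a", "b", "k", "IP"),
            predict=_wrap(_weib_predict, "weibull"),
            d1=_wrap(_weib_d1, "weibull"),
            d2=_wrap(_weib_d2, "weibull"),
            asymptote=lambda p: p["a"],
            initial_weight=lambda p: _weib_predict(p, np.array([0.0]))[0],
            closed_form_ip=lambda p, window=None: _weib_ip(p),
            start_heuristic=_weib_starts,
            positive_params=frozenset({"a", "IP", "k"}),
        ),
        ModelSpec(
            name="sinusoidal",
            parameter_symbols=("y0", "a", "b", "c"),
            predict=_wrap(_sin_predict, "sinusoidal"),
            d1=_wrap(_sin_d1, "sinusoidal"),
            d2=_wrap(_sin_d2, "sinusoidal"),
            asymptote=lambda p: p["a"] + p["y0"],
            initial_weight=lambda p: p["y0"] + p["a"] * math.sin(p["c"]),
            closed_form_ip=_sin_ip,
            param_jacobian=_sin_jac,
            start_heuristic=_sin_starts,
            positive_params=frozenset({"a", "b"}),
        ),
    ]
    return {s.name: s for s in specs}


def _raise_t0(name):
    raise ModelDomainError(f"{name}: initial weight undefined (t^m with m <= 0 at t = 0)")


_DEFAULT_REGISTRY = build_registry()


def list_models() -> list[ModelSpec]:
    """Return the eleven registered model specifications, in registry order."""
    return [_DEFAULT_REGISTRY[name] for name in MODEL_NAMES]


def get_model(name: str) -> ModelSpec:
    """Look up one model spec by its lowercase registry name."""
    try:
        return _DEFAULT_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# derived quantities (operate on any spec)
# ---------------------------------------------------------------------------


def predict(spec: ModelSpec, params: ParameterVector | Mapping[str, float], t):
    """Evaluate body weight (kg) at age ``t`` (days)."""
    return spec.predict(_pdict(spec, params), t)


def agr(spec: ModelSpec, params, t):
    """Absolute growth rate (kg/day): the analytic first time-derivative."""
    return spec.d1(_pdict(spec, params), t)


def curvature(spec: ModelSpec, params, t):
    """Second time-derivative of the growth curve (kg/day^2)."""
    return spec.d2(_pdict(spec, params), t)


def asymptotic_weight(spec: ModelSpec, params) -> float | None:
    """Mature (asymptotic) weight, or ``None`` where the model defines none.

    For most forms this is the ``t -> infinity`` limit under the sign
    convention that makes the exponential term vanish (the parameter ``a``);
    for the sinusoidal model it is the upper envelope ``a + y0``; for Bridges
    ``W0 + a``; Schumacher and Morgan have no estimated asymptote.
    """
    p = _pdict(spec, params)
    return None if spec.asymptote is None else float(spec.asymptote(p))


def initial_weight(spec: ModelSpec, params) -> float:
    """Predicted weight at hatch (t = 0); ``y0 + a sin(c)`` for sinusoidal."""
    return float(spec.initial_weight(_pdict(spec, params)))


def inflection_time(
    spec: ModelSpec,
    params,
    window: tuple[float, float],
    tol: float = 1e-8,
) -> float | None:
    """Smallest age in ``window`` where curvature is zero and AGR positive.

    Uses the model's closed-form inflection rule when available; otherwise a
    sign-change scan plus bisection on the second derivative to ``tol`` days.
    Returns ``None`` when no admissible root lies in the window.
    """
    lo, hi = float(window[0]), float(window[1])
    if not (hi > lo >= 0):
        raise ValueError("window must satisfy 0 <= lo < hi")
    p = _pdict(spec, params)

    if spec.closed_form_ip is not None:
        try:
            t0 = spec.closed_form_ip(p, (lo, hi))
        except TypeError:
            t0 = spec.closed_form_ip(p)
        if t0 is not None and lo < t0 <= hi and spec.d1(p, t0) > 0:
            return float(t0)
        if spec.name == "sinusoidal":
            return None  # closed form enumerates all candidates

    # bracketing scan on curvature
    eps = max(lo, 1e-9 * max(hi, 1.0))
    grid = np.linspace(max(lo, eps + 1e-12), hi, 2049)
    try:
        vals = spec.d2(p, grid)
    except ModelDomainError:
        return None
    sign = np.sign(vals)
    for i in range(len(grid) - 1):
        if sign[i] == 0 and spec.d1(p, grid[i]) > 0:
            return float(grid[i])
        if sign[i] * sign[i + 1] < 0:
            a_, b_ = grid[i], grid[i + 1]
            while b_ - a_ > tol:
                mid = 0.5 * (a_ + b_)
                if np.sign(spec.d2(p, mid)) == np.sign(spec.d2(p, a_)):
                    a_ = mid
                else:
                    b_ = mid
            root = 0.5 * (a_ + b_)
            if spec.d1(p, root) > 0:
                return float(root)
    return None


def _pdict(spec: ModelSpec, params) -> dict[str, float]:
    if isinstance(params, ParameterVector):
        if params.model_name != spec.name:
            raise ValueError(
                f"parameter vector for {params.model_name!r} used with {spec.name!r}"
            )
        vals = params.values
    else:
        vals = params
    pv = spec.make_params(vals)  # validates symbols and finiteness
    return dict(pv.values)
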