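"""Exception hierarchy shared across the package."""


class GrowthCurvesError(Exception):
    """Base class for all package errors."""


class ModelDomainError(GrowthCurvesError):
    """A model form is mathematically undefined at the requested inputs.

    Raised instead of silently returning NaN/complex values, e.g. when a
    power-law age term ``t**m`` with ``m < 0`` is evaluated at ``t = 0``.
    """


class FitError(GrowthCurvesError):
    """Nonlinear least-squares fitting failed."""


class SingularNormalEquationsError(FitError):
    """The (damped) Gauss-Newton normal equations could not be solved."""
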