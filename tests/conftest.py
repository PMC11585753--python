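"""Shared fixtures: published estimates, canonical parameter draws, data."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import growthcurves as gc

DATA_DIR = Path(__file__).parent / "data"

# One realistic parameter draw per model, used by derivative/Jacobian checks.
# Where available these are published estimates (data set 1); for the models
# whose published scale cells are garbled they are plausible fitted values.
CANONICAL_PARAMS = {
    "monomolecular": {"a": 104.5, "b": 2.9920, "k": 0.0163},
    "bridges": {"W0": 2.8732, "a": 108.1, "k": 0.00002, "m": 1.9516},
    "janoschek": {"a": 110.9, "W0": 2.8732, "k": 0.00002, "m": 1.9516},
    "logistic": {"a": 104.5, "b": 19.9255, "k": 0.0163},
    "von_bertalanffy": {"a": 131.0, "b": 0.8580, "k": 0.00656},
    "richards": {"a": 116.5, "b": 0.3656, "k": 0.00964, "m": 0.0776},
    "schumacher": {"a": 95.0, "b": 130.0, "k": 1.1},
    "morgan": {"a": 42000.0, "b": 175.0, "k": 2.3},
    "chanter": {"W0": 1.9078, "b": 110.0, "d": 0.0116, "mu": 0.0375},
    "weibull": {"a": 110.9, "b": 2.8732, "k": 1.9516, "IP": 161.0},
    "sinusoidal": {"y0": 49.3647, "a": 51.3537, "b": 843.2, "c": 4.9835},
}


@pytest.fixture(scope="session")
def reference_gof() -> pd.DataFrame:
    """Published goodness-of-fit statistics (long format)."""
    return pd.read_csv(DATA_DIR / "reference_gof.csv")


@pytest.fixture(scope="session")
def sin1():
    return gc.reference_params(1, "sinusoidal")


@pytest.fixture(scope="session")
def sin2():
    return gc.reference_params(2, "sinusoidal")


@pytest.fixture(scope="session")
def weib1():
    return gc.reference_params(1, "weibull")


@pytest.fixture(scope="session")
def sin1_clean_data(sin1):
    """Noiseless 12-point monthly series from the sinusoidal estimates."""
    design = gc.SimulationDesign("sinusoidal", sin1, noise_sd=0.0, seed=0)
    return gc.simulate_trajectory(design)


@pytest.fixture(scope="session")
def sin1_noisy_data(sin1):
    """Noisy (sd 0.5 kg) 12-point monthly series, fixed seed."""
    design = gc.SimulationDesign("sinusoidal", sin1, noise_sd=0.5, seed=7)
    return gc.simulate_trajectory(design)


def finite_diff_d1(spec, params, t, h=1e-2):
    return (gc.predict(spec, params, t + h) - gc.predict(spec, params, t - h)) / (2 * h)


def finite_diff_d2(spec, params, t, h=1e-2):
    return (
        gc.predict(spec, params, t + h)
        - 2 * gc.predict(spec, params, t)
        + gc.predict(spec, params, t - h)
    ) / h**2
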