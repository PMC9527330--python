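import numpy as np
import pytest

from ergpheno.config import RunConfig
from ergpheno.signal import STD_GRID, RawTrace, StdTrace, TraceKey
from ergpheno.synthcohort import SimConfig, generate_cohort


def make_key(patient="P0", eye="R", stimulus="DA10", repeat=1):
    return TraceKey(patient, eye, stimulus, repeat)


def make_std(voltage, **key_kwargs):
    return StdTrace(make_key(**key_kwargs), np.asarray(voltage, dtype=float))


def flash_wave(a_amp=250.0, a_time=15.0, b_amp=400.0, b_time=48.0,
               sigma_a=4.0, sigma_b=12.0, t=STD_GRID):
    return -a_amp * np.exp(-((t - a_time) ** 2) / (2 * sigma_a**2)) + b_amp * np.exp(
        -((t - b_time) ** 2) / (2 * sigma_b**2)
    )


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def fast_config():
    """Reduced hyperparameter grids and a single CV repeat, for speed."""
    return RunConfig(
        svm_grid=[{"C": 1.0, "gamma": "scale"}],
        ada_grid=[{"max_depth": 1, "n_estimators": 50}],
        lr_grid=[{"C": 1.0}],
        final_svm_c_grid=[1.0],
        cv_repeats=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient default-mode cohort shared across read-only tests."""
    return generate_cohort(SimConfig(n_patients=60, n_unilateral=2), seed=7)
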