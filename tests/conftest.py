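import numpy as np
import pytest

from eyepupil import EyeSpec, SweepSpec, ablation_suite, run_sweep
from eyepupil.experiments import e_sensitivity, turning_point_vs_sr


@pytest.fixture(scope="session")
def replication_eye_spec() -> EyeSpec:
    """The stationary-eye measurement condition: slightly myopic right eye."""
    return EyeSpec(spherical_error=-0.823)


@pytest.fixture(scope="session")
def replication_sweep():
    """Full viewing-angle sweep under the default replication settings."""
    return run_sweep(SweepSpec())


@pytest.fixture(scope="session")
def ablation_results():
    """Sweeps with model components added one at a time, plus the RMSE table."""
    return ablation_suite(SweepSpec())


@pytest.fixture(scope="session")
def turning_point_table():
    """Fitted turning point across emmetropic to strongly myopic eyes."""
    return turning_point_vs_sr([0.0, -5.0, -10.0])


@pytest.fixture(scope="session")
def e_stop_table():
    """Half-period scale across the physiological stop-radius range."""
    return e_sensitivity("stop_radius", [1.5, 2.65, 3.5])


@pytest.fixture(scope="session")
def e_iris_depth_table():
    """Half-period scale under accommodative-scale iris-depth perturbation."""
    return e_sensitivity("iris_depth", [3.7, 3.9, 4.1])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
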