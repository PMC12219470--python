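import numpy as np
import pytest

from duoscope.config import AnalysisConfig, ExperimentConfig
from duoscope.synthetic import simulate_experiment


@pytest.fixture(scope="session")
def small_cfg() -> ExperimentConfig:
    return ExperimentConfig(
        n_sessions=3,
        n_cells=25,
        session_duration_s=120.0,
        fps=15.0,
        fov_shape=(160, 160),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    return simulate_experiment(small_cfg)


@pytest.fixture(scope="session")
def single_session_cfg() -> ExperimentConfig:
    # one fully active session; used for spatial/place-cell tests
    return ExperimentConfig(
        n_sessions=1,
        n_cells=30,
        session_duration_s=300.0,
        fps=15.0,
        activity_prob=1.0,
        place_cell_fraction=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def single_session(single_session_cfg):
    from duoscope.spatial import segment_trajectory

    sessions, truth = simulate_experiment(single_session_cfg)
    ses = sessions[0]
    segment_trajectory(ses.trajectory)
    return ses, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_analysis() -> AnalysisConfig:
    return AnalysisConfig()
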