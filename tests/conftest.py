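"""Shared fixtures: small simulated studies and helper oracles."""

import numpy as np
import pytest

from pointkin import pipeline
from pointkin.movement_simulator import (SimConfig, evaluate_speed_shape,
                                         simulate_study)
from pointkin.trajectory_io import StudyDesign


@pytest.fixture(scope="session")
def small_design():
    """A 4-participant study with the full factorial cell structure."""
    return StudyDesign(n_participants=4)


@pytest.fixture(scope="session")
def small_study(small_design):
    cfg = SimConfig(design=small_design, seed=21, n_outlier_trials=0,
                    n_missing_trials=0)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_study, small_design):
    trials, _ = small_study
    return pipeline.run_landmark_analysis(trials, small_design,
                                          keep_series=True)


@pytest.fixture(scope="session")
def default_study():
    """The full study-scale simulation: 27 participants, 5184 trials,
    2 injected duration outliers + 1 injected missing-sample trial."""
    cfg = SimConfig(seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_analysis(default_study):
    trials, _ = default_study
    return pipeline.run_landmark_analysis(trials, keep_series=True)


def oracle_truncated_rdpv(rdpv_target: float, threshold: float = 0.10,
                          n_dense: int = 400001) -> float:
    """Segmentation-adjusted rDPV of the analytic beta speed curve: dense
    numerical evaluation, 10%-of-peak truncation, relative peak time of the
    truncated curve (independent of the extraction pipeline)."""
    tau = np.linspace(0.0, 1.0, n_dense)
    v = evaluate_speed_shape(rdpv_target, tau)
    above = np.flatnonzero(v > threshold * v.max())
    onset, offset = above[0], above[-1]
    return 100.0 * (np.argmax(v) - onset) / (offset - onset)
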