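import numpy as np
import pytest

import dopaproxy as dp
from dopaproxy.synthdata import KineticGroundTruth, frame_average, simulate_tissue_tac


@pytest.fixture(scope="session")
def study_schedule():
    return dp.study_frame_schedule()


@pytest.fixture(scope="session")
def default_truth():
    return KineticGroundTruth()


@pytest.fixture(scope="session")
def tissue_curves(default_truth):
    """Continuous noise-free target and reference curves over the scan span."""
    t = np.linspace(0.0, 89.0, 200)
    target = simulate_tissue_tac(default_truth, t, "target")
    reference = simulate_tissue_tac(default_truth, t, "reference")
    return target, reference


@pytest.fixture(scope="session")
def noise_free_tacs(tissue_curves, study_schedule):
    """Noise-free frame-averaged TACs on the 24-frame/89-min schedule."""
    target, reference = tissue_curves
    return (
        frame_average(target, study_schedule, region_label="striatum"),
        frame_average(reference, study_schedule, region_label="cerebellum"),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Study-sized cohort with all trait-ki correlations truly zero."""
    return dp.simulate_cohort(dp.study_cohort_spec(seed=42))
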