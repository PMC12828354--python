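import numpy as np
import pytest
from hypothesis import settings

import svautocorr as sv

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_spec() -> sv.SimSpec:
    """Reduced-grid study conditions: same band structure, ~330-voxel masks."""
    return sv.SimSpec(n_per_group=4, grid_shape=(20, 22, 14), seed=7)


@pytest.fixture(scope="session")
def small_masks(small_spec):
    return sv.make_roi_masks(small_spec)


@pytest.fixture(scope="session")
def control_acmap(small_spec, small_masks):
    """One control participant's left-hemisphere autocorrelation map."""
    left, right, truth = small_masks
    rec = sv.ParticipantRecord(pid="sub-001", group="control")
    rng = np.random.default_rng(11)
    run, motion = sv.simulate_participant(small_spec, rec, (left, right), truth, rng)
    tc = sv.extract_roi_timecourses(run, left)
    return sv.autocorr_map(tc)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return sv.simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort):
    from svautocorr.pipeline import analyze_cohort

    return analyze_cohort(small_cohort, seed=3, n_restarts=8)
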