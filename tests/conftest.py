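import dataclasses

import numpy as np
import pytest

from neuroprint import cohort, connectivity as conn, fingerprint as fp
from neuroprint.types import TimeSeriesRun


def make_run(data, fs=7.8, contrast="HbO", subject="s0", run="r0"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return TimeSeriesRun(
        subject_id=subject,
        run_id=run,
        contrast=contrast,
        data=data,
        sampling_rate=fs,
        channel_ids=[f"ch{i:02d}" for i in range(data.shape[0])],
    )


@pytest.fixture
def run_factory():
    return make_run


def _fcset_from_config(cfg):
    dataset = cohort.generate_cohort(cfg)
    return fp.build_fc_set([conn.fc_from_run(r) for r in dataset.runs])


@pytest.fixture(scope="session")
def default_fcset():
    """Strong-signature 21x5x48 cohort: ceiling accuracy at full training."""
    return _fcset_from_config(cohort.default_identification_config())


@pytest.fixture(scope="session")
def graded_fcset():
    """Harder cohort with sub-ceiling single-run accuracy."""
    return _fcset_from_config(cohort.graded_identification_config())


@pytest.fixture(scope="session")
def chance_fcsets():
    """Three zero-signature cohorts for chance-floor calibration."""
    base = cohort.default_identification_config()
    sets = []
    for seed in (7, 8, 9):
        cfg = dataclasses.replace(base, signature_strength=0.0, seed=seed)
        sets.append((seed, _fcset_from_config(cfg)))
    return sets
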