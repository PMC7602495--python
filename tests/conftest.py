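import numpy as np
import pytest

import tremorkit as tk


@pytest.fixture(scope="session")
def default_dataset():
    """The default 6-subject cohort, preprocessed and featurized once.

    Shared by the pipeline-level discrimination tests; computing the NTF
    stage for all 12 recordings dominates the cost, so it runs one time
    per session.
    """
    cohort = tk.gen_cohort(6, seed=1)
    ds = tk.build_dataset(cohort, feature_set=["mfcc_tnt", "energy"])
    return cohort, ds


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-subject, 5-minute-per-hand cohort for cheap pipeline tests."""
    return tk.gen_cohort(3, seed=11, config={"duration_s": 300.0})


@pytest.fixture(scope="session")
def mil_dataset():
    """A 4-subject, 10-minute-per-hand cohort with diary entries, featurized."""
    cohort = tk.gen_cohort(4, seed=5, config={"duration_s": 600.0})
    ds = tk.build_dataset(cohort, feature_set="mfcc_tnt")
    return cohort, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sine_window(freq_hz: float, amp: float = 1.0, axis: int = 0) -> np.ndarray:
    """A 150-sample window with a pure sine on one axis."""
    t = np.arange(150) / 50.0
    w = np.zeros((150, 3))
    w[:, axis] = amp * np.sin(2 * np.pi * freq_hz * t)
    return w
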