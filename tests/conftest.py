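import numpy as np
import pytest

import popsse as p


@pytest.fixture(scope="session")
def base_truth_30():
    return p.base_truth(30.0)


@pytest.fixture(scope="session")
def small_dataset(base_truth_30):
    """One 6-subject, 8-sample dataset at 30% IIV (fixed stream)."""
    rng = np.random.default_rng(12345)
    return p.simulate_dataset(p.base_design(), base_truth_30, 0, rng=rng, iiv_level=30.0)


@pytest.fixture(scope="session")
def toy_dataset(base_truth_30):
    """2-subject, 4-observation toy at 10% IIV for oracle comparisons."""
    truth = p.base_truth(10.0)
    design = p.StudyDesign(
        n_subjects=2, sampling_times=(0.5, 2.0, 8.0, 24.0), iiv_levels=(10.0,),
        n_replicates=1, seed=7,
    )
    rng = np.random.default_rng(777)
    return p.simulate_dataset(design, truth, 0, rng=rng, iiv_level=10.0), truth
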