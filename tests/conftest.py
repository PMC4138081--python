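import numpy as np
import pytest

from mirforge.models import oyster_sample_sheet
from mirforge import synthetic as syn


@pytest.fixture(scope="session")
def samples():
    return oyster_sample_sheet()


@pytest.fixture(scope="session")
def small_truth(samples):
    """A small validated study: 8 true plants + 1 decoy per criterion on a
    3 x 30 kb genome (session-scoped; generation is deterministic)."""
    specs = syn.study_plants(samples, n_true=8, n_decoys_per_criterion=1,
                             seed=7, n_clusters=1, cluster_size=3)
    return syn.plant_genome(3, 30_000, 0.4, specs, seed=8)


@pytest.fixture(scope="session")
def small_reads(small_truth, samples):
    return syn.simulate_reads(small_truth, samples, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
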