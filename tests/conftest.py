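import numpy as np
import pytest

from hicsub import annotate as ann
from hicsub import hic_matrix as hm
from hicsub import synthetic as syn
from hicsub.autoencoder import TrainingConfig

@pytest.fixture(scope="session")
def small_model() -> syn.PlantedModel:
    """A fast 200x200-bin planted model (two chromosomes per parity)."""
    return syn.PlantedModel(
        n_odd=200, n_even=200, depth=5e5, n_chroms_odd=2, n_chroms_even=2, seed=10
    )


@pytest.fixture(scope="session")
def small_fixture(small_model):
    dense, truth = syn.generate_dense(small_model)
    sparse = syn.generate_sparse(dense, 0.1, 11)
    return dense, sparse, truth


@pytest.fixture(scope="session")
def small_models(small_fixture):
    """Models trained once on the small fixture; reused across tests."""
    dense, _, truth = small_fixture
    cfg = TrainingConfig(seed=10)
    return ann.train_models(dense, 0.1, truth, cfg)


@pytest.fixture
def grids_3x3():
    odd = hm.BinGrid.from_chrom_sizes({"chr1": 300_000}, bin_size=100_000)
    even = hm.BinGrid.from_chrom_sizes({"chr2": 300_000}, bin_size=100_000)
    return odd, even


def make_track(labels, bin_size=100_000, chrom="chr1", proba=None):
    """AnnotationTrack on one synthetic chromosome from integer label codes."""
    labels = np.asarray(labels)
    bins = [
        hm.GenomicBin(chrom, i * bin_size, bin_size) for i in range(labels.size)
    ]
    return ann.AnnotationTrack(bins, labels, proba)
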