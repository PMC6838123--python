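"""Planted-truth generator for inter-chromosomal contact matrices.

Emulates the single statistical feature the pipeline relies on: 100 kb
bins carry one of five subcompartment identities arranged in contiguous
domain-like runs, and the expected contact count between two bins of
opposite parity depends only on their label pair through a symmetric
5×5 affinity matrix R.  Counts are independent Poisson draws scaled so
the expected matrix total equals a target sequencing depth; coverage
titration is binomial thinning of those counts.

The default affinity matrix is diagonal-dominant with strong A1–A1,
A2–A2 and B3–B3 self-affinity, moderate within-A and within-B cross
terms, weak A–B terms, and B1 intermediate — mirroring how the active
and inactive compartments segregate in real inter-chromosomal maps.  The
values are simulation knobs, not estimates of real contact frequencies.

What this does NOT emulate: distance effects (irrelevant between
chromosomes), mappability/GC bias, copy-number variation, translocation
artifacts, or cell-type mixtures.  Pipeline accuracy on these fixtures
therefore bounds what clean block-structured data allows, not real-data
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifier as clf
from . import hic_matrix as hm
from .annotate import AnnotationTrack, track_from_grids
from .evaluation import SignalTrack

# label order: A1, A2, B1, B2, B3
DEFAULT_PROPORTIONS = (0.15, 0.25, 0.15, 0.15, 0.30)
DEFAULT_AFFINITY = np.array(
    [
        [30.0, 8.0, 1.0, 0.5, 0.5],
        [8.0, 24.0, 1.5, 0.8, 0.8],
        [1.0, 1.5, 16.0, 4.0, 3.0],
        [0.5, 0.8, 4.0, 20.0, 7.0],
        [0.5, 0.8, 3.0, 7.0, 26.0],
    ]
)
DEFAULT_SIGNAL_MEANS = (4.0, 3.0, 2.0, 1.0, 0.5)  # active-to-repressed gradient


@dataclass
class PlantedModel:
    """Configuration of the planted-subcompartment simulator."""

    n_odd: int = 400
    n_even: int = 400
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    affinity: np.ndarray = field(default_factory=lambda: DEFAULT_AFFINITY.copy())
    depth: float = 2e6  # expected total read pairs in the dense matrix
    bin_size: int = hm.DEFAULT_BIN_SIZE
    n_chroms_odd: int = 4  # synthetic chr1,3,5,7
    n_chroms_even: int = 4  # synthetic chr2,4,6,8
    mean_run: float = 8.0  # geometric domain length in bins
    min_run: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.affinity = np.asarray(self.affinity, dtype=np.float64)
        if self.affinity.shape != (5, 5) or not np.allclose(self.affinity, self.affinity.T):
            raise ValueError("affinity must be a symmetric 5x5 matrix")
        if np.any(self.affinity <= 0):
            raise ValueError("affinity entries must be positive")
        if not np.isclose(sum(self.proportions), 1.0):
            raise ValueError("label proportions must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def _grids(model: PlantedModel) -> tuple[hm.BinGrid, hm.BinGrid]:
    def sizes(n_bins: int, n_chroms: int, start_num: int, step: int) -> dict[str, int]:
        per = [n_bins // n_chroms] * n_chroms
        for i in range(n_bins % n_chroms):
            per[i] += 1
        return {
            f"chr{start_num + step * i}": per[i] * model.bin_size
            for i in range(n_chroms)
        }

    odd = hm.BinGrid.from_chrom_sizes(sizes(model.n_odd, model.n_chroms_odd, 1, 2),
                                      bin_size=model.bin_size)
    even = hm.BinGrid.from_chrom_sizes(sizes(model.n_even, model.n_chroms_even, 2, 2),
                                       bin_size=model.bin_size)
    return odd, even


def _plant_labels(n: int, model: PlantedModel, rng: np.random.Generator) -> np.ndarray:
    """Contiguous label runs with geometric lengths (min enforced)."""
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    prev = -1
    p_new = min(1.0, 1.0 / max(self_mean := model.mean_run - model.min_run + 1, 1.0))
    probs = np.asarray(model.proportions, dtype=np.float64)
    while pos < n:
        choices = probs.copy()
        if prev >= 0:  # avoid zero-length boundaries between equal labels
            choices[prev] = 0.0
            choices /= choices.sum()
        lab = int(rng.choice(5, p=choices))
        run = model.min_run + rng.geometric(p_new) - 1
        labels[pos : pos + run] = lab
        pos += run
        prev = lab
    return labels


def generate_dense(model: PlantedModel) -> tuple[hm.InterContactMatrix, AnnotationTrack]:
    """Dense Poisson contact matrix plus the planted truth track.

    ``C_ij ~ Poisson(depth · R[l_i, l_j] / Z)`` with Z the sum of
    ``R[l_i, l_j]`` over all cells, so ``E[total] = depth``.  A pure
    function of (model, seed).
    """
    rng = np.random.default_rng(model.seed)
    odd_grid, even_grid = _grids(model)
    lab_odd = _plant_labels(model.n_odd, model, rng)
    lab_even = _plant_labels(model.n_even, model, rng)
    mean = model.affinity[np.ix_(lab_odd, lab_even)]
    mean = mean * (model.depth / mean.sum())
    counts = rng.poisson(mean).astype(np.float64)
    matrix = hm.InterContactMatrix(odd_grid, even_grid, counts)
    labels = np.concatenate([lab_odd, lab_even])
    proba = np.zeros((labels.size, len(clf.LABELS)))
    proba[np.arange(labels.size), labels] = 1.0
    truth = track_from_grids(odd_grid, even_grid, labels, proba, "planted-truth")
    return matrix, truth


def generate_sparse(
    dense: hm.InterContactMatrix, keep_rate: float, seed: int
) -> hm.InterContactMatrix:
    """Coverage titration of a dense fixture (binomial thinning)."""
    return hm.downsample(dense, keep_rate, seed)


def generate_signal_tracks(
    truth: AnnotationTrack,
    means: tuple[float, ...] = DEFAULT_SIGNAL_MEANS,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> SignalTrack:
    """Gaussian signal around each bin's label mean (a ChIP-like track)."""
    if len(means) != len(clf.LABELS):
        raise ValueError("need one mean per subcompartment label")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    means_arr = np.asarray(means, dtype=np.float64)
    values = np.full(len(truth), np.nan)
    ok = truth.labels != clf.NA
    values[ok] = means_arr[truth.labels[ok]] + rng.normal(0.0, noise_sd, ok.sum())
    return SignalTrack(truth.bins, values)


def default_fixture(
    seed: int = 0, keep_rate: float = 0.1, **overrides
) -> tuple[hm.InterContactMatrix, hm.InterContactMatrix, AnnotationTrack]:
    """(dense, sparse, truth) at the standard desk-scale study conditions."""
    model = PlantedModel(seed=seed, **overrides)
    dense, truth = generate_dense(model)
    sparse = generate_sparse(dense, keep_rate, seed + 1)
    return dense, sparse, truth
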