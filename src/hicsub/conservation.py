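"""Cross-cell-type conservation states and information content.

Given subcompartment tracks for N cell types on one bin grid, each bin
gets a count vector over the five labels.  Its annotation entropy is

    S_i = Σ_c −p_{i,c} · log p_{i,c},   p_{i,c} = (# cell types with label c) / N,

with natural logs and 0·log 0 ≡ 0.  Because annotations are discrete,
only finitely many count multisets — partitions of N into at most five
parts — can occur, so S takes finitely many values (23 for N = 9).
Multiset classes in which no label reaches a majority (max count < ⌈(N+1)/2⌉;
"fewer than 5 out of 9") are merged into a single non-conserved (NC)
state; the remaining classes are numbered 1, 2, … by ascending entropy,
state 1 being perfectly conserved.  For N = 9 that yields 12 numbered
states plus NC.  Per-label information content is IC = |p·log(p/q)| with
uniform background q = 0.2.

Bins where any cell type is NA are excluded from state assignment and
reported separately (their entropy would not be comparable).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from . import classifier as clf
from .annotate import AnnotationTrack

NC = 0  # state code for the merged non-conserved class; numbered states are 1..K
_ROUND = 12  # decimals for grouping float entropies into discrete classes


def annotation_fractions(tracks: list[AnnotationTrack]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin label counts, fractions, and the all-annotated mask.

    All tracks must share one bin grid.  Returns ``(counts, p, complete)``
    where counts is (n_bins, 5) over non-NA annotations, p normalizes each
    row by its annotated total (NaN rows where nothing is annotated), and
    complete flags bins annotated in every track.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two cell-type tracks")
    bins0 = tracks[0].bins
    for t in tracks[1:]:
        if t.bins != bins0:
            raise ValueError("annotation tracks are on different bin grids")
    stack = np.stack([t.labels for t in tracks])  # (N, n_bins)
    n_bins = stack.shape[1]
    counts = np.zeros((n_bins, len(clf.LABELS)), dtype=np.int64)
    for c in range(len(clf.LABELS)):
        counts[:, c] = (stack == c).sum(axis=0)
    total = counts.sum(axis=1)
    complete = total == len(tracks)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / total[:, None]
    return counts, p, complete


def annotation_entropy(p: np.ndarray) -> np.ndarray:
    """S = Σ −p log p (natural log, 0·log 0 = 0) per row; rows must sum to 1."""
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each fraction vector must be nonnegative and sum to 1")
    return _scipy_entropy(p, axis=1)


def information_content(p: np.ndarray | float, q: float = 0.2) -> np.ndarray | float:
    """IC = |p·log(p/q)| per label fraction; 0 at p = 0 and at p = q."""
    if q <= 0:
        raise ValueError("background probability q must be positive")
    arr = np.asarray(p, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("fractions must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = np.abs(arr * np.log(arr / q))
    ic = np.where(arr == 0, 0.0, ic)
    return float(ic) if np.isscalar(p) else ic


@dataclass(frozen=True)
class StateTable:
    """The discrete entropy classes achievable for N cell types, 5 labels."""

    n_cell_types: int
    entropies: tuple[float, ...]  # all distinct values, ascending
    majority_entropies: tuple[float, ...]  # those with a majority label, ascending
    n_nc_classes: int  # distinct-entropy classes merged into NC

    @property
    def n_states(self) -> int:
        """Numbered states plus NC."""
        return len(self.majority_entropies) + 1

    def state_of(self, count_vector: np.ndarray) -> int:
        """State code for one count vector: 1..K by ascending entropy, 0 = NC."""
        counts = np.asarray(count_vector)
        if counts.sum() != self.n_cell_types:
            raise ValueError("count vector does not sum to the number of cell types")
        if 2 * counts.max() <= self.n_cell_types:
            return NC
        s = round(float(annotation_entropy(counts / self.n_cell_types)[0]), _ROUND)
        return self.majority_entropies.index(s) + 1


def _partitions(n: int, parts: int, cap: int | None = None) -> list[tuple[int, ...]]:
    cap = n if cap is None else cap
    if parts == 1:
        return [(n,)] if n <= cap else []
    out = []
    for k in range(min(n, cap), -1, -1):
        out.extend((k, *rest) for rest in _partitions(n - k, parts - 1, k))
    return out


@lru_cache(maxsize=None)
def enumerate_states(n_cell_types: int, n_labels: int = 5) -> StateTable:
    """Enumerate every count multiset and build the state table.

    Count multisets are partitions of N into at most ``n_labels`` parts;
    entropy depends only on the multiset.  A class joins NC when its
    maximum count is not a strict majority (max·2 ≤ N).
    """
    if n_cell_types < 2:
        raise ValueError("need at least two cell types")
    parts = _partitions(n_cell_types, n_labels)
    ent: dict[float, int] = {}  # entropy -> max count in that class
    for p in parts:
        s = round(float(annotation_entropy(np.array(p) / n_cell_types)[0]), _ROUND)
        ent[s] = max(ent.get(s, 0), max(p))
    all_e = tuple(sorted(ent))
    maj = tuple(s for s in all_e if 2 * ent[s] > n_cell_types)
    return StateTable(n_cell_types, all_e, maj, len(all_e) - len(maj))


@dataclass
class ConservationProfile:
    """Per-bin conservation summary across N cell types."""

    bins: list
    counts: np.ndarray  # (n, 5)
    fractions: np.ndarray  # (n, 5)
    entropy: np.ndarray  # (n,)
    states: np.ndarray  # (n,) 1..K, 0 = NC, -1 = incomplete (some NA)
    ic: np.ndarray  # (n, 5)
    mode: np.ndarray  # (n,) most frequent label code, -1 where incomplete
    table: StateTable


def assign_states(tracks: list[AnnotationTrack], q: float = 0.2) -> ConservationProfile:
    """Full conservation profile for a set of cell-type tracks."""
    if not tracks:
        raise ValueError("empty track set")
    counts, p, complete = annotation_fractions(tracks)
    table = enumerate_states(len(tracks))
    n = counts.shape[0]
    states = np.full(n, -1, dtype=np.int64)
    ent = np.full(n, np.nan)
    ic = np.full((n, len(clf.LABELS)), np.nan)
    mode = np.full(n, -1, dtype=np.int64)
    idx = np.flatnonzero(complete)
    if idx.size:
        ent[idx] = annotation_entropy(p[idx])
        ic[idx] = information_content(p[idx], q)
        mode[idx] = np.argmax(counts[idx], axis=1)
        for i in idx:
            states[i] = table.state_of(counts[i])
    return ConservationProfile(
        tracks[0].bins, counts, p, ent, states, ic, mode, table
    )


# ----------------------------------------------------------------------
# text outputs


def write_state_bed(profile: ConservationProfile, path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for i, b in enumerate(profile.bins):
            if profile.states[i] < 0:
                continue
            name = "NC" if profile.states[i] == NC else str(int(profile.states[i]))
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{name}\n")
            n += 1
    return n


def write_entropy_bedgraph(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(profile.bins):
            if np.isnan(profile.entropy[i]):
                continue
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{profile.entropy[i]:.6f}\n")


def write_ic_bedgraphs(profile: ConservationProfile, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c, name in enumerate(clf.LABELS):
        with open(directory / f"ic_{name}.bedgraph", "w") as fh:
            for i, b in enumerate(profile.bins):
                if np.isnan(profile.ic[i, c]):
                    continue
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{profile.ic[i, c]:.6f}\n")
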