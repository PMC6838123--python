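"""Genomic bin grids and inter-chromosomal Hi-C contact matrices.

The central object is the inter-chromosomal contact matrix: rows are fixed
100 kb bins on the odd-numbered autosomes, columns are bins on the
even-numbered autosomes, entries are raw (or pre-normalized) contact
counts.  Subcompartment-specific contact patterns are far more distinct in
this inter-chromosomal block than within chromosomes, which is why the
whole pipeline operates on it.

Coordinates are 0-based, half-open, fixed-width bins; the final partial
bin of each chromosome is kept but flagged ``truncated``.  The
contact-probability transform maps a count ``C`` to ``exp(-1/C)`` (0 at
C = 0, the analytic limit), compressing heavy-tailed counts into [0, 1)
so networks can train with binary cross-entropy.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 100_000

_CHROM_NUM = re.compile(r"^(?:chr)?(\d+)$")


def chromosome_number(chrom: str) -> int | None:
    """Autosome number of a chromosome name, or None (chrX, chrM, ...)."""
    m = _CHROM_NUM.match(chrom)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width genomic interval [start, start+length)."""

    chrom: str
    start: int
    bin_size: int = DEFAULT_BIN_SIZE
    length: int = 0  # 0 means full bin_size; shorter => truncated terminal bin

    def __post_init__(self) -> None:
        if self.start < 0 or self.start % self.bin_size != 0:
            raise ValueError(f"bin start {self.start} invalid for size {self.bin_size}")
        if self.length == 0:
            object.__setattr__(self, "length", self.bin_size)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def truncated(self) -> bool:
        return self.length < self.bin_size


class BinGrid:
    """Ordered bins of one chromosome-parity group with an index map."""

    def __init__(self, bins: Iterable[GenomicBin]):
        self.bins: list[GenomicBin] = list(bins)
        if not self.bins:
            raise ValueError("empty grid")
        self.index: dict[tuple[str, int], int] = {}
        for i, b in enumerate(self.bins):
            key = (b.chrom, b.start)
            if key in self.index:
                raise ValueError(f"duplicate bin {key}")
            self.index[key] = i
        self.chroms: list[str] = list(dict.fromkeys(b.chrom for b in self.bins))

    def __len__(self) -> int:
        return len(self.bins)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BinGrid) and self.bins == other.bins

    def position(self, chrom: str, start: int) -> int:
        return self.index[(chrom, start)]

    def chrom_mask(self, chroms: Iterable[str]) -> np.ndarray:
        wanted = set(chroms)
        return np.array([b.chrom in wanted for b in self.bins])

    @classmethod
    def from_chrom_sizes(
        cls,
        sizes: dict[str, int],
        parity: str | None = None,
        bin_size: int = DEFAULT_BIN_SIZE,
    ) -> "BinGrid":
        """Tile chromosomes into bins, optionally keeping one parity.

        ``parity`` is ``"odd"`` or ``"even"`` (autosome number); ``None``
        keeps every chromosome in ``sizes``.  Chromosomes are ordered by
        autosome number, then name.
        """
        items = []
        for chrom, size in sizes.items():
            num = chromosome_number(chrom)
            if parity is not None:
                if num is None:
                    continue
                if parity == "odd" and num % 2 == 0:
                    continue
                if parity == "even" and num % 2 == 1:
                    continue
            items.append((num if num is not None else 10**9, chrom, size))
        items.sort()
        bins = []
        for _, chrom, size in items:
            for start in range(0, size, bin_size):
                bins.append(GenomicBin(chrom, start, bin_size, min(bin_size, size - start)))
        return cls(bins)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


@dataclass
class InterContactMatrix:
    """Odd-by-even contact counts on a pair of bin grids."""

    row_grid: BinGrid
    col_grid: BinGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (len(self.row_grid), len(self.col_grid)):
            raise ValueError(
                f"counts shape {self.counts.shape} != grids "
                f"({len(self.row_grid)}, {len(self.col_grid)})"
            )
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and nonnegative")

    @property
    def coverage(self) -> float:
        """Total contact count (read pairs for raw integer input)."""
        return float(self.counts.sum())

    def covered_rows(self) -> np.ndarray:
        """Mask of rows with nonzero marginal (mappable/informative bins)."""
        return self.counts.sum(axis=1) > 0

    def covered_cols(self) -> np.ndarray:
        return self.counts.sum(axis=0) > 0


@dataclass
class ProbabilityMatrix:
    """Elementwise contact probabilities in [0, 1) on the same grids."""

    row_grid: BinGrid
    col_grid: BinGrid
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.row_grid), len(self.col_grid)):
            raise ValueError("probs shape does not match grids")
        if np.any(self.probs < 0) or np.any(self.probs >= 1):
            raise ValueError("probabilities must lie in [0, 1)")


# ----------------------------------------------------------------------
# construction and I/O


def _open_text(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    p = Path(source)
    if p.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(p, "rb"))
    return open(p)


def load_contacts(
    source: str | Path | TextIO | Iterable[str],
    row_grid: BinGrid,
    col_grid: BinGrid,
) -> InterContactMatrix:
    """Accumulate triplet text into a dense inter-chromosomal matrix.

    Accepts 5-column ``chrom_i start_i chrom_j start_j count`` or
    pre-indexed 3-column ``i j count`` lines (whitespace separated, ``#``
    comments allowed).  Duplicate cells are summed; unreferenced cells are
    zero.  Lines referencing a bin outside either grid, or carrying a
    negative count, are rejected with the offending line quoted.
    """
    if hasattr(source, "read") or isinstance(source, (str, Path)):
        handle = _open_text(source)  # type: ignore[arg-type]
        lines: Iterable[str] = handle
    else:
        lines = source
    counts = np.zeros((len(row_grid), len(col_grid)), dtype=np.float64)
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if len(parts) == 5:
                i = row_grid.position(parts[0], int(parts[1]))
                j = col_grid.position(parts[2], int(parts[3]))
                value = float(parts[4])
            elif len(parts) == 3:
                i, j = int(parts[0]), int(parts[1])
                if not (0 <= i < len(row_grid) and 0 <= j < len(col_grid)):
                    raise KeyError((i, j))
                value = float(parts[2])
            else:
                raise ValueError("expected 3 or 5 columns")
        except KeyError as exc:
            raise ValueError(f"line {lineno}: bin not on grid: {line!r}") from exc
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed triplet: {line!r}") from exc
        if value < 0:
            raise ValueError(f"line {lineno}: negative count: {line!r}")
        counts[i, j] += value
    return InterContactMatrix(row_grid, col_grid, counts)


def write_triplets(m: InterContactMatrix, path: str | Path) -> None:
    """Write nonzero cells as 5-column triplet text (round-trips load_contacts)."""
    rows, cols = np.nonzero(m.counts)
    with open(path, "w") as fh:
        for i, j in zip(rows, cols):
            rb, cb = m.row_grid.bins[i], m.col_grid.bins[j]
            v = m.counts[i, j]
            vs = f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"
            fh.write(f"{rb.chrom}\t{rb.start}\t{cb.chrom}\t{cb.start}\t{vs}\n")


def write_dense_tsv(m: InterContactMatrix | ProbabilityMatrix, path: str | Path) -> None:
    data = m.counts if isinstance(m, InterContactMatrix) else m.probs
    idx = [f"{b.chrom}:{b.start}" for b in m.row_grid.bins]
    cols = [f"{b.chrom}:{b.start}" for b in m.col_grid.bins]
    pd.DataFrame(data, index=idx, columns=cols).to_csv(path, sep="\t")


# ----------------------------------------------------------------------
# transforms


def downsample(m: InterContactMatrix, keep_rate: float, seed: int) -> InterContactMatrix:
    """Binomial thinning: each cell count C becomes Binomial(C, keep_rate).

    For integer counts this has the same marginal distribution as keeping
    each underlying read pair independently with probability ``keep_rate``
    — the standard coverage-titration device.  Non-integer counts are
    rounded before thinning.  Deterministic for a fixed seed.
    """
    if not 0.0 <= keep_rate <= 1.0:
        raise ValueError(f"keep_rate {keep_rate} outside [0, 1]")
    if keep_rate == 1.0:
        return InterContactMatrix(m.row_grid, m.col_grid, m.counts.copy())
    rng = np.random.default_rng(seed)
    ints = np.rint(m.counts).astype(np.int64)
    thinned = rng.binomial(ints, keep_rate).astype(np.float64)
    return InterContactMatrix(m.row_grid, m.col_grid, thinned)


def to_probability(m: InterContactMatrix) -> ProbabilityMatrix:
    """Contact-probability transform P = exp(-1/C), with P(0) = 0.

    Strictly increasing in C, bounded in [0, 1); extreme counts saturate
    toward 1 instead of dominating the loss.  Zero counts map to the
    analytic C→0+ limit, preserving sparsity (no pseudocount).
    """
    c = m.counts
    with np.errstate(divide="ignore"):
        p = np.where(c > 0, np.exp(-1.0 / np.where(c > 0, c, 1.0)), 0.0)
    return ProbabilityMatrix(m.row_grid, m.col_grid, p)


def transpose_view(m: InterContactMatrix) -> InterContactMatrix:
    """Swap rows and columns (and their grids); an involution."""
    return InterContactMatrix(m.col_grid, m.row_grid, m.counts.T.copy())
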