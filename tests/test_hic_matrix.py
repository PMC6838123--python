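"""Bin grids, triplet I/O, thinning, and the contact-probability transform."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicsub import hic_matrix as hm


class TestGrids:
    def test_parity_split_and_ordering(self):
        sizes = {"chr2": 250_000, "chr1": 200_000, "chr3": 100_000, "chrX": 300_000}
        odd = hm.BinGrid.from_chrom_sizes(sizes, "odd")
        even = hm.BinGrid.from_chrom_sizes(sizes, "even")
        assert odd.chroms == ["chr1", "chr3"]
        assert even.chroms == ["chr2"]
        assert [b.start for b in odd.bins] == [0, 100_000, 0]

    def test_terminal_partial_bin_is_kept_and_flagged(self):
        grid = hm.BinGrid.from_chrom_sizes({"chr1": 250_000})
        assert len(grid) == 3
        assert not grid.bins[0].truncated
        assert grid.bins[2].truncated and grid.bins[2].end == 250_000

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            hm.GenomicBin("chr1", 50_000)  # not on the 100 kb lattice
        with pytest.raises(ValueError):
            hm.GenomicBin("chr1", -100_000)


class TestLoadContacts:
    def test_empty_stream_gives_zero_matrix(self, grids_3x3):
        odd, even = grids_3x3
        m = hm.load_contacts(io.StringIO(""), odd, even)
        assert m.counts.shape == (3, 3)
        assert m.counts.sum() == 0

    def test_duplicate_triplets_are_summed(self, grids_3x3):
        odd, even = grids_3x3
        text = "chr1\t0\tchr2\t0\t2\nchr1\t0\tchr2\t0\t3\n"
        m = hm.load_contacts(io.StringIO(text), odd, even)
        assert m.counts[0, 0] == 5

    def test_matches_naive_accumulation_oracle(self, grids_3x3):
        odd, even = grids_3x3
        rng = np.random.default_rng(0)
        lines, cells = [], {}
        for _ in range(50):
            i, j = rng.integers(0, 3, 2)
            v = int(rng.integers(0, 9))
            cells[(i, j)] = cells.get((i, j), 0) + v
            lines.append(f"chr1\t{i*100_000}\tchr2\t{j*100_000}\t{v}")
        m = hm.load_contacts(iter(lines), odd, even)
        expected = np.zeros((3, 3))
        for (i, j), v in cells.items():
            expected[i, j] = v
        np.testing.assert_array_equal(m.counts, expected)

    def test_preindexed_three_column_form(self, grids_3x3):
        odd, even = grids_3x3
        m = hm.load_contacts(iter(["0 1 4", "2 2 7"]), odd, even)
        assert m.counts[0, 1] == 4 and m.counts[2, 2] == 7

    @pytest.mark.parametrize(
        "bad",
        ["chr5\t0\tchr2\t0\t1", "chr1\t900000\tchr2\t0\t1", "chr1\t0\tchr2\t0\t-3"],
    )
    def test_bad_lines_rejected_with_line_context(self, grids_3x3, bad):
        odd, even = grids_3x3
        with pytest.raises(ValueError, match="line 1"):
            hm.load_contacts(iter([bad]), odd, even)

    def test_triplet_round_trip(self, tmp_path, grids_3x3):
        odd, even = grids_3x3
        counts = np.random.default_rng(1).integers(0, 5, (3, 3)).astype(float)
        m = hm.InterContactMatrix(odd, even, counts)
        path = tmp_path / "trip.tsv"
        hm.write_triplets(m, path)
        back = hm.load_contacts(path, odd, even)
        np.testing.assert_array_equal(back.counts, counts)


class TestDownsample:
    def _matrix(self, grids):
        odd, even = grids
        counts = np.arange(9, dtype=float).reshape(3, 3)
        return hm.InterContactMatrix(odd, even, counts)

    def test_keep_all_is_identity(self, grids_3x3):
        m = self._matrix(grids_3x3)
        np.testing.assert_array_equal(hm.downsample(m, 1.0, 0).counts, m.counts)

    def test_keep_none_is_zero(self, grids_3x3):
        m = self._matrix(grids_3x3)
        assert hm.downsample(m, 0.0, 0).counts.sum() == 0

    def test_seed_determinism(self, grids_3x3):
        m = self._matrix(grids_3x3)
        a, b = hm.downsample(m, 0.3, 42), hm.downsample(m, 0.3, 42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_binomial_expectation(self, grids_3x3):
        odd, even = grids_3x3
        m = hm.InterContactMatrix(odd, even, np.full((3, 3), 50.0))
        total = m.counts.sum()
        rate = 0.1
        totals = [hm.downsample(m, rate, s).counts.sum() for s in range(200)]
        # mean of Binomial(T, r) totals is r*T with per-draw var T*r*(1-r)
        se = math.sqrt(total * rate * (1 - rate) / len(totals))
        assert abs(np.mean(totals) - rate * total) < 3 * se

    def test_sequential_thinning_composes_multiplicatively(self, grids_3x3):
        odd, even = grids_3x3
        m = hm.InterContactMatrix(odd, even, np.full((3, 3), 40.0))
        total = m.counts.sum()
        two_pass = [
            hm.downsample(hm.downsample(m, 0.5, s), 0.4, 1000 + s).counts.sum()
            for s in range(100)
        ]
        one_pass = [hm.downsample(m, 0.2, 2000 + s).counts.sum() for s in range(100)]
        se = math.sqrt(2 * total * 0.2 * 0.8 / 100)
        assert abs(np.mean(two_pass) - np.mean(one_pass)) < 3 * se

    def test_rate_out_of_range_rejected(self, grids_3x3):
        m = self._matrix(grids_3x3)
        with pytest.raises(ValueError):
            hm.downsample(m, 1.5, 0)


class TestProbabilityTransform:
    def test_known_values_and_monotonicity(self, grids_3x3):
        odd, even = grids_3x3
        m = hm.InterContactMatrix(odd, even, np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]], float))
        p = hm.to_probability(m).probs
        assert p[0, 0] == 0.0
        assert p[0, 1] == pytest.approx(math.exp(-1), abs=1e-12)
        flat = p.ravel()
        assert all(flat[i] < flat[i + 1] for i in range(len(flat) - 1))
        assert np.all((flat >= 0) & (flat < 1))

    def test_zero_count_maps_to_zero_exactly(self, grids_3x3):
        odd, even = grids_3x3
        counts = np.random.default_rng(0).integers(0, 3, (3, 3)).astype(float)
        p = hm.to_probability(hm.InterContactMatrix(odd, even, counts)).probs
        np.testing.assert_array_equal(p == 0, counts == 0)

    def test_negative_counts_rejected(self, grids_3x3):
        odd, even = grids_3x3
        with pytest.raises(ValueError):
            hm.InterContactMatrix(odd, even, np.full((3, 3), -1.0))


class TestTranspose:
    def test_shape_and_involution(self):
        odd = hm.BinGrid.from_chrom_sizes({"chr1": 200_000})
        even = hm.BinGrid.from_chrom_sizes({"chr2": 300_000})
        m = hm.InterContactMatrix(odd, even, np.arange(6, dtype=float).reshape(2, 3))
        t = hm.transpose_view(m)
        assert t.counts.shape == (3, 2)
        assert t.row_grid is even and t.col_grid is odd
        back = hm.transpose_view(t)
        np.testing.assert_array_equal(back.counts, m.counts)

    def test_matches_elementwise_swap_oracle(self, grids_3x3):
        odd, even = grids_3x3
        counts = np.random.default_rng(3).random((3, 3))
        t = hm.transpose_view(hm.InterContactMatrix(odd, even, counts))
        for i in range(3):
            for j in range(3):
                assert t.counts[j, i] == counts[i, j]


class TestTransformProperties:
    """Property-based checks of the count→probability map."""

    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=2, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_elementwise_range_and_order_preservation(self, counts):
        odd = hm.BinGrid.from_chrom_sizes({"chr1": 100_000})
        even = hm.BinGrid.from_chrom_sizes({"chr2": len(counts) * 100_000})
        arr = np.array(counts, dtype=float)[None, :]
        p = hm.to_probability(hm.InterContactMatrix(odd, even, arr)).probs[0]
        assert np.all((p >= 0) & (p < 1))
        order = np.argsort(arr[0], kind="stable")
        assert np.all(np.diff(p[order]) >= 0)  # monotone in the count
        np.testing.assert_array_equal(p == 0, arr[0] == 0)
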