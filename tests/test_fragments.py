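"""Fragment I/O, window/feature matrices, and interval arithmetic."""

import numpy as np
import pandas as pd
import pytest

from beigechrom.fragments import (
    FragmentFileError,
    FragmentSet,
    bin_matrix,
    feature_matrix,
    interval_overlap,
    read_fragments,
    write_fragments,
)


def _fragset(rows):
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode"]))


class TestIO:
    def test_roundtrip_identity(self, tmp_path, rng):
        n = 1000
        df = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], n),
            "start": rng.integers(0, 99_000, n),
            "barcode": rng.choice([f"BC{i}" for i in range(40)], n),
        })
        df["end"] = df["start"] + rng.integers(50, 400, n)
        fs = FragmentSet(df[["chrom", "start", "end", "barcode"]])
        path = tmp_path / "frags.tsv"
        write_fragments(fs, path)
        back = read_fragments(path)
        pd.testing.assert_frame_equal(fs.df, back.df)

    def test_gzip_roundtrip(self, tmp_path):
        fs = _fragset([("chr1", 0, 100, "A"), ("chr1", 50, 200, "B")])
        path = tmp_path / "frags.tsv.gz"
        write_fragments(fs, path)
        pd.testing.assert_frame_equal(read_fragments(path).df, fs.df)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_fragments(path)) == 0

    def test_bad_coordinates_name_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t100\t50\tA\n")
        with pytest.raises(FragmentFileError, match="line 1"):
            read_fragments(path)

    def test_unsorted_policy(self, tmp_path):
        path = tmp_path / "unsorted.tsv"
        path.write_text("chr1\t500\t600\tA\nchr1\t100\t200\tB\n")
        assert read_fragments(path, on_unsorted="sort").df["start"].is_monotonic_increasing
        with pytest.raises(FragmentFileError, match="not sorted"):
            read_fragments(path, on_unsorted="error")

    def test_duplicates_collapsed(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("chr1\t100\t200\tA\nchr1\t100\t200\tA\n")
        assert len(read_fragments(path)) == 1


class TestBinMatrix:
    def test_fragment_spanning_two_windows(self):
        fs = _fragset([("chr1", 9_990, 10_010, "A")])
        fm = bin_matrix(fs, {"chr1": 30_000}, width=10_000)
        row = np.asarray(fm.matrix.todense())[0]
        assert list(fm.feature_ids[row > 0]) == ["chr1:0-10000", "chr1:10000-20000"]

    def test_blacklisted_window_absent(self):
        fs = _fragset([("chr1", 100, 200, "A")])
        bl = pd.DataFrame([("chr1", 25_000, 26_000)], columns=["chrom", "start", "end"])
        fm = bin_matrix(fs, {"chr1": 40_000}, width=10_000, blacklist=bl)
        assert "chr1:20000-30000" not in fm.feature_ids
        assert fm.matrix.shape[1] == 3

    def test_column_sums_match_bruteforce(self, small_cohort):
        genome, _, frags, _ = small_cohort
        sub = frags.subset_barcodes(frags.barcodes[:5])
        fm = bin_matrix(sub, genome.chrom_lengths, width=10_000)
        width = 10_000
        for bi, bc in enumerate(fm.barcodes):
            rows = sub.df[sub.df["barcode"] == bc]
            wins = set()
            for r in rows.itertuples():
                for w in range(r.start // width, (r.end - 1) // width + 1):
                    wins.add((r.chrom, w))
            assert fm.matrix[bi].sum() == len(wins)

    def test_binary_entries_and_totals(self, small_cohort):
        genome, _, frags, ct = small_cohort
        fm = bin_matrix(frags, genome.chrom_lengths, width=10_000)
        assert set(np.unique(fm.matrix.data)) == {1.0}
        # totals cache the pre-binarisation window hits, >= distinct windows
        sums = np.asarray(fm.matrix.sum(axis=1)).ravel()
        assert (fm.totals >= sums).all()


class TestFeatureMatrix:
    def test_strand_aware_upstream_extension(self):
        frags = _fragset([
            ("chr1", 3_500, 3_600, "A"),  # in plus-gene upstream only
            ("chr1", 7_000, 7_100, "B"),  # in minus-gene upstream only
        ])
        genes = pd.DataFrame({
            "name": ["plus", "minus"],
            "chrom": ["chr1", "chr1"],
            "start": [5_000, 5_000],
            "end": [6_000, 6_000],
            "strand": ["+", "-"],
        })
        fm = feature_matrix(frags, genes, mode="genes")
        dense = np.asarray(fm.matrix.todense())
        a, b = list(fm.barcodes).index("A"), list(fm.barcodes).index("B")
        p, m = list(fm.feature_ids).index("plus"), list(fm.feature_ids).index("minus")
        assert dense[a, p] == 1 and dense[a, m] == 0
        assert dense[b, m] == 1 and dense[b, p] == 0

    def test_extension_clipped_at_chromosome_start(self):
        frags = _fragset([("chr1", 10, 60, "A")])
        genes = pd.DataFrame({
            "name": ["g"], "chrom": ["chr1"], "start": [500], "end": [900],
            "strand": ["+"],
        })
        fm = feature_matrix(frags, genes, mode="genes")
        assert fm.matrix.sum() == 1  # upstream clipped to [0, 900)

    def test_counts_match_quadratic_oracle(self, small_cohort):
        genome, truth, frags, _ = small_cohort
        sub = frags.subset_barcodes(frags.barcodes[:8])
        fm = feature_matrix(sub, truth.peaks)
        dense = np.asarray(fm.matrix.todense())
        bidx = {b: i for i, b in enumerate(fm.barcodes)}
        expected = np.zeros_like(dense)
        for r in sub.df.itertuples():
            for j, p in enumerate(truth.peaks.itertuples()):
                if r.chrom == p.chrom and r.start < p.end and p.start < r.end:
                    expected[bidx[r.barcode], j] += 1
        assert np.array_equal(dense, expected)

    def test_monotone_in_fragments(self, small_cohort):
        genome, truth, frags, _ = small_cohort
        sub = frags.subset_barcodes(frags.barcodes[:4])
        full = np.asarray(feature_matrix(sub, truth.peaks).matrix.todense())
        half = FragmentSet(sub.df.iloc[: len(sub.df) // 2])
        part = feature_matrix(half, truth.peaks)
        partial = np.zeros_like(full)
        rows = [list(feature_matrix(sub, truth.peaks).barcodes).index(b) for b in part.barcodes]
        partial[rows] = np.asarray(part.matrix.todense())
        assert (full >= partial).all()


class TestIntervalOverlap:
    @pytest.mark.parametrize("b_start,b_end,expected", [
        (10, 20, False),  # bookended half-open intervals do not overlap
        (9, 20, True),
        (0, 1, True),
    ])
    def test_half_open_semantics(self, b_start, b_end, expected):
        a = pd.DataFrame([("chr1", 0, 10)], columns=["chrom", "start", "end"])
        b = pd.DataFrame([("chr1", b_start, b_end)], columns=["chrom", "start", "end"])
        hit, _ = interval_overlap(a, b)
        assert hit[0] == expected

    def test_matches_quadratic_oracle(self, rng):
        def random_set(n):
            start = rng.integers(0, 10_000, n)
            return pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], n),
                "start": start,
                "end": start + rng.integers(1, 500, n),
            })

        a, b = random_set(200), random_set(200)
        hit, hits = interval_overlap(a, b)
        for i, ra in enumerate(a.itertuples()):
            expected = sorted(
                j for j, rb in enumerate(b.itertuples())
                if ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end
            )
            assert hits[i] == expected
            assert hit[i] == bool(expected)
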