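"""PWM scanning, chromVAR deviations, enrichment, modules, footprints."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beigechrom.fragments import FeatureMatrix, FragmentSet, feature_matrix
from beigechrom.motifs import (
    DeviationMatrix,
    Motif,
    MotifSet,
    chromvar_deviations,
    encode_sequence,
    footprint,
    motif_enrichment,
    motifset_from_consensus,
    raw_deviations,
    read_jaspar,
    scan_motifs,
    score_threshold,
    tf_modules,
)
from beigechrom.synthetic import DEFAULT_MOTIF_CONSENSUS, GenomeModel

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _toy_genome(seqs: dict[str, str]) -> GenomeModel:
    return GenomeModel(
        list(seqs), {c: len(s) for c, s in seqs.items()}, dict(seqs),
        pd.DataFrame(columns=["chrom", "start", "end"]),
    )


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestScan:
    def test_consensus_and_reverse_complement_match(self, rng):
        cons = "TGACCTTGACCT"
        ms = motifset_from_consensus({"M": cons})
        rc = "".join(COMP[b] for b in reversed(cons))
        bg = _random_seq(rng, 200)
        genome = _toy_genome({
            "chr1": bg[:50] + cons + bg[50:],
            "chr2": bg[100:150] + rc + bg[150:],
            "chr3": _random_seq(rng, 100),
        })
        peaks = pd.DataFrame({
            "chrom": ["chr1", "chr2", "chr3"],
            "start": [30, 30, 20],
            "end": [90, 90, 80],
        })
        match, gc = scan_motifs(peaks, genome, ms)
        assert match[0, 0] and match[0, 1]
        assert not match[0, 2]
        assert gc == pytest.approx([
            _gc(genome.fetch(c, s, e)) for c, s, e in peaks.itertuples(index=False)
        ])

    def test_matches_equal_exhaustive_rescoring_oracle(self, rng):
        ms = motifset_from_consensus(
            {k: DEFAULT_MOTIF_CONSENSUS[k] for k in list(DEFAULT_MOTIF_CONSENSUS)[:3]})
        genome = _toy_genome({"chr1": _random_seq(rng, 20_000)})
        starts = rng.integers(0, 19_000, 50)
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 300})
        bg = np.full(4, 0.25)
        match, _ = scan_motifs(peaks, genome, ms, background=bg)
        for mi, motif in enumerate(ms.motifs):
            lodds = motif.log_odds(bg)
            thr = score_threshold(lodds, bg)
            for pi, r in enumerate(peaks.itertuples()):
                seq = genome.fetch("chr1", r.start, r.end)
                best = -np.inf
                for s in (seq, "".join(COMP[b] for b in reversed(seq))):
                    code = encode_sequence(s)
                    for off in range(len(code) - motif.width + 1):
                        best = max(best, lodds[code[off:off + motif.width],
                                               np.arange(motif.width)].sum())
                assert bool(match[mi, pi]) == (best >= thr)

    def test_threshold_calibrates_false_positive_rate(self, rng):
        """Per-position match rate on random background sequence
        approximates the PWM p-value (smooth PWM, quasi-continuous score
        distribution)."""
        ms = motifset_from_consensus({"M": "TGACGTCATGAC"}, confidence=0.6)
        bg = np.full(4, 0.25)
        lodds = ms.motifs[0].log_odds(bg)
        thr = score_threshold(lodds, bg, pvalue=5e-5)
        n, width = 2_000_000, 12
        code = rng.integers(0, 4, n)
        win = np.lib.stride_tricks.sliding_window_view(code, width)
        scores = lodds[win, np.arange(width)].sum(axis=1)
        rate = (scores >= thr).mean()
        assert 5e-6 < rate <= 1e-4  # at most the target rate, same order

    def test_short_peak_never_matches(self, rng):
        ms = motifset_from_consensus({"M": "TGACCTTGACCT"})
        genome = _toy_genome({"chr1": _random_seq(rng, 100)})
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [6]})
        match, _ = scan_motifs(peaks, genome, ms)
        assert not match.any()


def _gc(seq):
    return (seq.count("G") + seq.count("C")) / len(seq)


def test_jaspar_reader_and_ppm_invariants(tmp_path):
    path = tmp_path / "motifs.jaspar"
    path.write_text(
        ">MA0001.1 TOY\n"
        "A [ 10  0  2 ]\n"
        "C [  0 12  2 ]\n"
        "G [  1  0  6 ]\n"
        "T [  1  0  2 ]\n"
    )
    ms = read_jaspar(path)
    assert len(ms) == 1
    ppm = ms.motifs[0].ppm
    np.testing.assert_allclose(ppm.sum(axis=0), 1.0, atol=1e-9)
    assert ppm[0, 0] == pytest.approx(10 / 12)


class TestChromVar:
    def _toy(self, rng, n_cells=20, n_peaks=100):
        X = rng.poisson(1.5, (n_cells, n_peaks)).astype(float)
        fm = FeatureMatrix(X, np.array([f"C{i}" for i in range(n_cells)]),
                           np.array([f"P{j}" for j in range(n_peaks)]))
        match = rng.random((5, n_peaks)) < 0.2
        match[:, 0] = True  # every motif has at least one peak
        gc = rng.uniform(0.3, 0.6, n_peaks)
        return fm, match, gc

    def test_raw_deviations_equal_double_loop_oracle(self, rng):
        fm, match, gc = self._toy(rng)
        raw = raw_deviations(fm, match)
        X = np.asarray(fm.matrix.todense())
        T, f = fm.totals, X.sum(axis=0) / X.sum()
        for j in range(match.shape[0]):
            for i in range(fm.n_cells):
                o = (X[i] * match[j]).sum()
                e = T[i] * (match[j] * f).sum()
                assert raw[j, i] == pytest.approx((o - e) / e, rel=1e-10)

    def test_proportional_cell_has_zero_deviation(self, rng):
        X = rng.poisson(2.0, (10, 40)).astype(float) + 1
        f_rest = X[1:].sum(axis=0)
        # proportional to the other cells' totals => proportional to the
        # final column totals as well
        X[0] = 3 * f_rest / f_rest.sum() * 100
        fm = FeatureMatrix(X, np.array([f"C{i}" for i in range(10)]), np.arange(40))
        match = rng.random((3, 40)) < 0.3
        raw = raw_deviations(fm, match)
        assert np.allclose(raw[:, 0], 0.0, atol=1e-10)

    def test_z_scores_and_variability_shapes(self, rng):
        fm, match, gc = self._toy(rng)
        dev = chromvar_deviations(fm, match, gc, n_background=20, seed=0)
        assert dev.z.shape[1] == fm.n_cells
        assert (dev.variability >= 0).all()

    def test_background_reproducible_and_stable(self, rng):
        fm, match, gc = self._toy(rng, n_cells=30)
        d1 = chromvar_deviations(fm, match, gc, n_background=100, seed=5)
        d2 = chromvar_deviations(fm, match, gc, n_background=100, seed=5)
        pd.testing.assert_frame_equal(d1.z, d2.z)
        d3 = chromvar_deviations(fm, match, gc, n_background=100, seed=6)
        rms = np.sqrt(np.nanmean((d1.z.to_numpy() - d3.z.to_numpy()) ** 2))
        assert rms < 0.2

    def test_null_z_mean_near_zero(self, rng):
        X = rng.poisson(2.0, (500, 60)).astype(float)
        fm = FeatureMatrix(X, np.array([f"C{i}" for i in range(500)]), np.arange(60))
        match = rng.random((4, 60)) < 0.25
        gc = rng.uniform(0.3, 0.6, 60)
        dev = chromvar_deviations(fm, match, gc, n_background=30, seed=0)
        assert np.nanmean(np.abs(np.nanmean(dev.z.to_numpy(), axis=1))) < 0.1

    def test_unmatched_motif_dropped(self, rng):
        fm, match, gc = self._toy(rng)
        match[2] = False
        dev = chromvar_deviations(fm, match, gc,
                                  motif_names=[f"M{i}" for i in range(5)],
                                  n_background=10, seed=0)
        assert "M2" not in dev.z.index


def test_planted_beige_motif_separates_cell_types_and_ranks_variable():
    """The motif planted in beige-specific peaks gets higher deviation
    z-scores in beige than in white cells, and its variability ranks in
    the top 3 across motifs on a balanced cohort."""
    from beigechrom.synthetic import SampleSpec, make_genome, make_truth, simulate_atac

    rng = np.random.default_rng(7)
    genome = make_genome(rng)
    types = ["white_adipocyte", "beige_adipocyte", "macrophage", "tcell"]
    truth = make_truth(genome, rng, cell_types=types)
    props = {t: 0.25 for t in types}
    design = [SampleSpec(f"s{r}", "RT", 0, r, 150, props) for r in (1, 2, 3)]
    _, _, frags, ct = simulate_atac(design=design, genome=genome, truth=truth,
                                    depth_lognormal=(7.0, 0.6), seed=7)
    ms = motifset_from_consensus(DEFAULT_MOTIF_CONSENSUS)
    match, gc = scan_motifs(truth.peaks, genome, ms)
    pm = feature_matrix(frags, truth.peaks)
    dev = chromvar_deviations(pm, match, gc, ms.names, n_background=30, seed=0)
    ctm = ct.set_index("barcode").loc[pm.barcodes]
    zb = dev.z.loc["M_BEIGE"]
    beige = (ctm["true_type"] == "beige_adipocyte").to_numpy()
    white = (ctm["true_type"] == "white_adipocyte").to_numpy()
    assert zb[beige].mean() > zb[white].mean() + 1.0
    top3 = dev.variability.nlargest(3).index
    assert "M_BEIGE" in top3


class TestEnrichment:
    def test_identical_sets_have_unit_fold(self, rng):
        match = rng.random((4, 60)) < 0.3
        idx = np.arange(30)
        table = motif_enrichment(idx, idx, match)
        assert np.allclose(table["fold"], 1.0)

    def test_extreme_enrichment_matches_hypergeom_tail(self):
        match = np.zeros((1, 40), bool)
        match[0, :20] = True  # all foreground, no background
        table = motif_enrichment(np.arange(20), np.arange(20, 40), match)
        expected = stats.hypergeom.sf(19, 40, 20, 20)
        assert table["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_direction_reversal_inverts_fold(self, rng):
        match = rng.random((5, 80)) < 0.4
        fg, bg = np.arange(40), np.arange(40, 80)
        t1 = motif_enrichment(fg, bg, match).set_index("motif")
        t2 = motif_enrichment(bg, fg, match).set_index("motif")
        np.testing.assert_allclose(t1["fold"], 1.0 / t2["fold"], rtol=1e-9)


class TestModules:
    def _block_dev(self, rng, n_cells=60):
        base = rng.normal(size=(3, n_cells)) * 3
        rows, names = [], []
        for b in range(3):
            for i in range(4):
                rows.append(base[b] + rng.normal(0, 0.1, n_cells))
                names.append(f"M{b}_{i}")
        z = pd.DataFrame(rows, index=names)
        variability = z.std(axis=1, ddof=1)
        return DeviationMatrix(z.copy(), z, variability)

    def test_identical_rows_share_a_module(self, rng):
        dev = self._block_dev(rng)
        modules, corr = tf_modules(dev, var_min=0.5, n_modules=3)
        assert modules["M0_0"] == modules["M0_1"]
        assert corr.loc["M0_0", "M0_1"] > 0.99

    def test_planted_blocks_recovered_exactly(self, rng):
        from sklearn.metrics import adjusted_rand_score

        dev = self._block_dev(rng)
        modules, _ = tf_modules(dev, var_min=0.5, n_modules=3)
        truth = [name.split("_")[0] for name in modules.index]
        assert adjusted_rand_score(truth, modules.to_numpy()) == 1.0

    def test_threshold_above_all_variability_raises(self, rng):
        dev = self._block_dev(rng)
        with pytest.raises(ValueError, match="variability"):
            tf_modules(dev, var_min=1e6)


class TestFootprint:
    def _uniform_genome_frags(self, rng, L=200_000, n=40_000):
        genome = _toy_genome({"chr1": _random_seq(rng, L)})
        starts = rng.integers(0, L - 200, n)
        frags = FragmentSet(pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + 150,
            "barcode": "A",
        }))
        return genome, frags

    def test_uniform_insertions_give_flat_corrected_profile(self, rng):
        genome, frags = self._uniform_genome_frags(rng)
        sites = pd.DataFrame({"chrom": "chr1",
                              "center": rng.integers(1_000, 199_000, 200)})
        prof = footprint(frags, sites, genome)
        flank = prof[np.abs(prof["position"]) > 200]["corrected"]
        centre = prof[np.abs(prof["position"]) <= 10]["corrected"]
        assert abs(centre.mean()) < 3 * flank.std()

    def test_planted_protection_dips_at_centre(self, rng):
        genome, frags = self._uniform_genome_frags(rng, n=60_000)
        centers = rng.integers(2_000, 198_000, 150)
        protected = set()
        for c in centers:
            protected.update(range(c - 10, c + 11))
        keep = []
        ins_drop = rng.random(len(frags.df))
        for i, r in enumerate(frags.df.itertuples()):
            # halve insertion probability within +/-10 bp of site centres
            if (r.start in protected or (r.end - 1) in protected) and ins_drop[i] < 0.5:
                continue
            keep.append(i)
        thinned = FragmentSet(frags.df.iloc[keep])
        sites = pd.DataFrame({"chrom": "chr1", "center": centers})
        prof = footprint(thinned, sites, genome)
        min_pos = prof.loc[prof["corrected"].idxmin(), "position"]
        assert abs(min_pos) <= 10

    def test_depth_invariance_after_scaling(self, rng):
        genome, frags = self._uniform_genome_frags(rng)
        double = FragmentSet(pd.concat([frags.df, frags.df.assign(barcode="B")]))
        sites = pd.DataFrame({"chrom": "chr1",
                              "center": rng.integers(1_000, 199_000, 100)})
        p1 = footprint(frags, sites, genome)
        p2 = footprint(double, sites, genome)
        np.testing.assert_allclose(p2["observed"], 2 * p1["observed"], rtol=1e-9)
        np.testing.assert_allclose(p2["corrected"], 2 * p1["corrected"], atol=1e-9)

    def test_sites_at_chromosome_edge_skipped(self, rng):
        genome, frags = self._uniform_genome_frags(rng)
        sites = pd.DataFrame({"chrom": "chr1", "center": [10, 100_000]})
        prof = footprint(frags, sites, genome)
        assert np.isfinite(prof["observed"]).all()
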