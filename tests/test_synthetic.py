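"""Ground-truth properties of the synthetic cohort and lipid generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beigechrom import synthetic
from beigechrom.lipids import SpeciesFormatError
from beigechrom.synthetic import (
    BASE_PROPORTIONS,
    ConfigurationError,
    SampleSpec,
    default_design,
    simulate_atac,
    simulate_lipids,
)


def _mini_design(n=60, n_samples=2):
    return [
        SampleSpec(f"s{i}", "RT", 0, i, n, dict(BASE_PROPORTIONS))
        for i in range(1, n_samples + 1)
    ]


class TestSimulateAtac:
    def test_zero_collision_rate_means_no_collisions(self):
        _, _, _, ct = simulate_atac(_mini_design(), depth_lognormal=(5.0, 0.5),
                                    collision_rate=0.0, seed=0)
        assert not ct["is_collision"].any()

    def test_same_seed_is_byte_identical(self):
        _, _, f1, ct1 = simulate_atac(_mini_design(), depth_lognormal=(5.0, 0.5),
                                      collision_rate=0.1, seed=7)
        _, _, f2, ct2 = simulate_atac(_mini_design(), depth_lognormal=(5.0, 0.5),
                                      collision_rate=0.1, seed=7)
        pd.testing.assert_frame_equal(f1.df, f2.df)
        pd.testing.assert_frame_equal(ct1, ct2)

    def test_total_fragments_equal_sum_of_depths(self):
        _, _, frags, ct = simulate_atac(_mini_design(), depth_lognormal=(5.0, 0.5),
                                        collision_rate=0.1, seed=3)
        assert len(frags) == ct["n_fragments"].sum()

    def test_collisions_have_two_distinct_same_sample_parents(self):
        _, _, _, ct = simulate_atac(_mini_design(), depth_lognormal=(5.0, 0.5),
                                    collision_rate=0.2, seed=3)
        coll = ct[ct["is_collision"]]
        assert len(coll) == pytest.approx(0.2 * 120, abs=2)
        for r in coll.itertuples():
            a, b = r.parent_barcodes.split("|")
            assert a != b

    def test_beige_fraction_within_binomial_ci(self):
        """Realised beige proportions fall in the exact binomial 95% CI of
        the design targets (1% at day 0, 5% at day 7)."""
        n = 600
        design = []
        for day, frac in ((0, 0.01), (7, 0.05)):
            props = dict(BASE_PROPORTIONS)
            props["beige_adipocyte"] = frac
            props["white_adipocyte"] -= frac - 0.01
            design.append(SampleSpec(f"d{day}", "cold" if day else "RT", day, 1, n, props))
        _, _, _, ct = simulate_atac(design, depth_lognormal=(4.0, 0.3), seed=1)
        for day, frac in ((0, 0.01), (7, 0.05)):
            k = int(((ct["day"] == day) & (ct["true_type"] == "beige_adipocyte")).sum())
            lo, hi = stats.binom.interval(0.95, n, frac)
            assert lo <= k <= hi

    def test_in_peak_fraction_matches_analytic_mixture(self, small_cohort):
        genome, truth, frags, ct = small_cohort
        bc = ct.loc[ct["true_type"] == "macrophage", "barcode"].head(60)
        sub = frags.subset_barcodes(bc)
        merged = truth.peaks[["chrom", "start", "end"]]
        starts = {c: g["start"].to_numpy() for c, g in merged.groupby("chrom")}
        ends = {c: g["end"].to_numpy() for c, g in merged.groupby("chrom")}
        inpeak = 0
        for r in sub.df.itertuples():
            i = np.searchsorted(starts[r.chrom], r.end) - 1
            if i >= 0 and ends[r.chrom][i] > r.start:
                inpeak += 1
        act = truth.activity.loc["macrophage"].mean()
        peak_bp = (merged["end"] - merged["start"]).sum() / genome.total_length
        expected = act + (1 - act) * peak_bp
        assert inpeak / len(sub.df) == pytest.approx(expected, abs=0.02)

    def test_unknown_cell_type_raises(self):
        bad = [SampleSpec("s", "RT", 0, 1, 10, {"unicorn": 1.0})]
        with pytest.raises(ConfigurationError, match="unknown cell types"):
            simulate_atac(bad, seed=0)

    def test_collision_rate_bounds(self):
        with pytest.raises(ConfigurationError):
            simulate_atac(_mini_design(), collision_rate=0.6, seed=0)


class TestGenomeAndTruth:
    def test_genome_invariants(self, small_cohort):
        genome, truth, _, _ = small_cohort
        for chrom in genome.chrom_names:
            assert len(genome.sequence[chrom]) == genome.chrom_lengths[chrom]
        for r in genome.blacklist.itertuples():
            assert 0 <= r.start < r.end <= genome.chrom_lengths[r.chrom]
        act = truth.activity.to_numpy()
        assert act.min() >= 0 and act.max() <= 1

    def test_peaks_spaced_and_fixed_width(self, small_cohort):
        _, truth, _, _ = small_cohort
        peaks = truth.peaks
        assert ((peaks["end"] - peaks["start"]) == 500).all()
        for _, grp in peaks.groupby("chrom"):
            gaps = grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1]
            assert (gaps >= 4_000).all()  # >= min_gap minus jitter

    def test_planted_motif_consensus_in_sequence(self, small_cohort):
        genome, truth, _, _ = small_cohort
        planted = truth.peaks[truth.peaks["motif"] != ""].head(10)
        for r in planted.itertuples():
            seq = genome.fetch(r.chrom, r.start, r.end)
            assert synthetic.DEFAULT_MOTIF_CONSENSUS[r.motif] in seq


class TestSimulateLipids:
    def test_noise_free_zero_slope_equals_base(self, lipid_design):
        base = {"16:0": 30.0, "16:1n-7": 10.0, "18:0": 10.0,
                "18:1n-7": 5.0, "18:1n-9": 25.0, "18:2n-6": 20.0}
        table = simulate_lipids(lipid_design, base, noise_sd=0.0, seed=0)
        for sp, val in base.items():
            assert np.allclose(table.values[sp], val)

    def test_rows_sum_to_100(self, lipid_design):
        base = {"16:0": 40.0, "16:1n-7": 10.0, "18:0": 10.0,
                "18:1n-7": 10.0, "18:1n-9": 30.0}
        table = simulate_lipids(lipid_design, base, noise_sd=2.0, seed=1)
        assert np.allclose(table.values.sum(axis=1), 100.0, atol=1e-9)

    def test_bad_species_name_rejected(self, lipid_design):
        with pytest.raises(SpeciesFormatError):
            simulate_lipids(lipid_design, {"oleic": 100.0}, seed=0)

    def test_base_must_sum_to_100(self, lipid_design):
        with pytest.raises(ConfigurationError):
            simulate_lipids(lipid_design, {"16:0": 50.0}, seed=0)

    def test_planted_slope_sign_recovered_by_ols(self, lipid_design):
        """A planted positive oleic-acid slope under CL is recovered in sign
        by the slope comparison (OLS on the noise-free table as oracle)."""
        from beigechrom.lipids import slope_compare

        base = {"16:0": 30.0, "16:1n-7": 10.0, "18:0": 10.0,
                "18:1n-7": 5.0, "18:1n-9": 25.0, "18:2n-6": 20.0}
        slopes = {"CL": {"18:1n-9": 1.0, "16:0": -1.0}}
        table = simulate_lipids(lipid_design, base, slopes, noise_sd=0.0, seed=0)
        res = slope_compare(table.values["18:1n-9"], lipid_design)
        assert res["slope_CL"] > 0
        assert res["slope_CL"] > res["slope_cold"]


def test_default_design_matches_study_layout():
    design = default_design(n_cells_per_sample=100)
    assert len(design) == 21  # 7 groups x 3 replicates
    days = sorted({(s.condition, s.day) for s in design})
    assert ("RT", 0) in days and ("cold", 7) in days and ("CL", 7) in days
    for s in design:
        assert sum(s.proportions.values()) == pytest.approx(1.0)
    d7 = [s for s in design if s.day == 7 and s.condition == "cold"][0]
    assert d7.proportions["beige_adipocyte"] == pytest.approx(0.05)
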