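"""Ground-truth benchmarks: every pipeline stage scored on synthetic
cohorts with known truth.

Each function simulates the relevant study condition (composition, depth,
planted effects), runs the corresponding pipeline stage end-to-end, and
scores it against the planted truth. The functions are consumed by the
acceptance script and the acceptance tests; all randomness derives from
the seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import synthetic
from .abundance import milo_da
from .embedding import knn_graph, tfidf_lsi
from .fragments import feature_matrix, interval_overlap
from .lipids import fa_indices, group_tests
from .motifs import raw_deviations
from .peaks import call_cluster_peaks, merge_peaks
from .pipeline import two_pass_cluster
from .qc import detect_doublets
from .synthetic import BASE_PROPORTIONS, SampleSpec, simulate_atac


def _sub(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def doublet_benchmark(seed: int = 1, n_per_sample: int = 700) -> dict:
    """Collision detection on a balanced 8-type cohort with 8% collisions.

    Study depth (log-normal mu 8, sigma 0.6); equal type proportions keep
    the same-type collision share (undetectable in principle) near 12%.
    """
    types = synthetic.DEFAULT_CELL_TYPES
    props = {t: 1.0 / len(types) for t in types}
    design = [SampleSpec(f"s{r}", "RT", 0, r, n_per_sample, props) for r in (1, 2, 3)]
    _, truth, frags, ct = simulate_atac(
        design=design, depth_lognormal=(8.0, 0.6), collision_rate=0.08,
        seed=_sub(seed, 1),
    )
    pm = feature_matrix(frags, truth.peaks)
    scores = detect_doublets(pm, k=30, cutoff=0.2, seed=_sub(seed, 2))
    truth_flags = ct.set_index("barcode").loc[scores.index, "is_collision"].to_numpy()
    flagged = scores["flagged"].to_numpy()
    tp = int((flagged & truth_flags).sum())
    return {
        "precision": tp / max(int(flagged.sum()), 1),
        "recall": tp / int(truth_flags.sum()),
        "n_cells": len(scores),
        "planted": int(truth_flags.sum()),
    }


def peak_benchmark(seed: int = 1, n_per_sample: int = 60) -> dict:
    """Per-cluster peak calling scored against planted peaks (q <= 0.05)."""
    design = synthetic.default_design(n_cells_per_sample=n_per_sample)
    genome, truth, frags, ct = simulate_atac(
        design=design, depth_lognormal=(8.0, 0.6), seed=_sub(seed, 3))
    ctm = ct.set_index("barcode")
    label_of = dict(zip(ctm.index, pd.Categorical(ctm["true_type"]).codes))
    sets = call_cluster_peaks(frags, label_of, genome.chrom_lengths, q_max=0.05)
    merged = merge_peaks(list(sets.values()), genome.chrom_lengths,
                         blacklist=genome.blacklist)
    called = merged.intervals
    planted = truth.peaks[["chrom", "start", "end"]]
    hit_called, _ = interval_overlap(called, planted)
    hit_planted, _ = interval_overlap(planted, called)
    bl_hit, _ = interval_overlap(planted, genome.blacklist)
    return {
        "precision": float(hit_called.mean()),
        "recall": float(hit_planted[~bl_hit].mean()),
        "n_called": len(called),
        "n_planted": int((~bl_hit).sum()),
    }


def chromvar_oracle_benchmark(seed: int = 1) -> dict:
    """Raw deviations vs an independent double-loop oracle (20 x 100)."""
    rng = np.random.default_rng(_sub(seed, 4))
    X = rng.poisson(1.5, (20, 100)).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    from .fragments import FeatureMatrix

    fm = FeatureMatrix(X, np.array([f"C{i}" for i in range(20)]),
                       np.array([f"P{j}" for j in range(100)]))
    match = rng.random((8, 100)) < 0.15
    match[:, 0] = True
    raw = raw_deviations(fm, match)
    T, f = fm.totals, X.sum(axis=0) / X.sum()
    max_rel = 0.0
    for j in range(match.shape[0]):
        for i in range(20):
            o = float((X[i] * match[j]).sum())
            e = float(T[i] * (match[j] * f).sum())
            expected = (o - e) / e
            denom = max(abs(expected), 1e-300)
            max_rel = max(max_rel, abs(raw[j, i] - expected) / denom)
    return {"max_relative_error": max_rel}


def clustering_benchmark(seed: int = 1, n_per_sample: int = 100) -> dict:
    """Two-pass window->peak clustering vs planted cell types (ARI)."""
    design = synthetic.default_design(n_cells_per_sample=n_per_sample)
    genome, truth, frags, ct = simulate_atac(
        design=design, depth_lognormal=(7.0, 0.6), seed=_sub(seed, 5))
    result = two_pass_cluster(frags, genome, seed=0)
    ctm = ct.set_index("barcode").loc[result.peak_matrix.barcodes]
    ari = adjusted_rand_score(ctm["true_type"], result.clusters.labels)
    return {
        "ari": float(ari),
        "n_clusters": result.clusters.n_clusters,
    }


def beige_expansion_benchmark(seed: int = 1, n_per_sample: int = 2_000) -> dict:
    """Realised beige percentages at day 0 and day 7 under cold exposure
    (design targets 1% and 5%), measured on a large draw."""
    design = [s for s in synthetic.default_design(n_cells_per_sample=n_per_sample)
              if (s.day, s.condition) in ((0, "RT"), (7, "cold"))]
    _, _, _, ct = simulate_atac(design=design, depth_lognormal=(3.0, 0.4),
                                seed=_sub(seed, 12))
    beige = ct["true_type"] == "beige_adipocyte"
    day0 = float(beige[ct["day"] == 0].mean())
    day7 = float(beige[ct["day"] == 7].mean())
    return {
        "beige_percent_day0": 100 * day0,
        "beige_percent_day7_cold": 100 * day7,
        "n_per_group": 3 * n_per_sample,
    }


def _milo_cohort(beige7: float, seed: int, n_per_sample: int, k: int):
    props0 = dict(BASE_PROPORTIONS)
    design = [SampleSpec(f"d0r{r}", "RT", 0, r, n_per_sample, props0)
              for r in (1, 2, 3)]
    props7 = dict(BASE_PROPORTIONS)
    props7["beige_adipocyte"] = beige7
    props7["white_adipocyte"] -= beige7 - props0["beige_adipocyte"]
    design += [SampleSpec(f"d7r{r}", "cold", 7, r, n_per_sample, props7)
               for r in (1, 2, 3)]
    _, truth, frags, ct = simulate_atac(
        design=design, depth_lognormal=(7.0, 0.6), seed=seed)
    pm = feature_matrix(frags, truth.peaks)
    emb = tfidf_lsi(pm, n_components=15, variable_fraction=1.0)
    X = emb.matrix()
    idx, dist = knn_graph(X, k)
    ctm = ct.set_index("barcode").loc[pm.barcodes]
    meta = pd.DataFrame({"sample": ctm["sample"].to_numpy(),
                         "condition": ctm["condition"].to_numpy()})
    return X, idx, dist, meta, ctm


def milo_benchmark(seed: int = 1, n_planted: int = 800, n_null: int = 250,
                   n_null_seeds: int = 20, k: int = 40) -> dict:
    """Neighbourhood DA: planted 1%->5% beige expansion and a no-effect
    null, both at spatial FDR 10% with 3 replicates per condition."""
    X, idx, dist, meta, ctm = _milo_cohort(0.05, _sub(seed, 6), n_planted, k)
    ns = milo_da(idx, dist, X, meta, contrast=("RT", "cold"), seed=_sub(seed, 7))
    beige_nh = ns.annotate((ctm["true_type"] == "beige_adipocyte").to_numpy()).to_numpy()
    called = (ns.stats["significant"] & (ns.stats["logFC"] > 0)).to_numpy()
    detection = float(called[beige_nh].mean()) if beige_nh.sum() else float("nan")
    rates = []
    for s in range(n_null_seeds):
        Xn, idxn, distn, metan, _ = _milo_cohort(
            BASE_PROPORTIONS["beige_adipocyte"], _sub(seed, 100 + s), n_null, k)
        nsn = milo_da(idxn, distn, Xn, metan, contrast=("RT", "cold"),
                      seed=_sub(seed, 200 + s))
        rates.append(float(nsn.stats["significant"].mean()))
    return {
        "beige_detection_rate": detection,
        "n_beige_neighbourhoods": int(beige_nh.sum()),
        "null_call_rate": float(np.mean(rates)),
        "n_null_seeds": n_null_seeds,
    }


def pseudotime_benchmark(seed: int = 1, n_cells: int = 400, n_null_tf: int = 1000) -> dict:
    """Pseudotime vs a planted linear ordering, plus the TF gene-motif
    correlation null pass rate."""
    from .embedding import ClusterAssignment
    from .trajectory import fit_backbone, tf_gene_motif_correlation

    rng = np.random.default_rng(_sub(seed, 8))
    x = np.sort(rng.uniform(0, 10, n_cells))
    X = np.column_stack([x, rng.normal(0, 0.3, n_cells)])
    asg = ClusterAssignment((x > 5).astype(int), 0.0)
    bcs = np.array([f"c{i:05d}" for i in range(n_cells)])
    traj = fit_backbone(X, asg, [0, 1], bcs)
    rho = stats.spearmanr(traj.pseudotime.loc[bcs], x).statistic

    nb = 100
    kernel = np.ones(11) / 11

    def smooth(arr):
        pad = np.pad(arr, ((0, 0), (5, 5)), mode="edge")
        return np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), 1, pad)

    genes = pd.DataFrame(smooth(rng.normal(size=(n_null_tf, nb))),
                         index=[f"g{i}" for i in range(n_null_tf)])
    motifs = pd.DataFrame(smooth(rng.normal(size=(n_null_tf, nb))),
                          index=[f"m{i}" for i in range(n_null_tf)])
    tab = tf_gene_motif_correlation(
        genes, motifs, {f"t{i}": (f"g{i}", f"m{i}") for i in range(n_null_tf)})
    return {
        "spearman": float(rho),
        "tf_null_pass_rate": float(tab["positive_regulator"].mean()),
    }


def coaccess_benchmark(seed: int = 1, n_cells: int = 6_000) -> dict:
    """AUC of co-accessibility scores for planted vs independent pairs."""
    from .coaccess import coaccessibility

    fm, pairs = synthetic.simulate_coaccess_cells(n_cells=n_cells, seed=_sub(seed, 9))
    emb = tfidf_lsi(fm, n_components=20, variable_fraction=1.0)
    links = coaccessibility(fm, emb, k_agg=50, seed=_sub(seed, 10))
    key = set(map(tuple, pairs.to_numpy()))
    labels = np.array([(a, b) in key for a, b in zip(links["peak_a"], links["peak_b"])])
    return {
        "auc": float(roc_auc_score(labels, links["score"])),
        "n_planted_scored": int(labels.sum()),
        "n_links": len(links),
    }


LIPID_BASE = {"16:0": 20.0, "16:1n-7": 5.0, "18:0": 4.0, "18:1n-7": 2.0,
              "18:1n-9": 40.0, "18:2n-6": 29.0}


def lipid_benchmark(seed: int = 1) -> dict:
    """Formula fixtures plus the opposite-UFA:SFA-slope interaction test."""
    fixture = pd.DataFrame([LIPID_BASE], index=["fixture"])
    from .lipids import LipidTable

    idx = fa_indices(LipidTable(fixture))
    groups = pd.DataFrame(
        [(f"{c}{d}r{r}", c, d, r)
         for c in ("cold", "CL") for d in (1, 3, 7) for r in (1, 2, 3)]
        + [(f"RT0r{r}", "RT", 0, r) for r in (1, 2, 3)],
        columns=["sample", "condition", "day", "replicate"])
    slopes = {"cold": {"18:2n-6": 1.0, "16:0": -1.0},
              "CL": {"18:2n-6": -1.0, "16:0": 1.0}}
    table = synthetic.simulate_lipids(groups, LIPID_BASE, slopes,
                                      noise_sd=0.2, seed=_sub(seed, 11))
    res = group_tests(table)
    ufa = res["slopes"]["UFA_SFA"]
    return {
        "elongation_ratio": float(idx["elongation"].iloc[0]),
        "desaturation_ratio": float(idx["desaturation"].iloc[0]),
        "ufa_sfa_slope_cold": ufa["slope_cold"],
        "ufa_sfa_slope_cl": ufa["slope_CL"],
        "ufa_sfa_interaction_p": ufa["interaction_p"],
    }
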