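"""Metacell aggregation and distance-penalised co-accessibility links.

Single cells are too sparse for peak-peak correlation, so cells are
aggregated into metacells (sums over a seed cell's k nearest neighbours,
seeds chosen greedily so accepted metacells share under 10% of members).
Within sliding genomic windows, a graphical-lasso style estimator with an
element-wise penalty growing linearly with inter-peak distance yields a
sparse precision matrix; the co-accessibility score of a peak pair is the
negated normalised precision entry (the partial correlation), clipped to
[-1, 1]. Long-range pairs are penalised toward exactly zero, mirroring the
distance decay of chromatin contacts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .embedding import Embedding, knn_graph
from .fragments import FeatureMatrix

logger = logging.getLogger(__name__)


def make_metacells(
    emb: Embedding,
    fm: FeatureMatrix,
    k_agg: int = 50,
    max_share: float = 0.1,
    seed: int = 0,
):
    """Greedy low-overlap metacells: sums over seed cells' kNN balls.

    Returns ``(counts, totals, members)`` where counts is metacells x peaks.
    """
    if fm.n_cells < k_agg:
        raise ValueError(f"need at least k_agg={k_agg} cells")
    X = emb.matrix()
    idx, _ = knn_graph(X, k_agg - 1)
    balls = [frozenset([i, *idx[i]]) for i in range(fm.n_cells)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(fm.n_cells)
    accepted: list[int] = []
    member_sets: list[frozenset] = []
    limit = max_share * k_agg
    for i in order:
        if all(len(balls[i] & m) < limit for m in member_sets):
            accepted.append(i)
            member_sets.append(balls[i])
    members = [np.fromiter(m, dtype=int) for m in member_sets]
    counts = np.vstack([
        np.asarray(fm.matrix[m].sum(axis=0)).ravel() for m in members
    ])
    totals = np.array([fm.totals[m].sum() for m in members], dtype=float)
    return counts, totals, members


def _normalise(counts: np.ndarray, totals: np.ndarray, scale: float = 1e4) -> np.ndarray:
    tot = np.where(totals > 0, totals, 1.0)
    return np.log1p(scale * counts / tot[:, None])


def _penalised_precision(S: np.ndarray, penalty: np.ndarray,
                         max_iter: int = 200, tol: float = 1e-5) -> np.ndarray:
    """Element-wise L1-penalised precision matrix by proximal gradient.

    Minimises tr(S Theta) - logdet Theta + sum penalty_ij |theta_ij| over
    positive-definite Theta (diagonal unpenalised), with backtracking to
    keep iterates positive definite.
    """
    p = S.shape[0]
    ridge = 1e-3 * np.trace(S) / p
    S = S + ridge * np.eye(p)
    theta = np.linalg.inv(S)
    step = 1.0 / max(np.linalg.eigvalsh(S).max() ** 2, 1e-8)
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        t = step
        for _ in range(30):
            cand = theta - t * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - t * penalty, 0.0)
            np.fill_diagonal(cand, np.diag(theta - t * grad))
            try:
                np.linalg.cholesky(cand)
                break
            except np.linalg.LinAlgError:
                t *= 0.5
        else:
            break
        delta = np.abs(cand - theta).max()
        theta = cand
        if delta < tol:
            break
    return theta


def coaccessibility(
    fm: FeatureMatrix,
    emb: Embedding,
    k_agg: int = 50,
    window: int = 500_000,
    alpha: float = 0.5,
    d_floor: int = 10_000,
    base_penalty: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-penalised co-accessibility links between peaks.

    Requires ``fm.features`` to carry peak intervals. Windows slide by
    window/2; a pair scored in several windows gets the mean score. Returns
    a DataFrame (peak_a, peak_b, chrom, distance, score) with peak_a <
    peak_b row indices into ``fm.features``.
    """
    if fm.features is None:
        raise ValueError("feature matrix must carry peak intervals")
    counts, totals, _ = make_metacells(emb, fm, k_agg=k_agg, seed=seed)
    norm = _normalise(counts, totals)
    feats = fm.features.reset_index(drop=True)
    mid = ((feats["start"] + feats["end"]) // 2).to_numpy()
    scores: dict[tuple[int, int], list[float]] = {}
    for chrom in feats["chrom"].unique():
        cix = np.flatnonzero((feats["chrom"] == chrom).to_numpy())
        if len(cix) < 2:
            continue
        cmid = mid[cix]
        lo, hi = cmid.min(), cmid.max()
        starts = np.arange(lo, hi + 1, window // 2)
        for w0 in starts:
            inw = cix[(cmid >= w0) & (cmid < w0 + window)]
            if len(inw) < 2:
                continue
            Y = norm[:, inw]
            sd = Y.std(axis=0)
            ok = sd > 0
            inw = inw[ok]
            if len(inw) < 2:
                continue
            Y = (Y[:, ok] - Y[:, ok].mean(axis=0)) / sd[ok]
            S = (Y.T @ Y) / max(Y.shape[0] - 1, 1)
            d = np.abs(mid[inw][:, None] - mid[inw][None, :]).astype(float)
            # base sparsity penalty on every pair plus a linear distance
            # ramp beyond the floor
            penalty = base_penalty + alpha * np.maximum(0.0, d - d_floor) / window
            np.fill_diagonal(penalty, 0.0)
            theta = _penalised_precision(S, penalty)
            dd = np.sqrt(np.abs(np.diag(theta)))
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = -theta / np.outer(dd, dd)
            rho = np.clip(rho, -1.0, 1.0)
            for a in range(len(inw)):
                for b in range(a + 1, len(inw)):
                    key = (int(inw[a]), int(inw[b]))
                    scores.setdefault(key, []).append(float(rho[a, b]))
    rows = [
        (a, b, feats.at[a, "chrom"], int(abs(mid[b] - mid[a])), float(np.mean(v)))
        for (a, b), v in sorted(scores.items())
    ]
    return pd.DataFrame(rows, columns=["peak_a", "peak_b", "chrom", "distance", "score"])


def link_genes(
    links: pd.DataFrame,
    gene_models: pd.DataFrame,
    peak_intervals: pd.DataFrame,
    score_min: float = 0.2,
    promoter_flank: int = 1_000,
) -> dict[str, list[int]]:
    """Promoter-enhancer linkage: map genes to distal linked peaks.

    Promoters are TSS +/- ``promoter_flank`` (strand-aware). A distal peak
    (one not overlapping any gene body) is linked to a gene when a
    co-accessibility link with score >= ``score_min`` joins it directly to a
    peak overlapping the gene's promoter.
    """
    from .fragments import interval_overlap

    peaks = peak_intervals.reset_index(drop=True)
    genes = gene_models.reset_index(drop=True)
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    promoters = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": np.maximum(tss - promoter_flank, 0),
        "end": tss + promoter_flank,
    })
    _, prom_hits = interval_overlap(promoters, peaks[["chrom", "start", "end"]])
    body_hit, _ = interval_overlap(peaks[["chrom", "start", "end"]],
                                   genes[["chrom", "start", "end"]])
    distal = ~body_hit
    good = links[links["score"] >= score_min]
    neighbours: dict[int, set[int]] = {}
    for r in good.itertuples():
        neighbours.setdefault(int(r.peak_a), set()).add(int(r.peak_b))
        neighbours.setdefault(int(r.peak_b), set()).add(int(r.peak_a))
    out: dict[str, list[int]] = {}
    for gi, prom_peaks in enumerate(prom_hits):
        gene = genes.at[gi, "name"] if "name" in genes.columns else genes.at[gi, "gene"]
        linked: set[int] = set()
        for pp in prom_peaks:
            for q in neighbours.get(pp, ()):  # direct links only
                if distal[q]:
                    linked.add(q)
        if linked:
            out[str(gene)] = sorted(linked)
    return out
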