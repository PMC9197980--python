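"""Backbone-constrained pseudotime and feature dynamics along it.

Pseudotime follows the cluster-backbone recipe: the user supplies an
ordered list of clusters (e.g. the cluster richest in day-0 cells first,
the cluster richest in day-7 cells last); cells are ordered within each
cluster by their position between the neighbouring clusters' centroids,
and within-cluster ranks are mapped onto equal consecutive pseudotime
spans so the full trajectory covers [0, 100].

The within-cluster ordering key is d(x, previous centroid) - d(x, next
centroid) (terms for missing neighbours dropped), which reduces to
"decreasing distance to the next centroid" at the ends of the backbone and
makes backbone reversal map pseudotime t to exactly 100 - t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .embedding import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Per-cell pseudotime in [0, 100] over an ordered cluster backbone."""

    pseudotime: pd.Series  # indexed by barcode; backbone cells only
    backbone: list[int]
    cluster_of_cell: pd.Series

    def __len__(self) -> int:
        return len(self.pseudotime)


def fit_backbone(
    X: np.ndarray,
    assignment: ClusterAssignment,
    backbone: list[int],
    barcodes: np.ndarray,
) -> Trajectory:
    """Order cells along an ordered cluster backbone.

    Cells outside the backbone clusters are excluded. Ties in the ordering
    key break deterministically by barcode.
    """
    labels = assignment.labels
    present = set(np.unique(labels).tolist())
    unknown = [c for c in backbone if c not in present]
    if unknown:
        raise ValueError(f"backbone references unknown clusters {unknown}")
    for c in backbone:
        if (labels == c).sum() == 0:
            raise ValueError(f"backbone cluster {c} is empty")
    X = np.asarray(X, dtype=float)
    barcodes = np.asarray(barcodes)
    K = len(backbone)
    centroids = {c: X[labels == c].mean(axis=0) for c in backbone}
    times: dict[str, float] = {}
    clusters: dict[str, int] = {}
    for k, c in enumerate(backbone):
        cells = np.flatnonzero(labels == c)
        key = np.zeros(len(cells))
        if K > 1:
            if k > 0:
                key += np.linalg.norm(X[cells] - centroids[backbone[k - 1]], axis=1)
            if k < K - 1:
                key -= np.linalg.norm(X[cells] - centroids[backbone[k + 1]], axis=1)
        else:
            key = np.linalg.norm(X[cells] - centroids[c], axis=1)
        order = np.lexsort((barcodes[cells], key))
        n = len(cells)
        lo, hi = 100.0 * k / K, 100.0 * (k + 1) / K
        for rank, ci in enumerate(order):
            t = lo + (hi - lo) * (rank / (n - 1) if n > 1 else 0.5)
            bc = str(barcodes[cells[ci]])
            times[bc] = t
            clusters[bc] = c
    pt = pd.Series(times, name="pseudotime").sort_values(kind="mergesort")
    return Trajectory(pt, list(backbone), pd.Series(clusters))


def pseudotime_features(
    values: pd.DataFrame,
    traj: Trajectory,
    n_bins: int = 100,
    smooth_window: int = 11,
) -> pd.DataFrame:
    """Smoothed per-feature profiles over pseudotime bins.

    ``values`` is features x cells (columns are barcodes). Cells are binned
    by pseudotime quantile, per-bin means are smoothed with a centred
    moving average, and rows are ordered by the smoothed profile's argmax
    bin. Empty bins are filled by linear interpolation (logged). Constant
    features are kept (flat profile) but sort last.
    """
    if n_bins < smooth_window:
        raise ValueError("n_bins must be >= smooth_window")
    cells = [c for c in traj.pseudotime.index if c in values.columns]
    pt = traj.pseudotime.loc[cells]
    ranks = stats.rankdata(pt.to_numpy(), method="ordinal") - 1
    bins = (ranks * n_bins // len(cells)).astype(int)
    V = values[cells].to_numpy(dtype=float)
    prof = np.full((V.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            prof[:, b] = V[:, mask].mean(axis=1)
    empty = np.isnan(prof[0])
    if empty.any():
        logger.info("interpolating %d empty pseudotime bins", int(empty.sum()))
        xs = np.flatnonzero(~empty)
        for i in range(prof.shape[0]):
            prof[i, empty] = np.interp(np.flatnonzero(empty), xs, prof[i, xs])
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    padded = np.pad(prof, ((0, 0), (pad, pad)), mode="edge")
    smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, padded)
    out = pd.DataFrame(smooth, index=values.index, columns=range(n_bins))
    argmax = out.to_numpy().argmax(axis=1)
    spread = np.ptp(out.to_numpy(), axis=1)
    order = np.lexsort((argmax, spread == 0))  # constants last
    return out.iloc[order]


def tf_gene_motif_correlation(
    gene_profiles: pd.DataFrame,
    motif_profiles: pd.DataFrame,
    tf_map: dict[str, tuple[str, str]],
    r_min: float = 0.5,
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """Correlate TF gene-accessibility and motif-deviation pseudotime
    profiles.

    ``tf_map`` maps TF name -> (gene id, motif id) into the two profile
    tables (rows = features, columns = pseudotime bins). Positive
    regulators pass with Pearson r >= ``r_min`` and BH-adjusted p <
    ``p_adj_max``. TFs with a missing gene or motif are skipped (reported).
    """
    rows, skipped = [], []
    for tf, (gene, motif) in tf_map.items():
        if gene not in gene_profiles.index or motif not in motif_profiles.index:
            skipped.append(tf)
            continue
        g = gene_profiles.loc[gene].to_numpy(dtype=float)
        m = motif_profiles.loc[motif].to_numpy(dtype=float)
        if g.std() == 0 or m.std() == 0:
            skipped.append(tf)
            continue
        r, p = stats.pearsonr(g, m)
        rows.append((tf, gene, motif, float(r), float(p)))
    if skipped:
        logger.info("skipped TFs with missing gene/motif or constant profile: %s", skipped)
    df = pd.DataFrame(rows, columns=["tf", "gene", "motif", "r", "p"])
    if len(df):
        _, df["p_adj"], _, _ = multipletests(df["p"], method="fdr_bh")
        df["positive_regulator"] = (df["r"] >= r_min) & (df["p_adj"] < p_adj_max)
    else:
        df["p_adj"] = []
        df["positive_regulator"] = []
    return df
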