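"""Differential accessibility: marker tests, threshold selection, and the
lipogenic/glycolytic panel fold-change statistics.

Counts are depth-normalised as ln(1 + 1e4 * x / cell_total) before testing.
The per-feature test is a two-sided Wilcoxon rank-sum (asymptotic normal
approximation with tie correction and continuity correction); log2
fold-changes compare group means of the normalised values with a 1e-4
pseudocount, positive meaning higher accessibility in the first group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragments import FeatureMatrix

logger = logging.getLogger(__name__)

# Metabolic gene panels used for the time-course fold-change comparisons.
PANELS = {
    "lipogenic": ["Acaca", "Acacb", "Acly", "Acss2", "Fasn", "Scd1", "Elovl6"],
    "glycolytic": ["Hk1", "Gpi1", "Pfkl", "Pfkp", "Gapdh", "Pgk1", "Pgm1",
                   "Eno1", "Pkm", "Ldha"],
}

EPS = 1e-4


@dataclass
class MarkerTable:
    """Per-feature differential accessibility results (group1 vs group2)."""

    df: pd.DataFrame  # feature, log2fc, p, p_adj, frac_a, frac_b

    def __len__(self) -> int:
        return len(self.df)


def _rows_for(fm: FeatureMatrix, barcodes) -> np.ndarray:
    index = {b: i for i, b in enumerate(fm.barcodes)}
    return np.array([index[b] for b in barcodes], dtype=int)


def find_markers(
    fm: FeatureMatrix,
    cells_a,
    cells_b,
    adjust: str = "bonferroni",
) -> MarkerTable:
    """Wilcoxon rank-sum differential accessibility between two cell groups.

    Groups must be disjoint with at least 3 cells each. Features absent in
    both groups are skipped (logged). ``adjust`` is ``"bonferroni"`` or
    ``"bh"``; the correction runs over the tested features only.
    """
    if set(cells_a) & set(cells_b):
        raise ValueError("marker groups must be disjoint")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    norm = fm.normalized()
    ra, rb = _rows_for(fm, cells_a), _rows_for(fm, cells_b)
    A = np.asarray(norm[ra].todense())
    B = np.asarray(norm[rb].todense())
    present = (A.sum(axis=0) > 0) | (B.sum(axis=0) > 0)
    n_skip = int((~present).sum())
    if n_skip:
        logger.info("skipping %d features absent in both groups", n_skip)
    Ak, Bk = A[:, present], B[:, present]
    res = stats.mannwhitneyu(Ak, Bk, alternative="two-sided",
                             method="asymptotic", axis=0)
    pvals = np.atleast_1d(res.pvalue)
    log2fc = np.log2((Ak.mean(axis=0) + EPS) / (Bk.mean(axis=0) + EPS))
    if adjust == "bonferroni":
        p_adj = np.minimum(1.0, pvals * Ak.shape[1])
    elif adjust == "bh":
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    df = pd.DataFrame({
        "feature": fm.feature_ids[present],
        "log2fc": log2fc,
        "p": pvals,
        "p_adj": p_adj,
        "frac_a": (Ak > 0).mean(axis=0),
        "frac_b": (Bk > 0).mean(axis=0),
    })
    return MarkerTable(df)


def threshold_select(table: MarkerTable, p_adj_max: float = 0.05,
                     abs_lfc_min: float = 1.2, sign: int = 0) -> pd.DataFrame:
    """Features with p_adj strictly below and |log2FC| strictly above the
    thresholds; ``sign`` +1/-1 additionally restricts the fold-change
    direction (+1 = higher in group1)."""
    if p_adj_max <= 0 or abs_lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    df = table.df
    keep = (df["p_adj"] < p_adj_max) & (df["log2fc"].abs() > abs_lfc_min)
    if sign > 0:
        keep &= df["log2fc"] > 0
    elif sign < 0:
        keep &= df["log2fc"] < 0
    return df.loc[keep].reset_index(drop=True)


def panel_foldchange_test(
    gene_fm: FeatureMatrix,
    panel: list[str],
    metadata: pd.DataFrame,
    baseline: tuple[str, int] = ("RT", 0),
) -> dict:
    """Per-cell panel-average accessibility fold-changes vs the baseline
    group, plus Welch's t-test between cold and CL cells at matched days.

    ``metadata`` needs one row per barcode with columns barcode, condition,
    day. Each cell's score is its mean normalised accessibility over the
    panel genes divided by the baseline-group mean of that score.
    """
    ids = list(gene_fm.feature_ids)
    missing = [g for g in panel if g not in ids]
    if missing:
        raise ValueError(f"panel genes missing from matrix: {missing}")
    cols = np.array([ids.index(g) for g in panel])
    norm = gene_fm.normalized()
    score = np.asarray(norm[:, cols].mean(axis=1)).ravel()
    meta = metadata.set_index("barcode").loc[list(gene_fm.barcodes)]
    base_mask = (meta["condition"].to_numpy() == baseline[0]) & (
        meta["day"].to_numpy() == baseline[1])
    if not base_mask.any():
        raise ValueError("baseline group is empty")
    base_mean = float(score[base_mask].mean())
    if base_mean == 0:
        raise ValueError("baseline group has zero mean panel accessibility")
    fc = score / base_mean
    cells = pd.DataFrame({
        "barcode": gene_fm.barcodes,
        "condition": meta["condition"].to_numpy(),
        "day": meta["day"].to_numpy(),
        "fold_change": fc,
    })
    rows = []
    for day in sorted(cells.loc[cells["condition"] != baseline[0], "day"].unique()):
        a = cells.loc[(cells["condition"] == "cold") & (cells["day"] == day), "fold_change"]
        b = cells.loc[(cells["condition"] == "CL") & (cells["day"] == day), "fold_change"]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((day, float(t), float(p)))
    return {
        "cells": cells,
        "welch": pd.DataFrame(rows, columns=["day", "t", "p"]),
        "baseline_mean": base_mean,
    }
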