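"""Differential abundance: cluster proportions and KNN-neighbourhood tests.

Two complementary views of composition change. The cluster-level test
compares per-replicate cell-type proportions across the seven treatment
groups with one-way ANOVA and Bonferroni correction (post-hoc vs day 0).
The neighbourhood-level test works on the KNN graph directly: index cells
are sampled and refined toward neighbourhood medoids, each index cell's
k-ball becomes a neighbourhood, per-sample cell counts are modelled with a
negative-binomial GLM (log link, log sample size offset, condition
covariate), and multiplicity is controlled with a spatial FDR — a weighted
Benjamini-Hochberg procedure whose weights are inverse kth-neighbour
distances, down-weighting neighbourhoods in dense regions that carry many
overlapping tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .embedding import ClusterAssignment
from .lipids import anova_bonferroni

logger = logging.getLogger(__name__)


def cluster_proportion_test(
    assignment: ClusterAssignment,
    metadata: pd.DataFrame,
    cluster_names: dict[int, str] | None = None,
):
    """Per-cluster per-sample proportions with ANOVA across groups.

    ``metadata`` has one row per cell (aligned with ``assignment.labels``)
    with columns sample, condition, day, replicate. Returns ``(proportions,
    anova, posthoc)``: the samples x clusters proportion table (rows sum to
    1), per-cluster ANOVA with Bonferroni over clusters, and pairwise
    comparisons vs the day-0 group (Bonferroni within cluster).
    """
    meta = metadata.reset_index(drop=True)
    if (meta.groupby("sample").size() == 0).any():
        raise ValueError("empty sample")
    df = pd.DataFrame({"sample": meta["sample"], "cluster": assignment.labels})
    counts = df.groupby(["sample", "cluster"]).size().unstack(fill_value=0)
    props = counts.div(counts.sum(axis=1), axis=0)
    if cluster_names:
        props = props.rename(columns=cluster_names)
    sample_meta = meta.drop_duplicates("sample")[
        ["sample", "condition", "day", "replicate"]
    ]
    anova, posthoc = anova_bonferroni(props, sample_meta)
    return props, anova, posthoc


@dataclass
class NeighborhoodSet:
    """KNN neighbourhoods with per-sample counts and DA statistics."""

    index_cells: np.ndarray
    members: list[np.ndarray]
    counts: pd.DataFrame  # neighbourhoods x samples
    weights: np.ndarray  # spatial weights (1 / kth-NN distance)
    stats: pd.DataFrame  # logFC, p, spatial_fdr per neighbourhood

    def __len__(self) -> int:
        return len(self.index_cells)

    def annotate(self, labels: np.ndarray) -> pd.Series:
        """Majority cell label per neighbourhood (for beeswarm grouping)."""
        majority = []
        for m in self.members:
            vals, cnt = np.unique(np.asarray(labels)[m], return_counts=True)
            majority.append(vals[np.argmax(cnt)])
        return pd.Series(majority, index=self.stats.index, name="majority")


def sample_index_cells(
    knn_idx: np.ndarray,
    X: np.ndarray,
    prop: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sampling-refinement: random cells swapped toward their
    neighbourhood's most central member, then de-duplicated."""
    n = X.shape[0]
    n_pick = max(1, int(round(prop * n)))
    picked = rng.choice(n, size=n_pick, replace=False)
    refined = []
    for i in picked:
        members = np.concatenate([[i], knn_idx[i]])
        centre = X[members].mean(axis=0)
        d = np.linalg.norm(X[members] - centre, axis=1)
        refined.append(int(members[np.argmin(d)]))
    return np.unique(refined)


def _fit_dispersion(y: np.ndarray, design: np.ndarray, offset: np.ndarray) -> float:
    """Per-neighbourhood NB dispersion (alpha) by maximum likelihood."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, design, offset=offset)
            fit = model.fit(disp=0, maxiter=200)
            alpha = float(fit.params[-1])
        except Exception:
            alpha = 0.0
    return max(alpha, 1e-8)


def milo_da(
    knn_idx: np.ndarray,
    knn_dist: np.ndarray,
    X: np.ndarray,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    prop: float = 0.1,
    fdr_max: float = 0.1,
    seed: int = 0,
    shrink: float = 0.5,
) -> NeighborhoodSet:
    """KNN-neighbourhood differential abundance between two conditions.

    ``metadata`` has one row per cell (columns sample, condition) aligned
    with the rows of ``knn_idx``/``X``; ``contrast = (reference, alternative)``
    — positive log fold-changes mean more abundant under the alternative.
    Dispersion is estimated per neighbourhood by ML (floored at 1e-8) and
    shrunk halfway toward the global mean before the final GLM fit; Wald
    p-values use a t reference with (samples - 2) degrees of freedom to
    respect the few-replicates design. Significance is spatial FDR <
    ``fdr_max``.
    """
    from scipy import stats as sps

    ref, alt = contrast
    meta = metadata.reset_index(drop=True)
    keep_cond = meta["condition"].isin([ref, alt])
    samples = sorted(meta.loc[keep_cond, "sample"].unique())
    cond_of = meta.drop_duplicates("sample").set_index("sample")["condition"]
    for c in (ref, alt):
        if (cond_of.loc[samples] == c).sum() < 2:
            raise ValueError(f"need >= 2 samples for condition {c!r}")
    rng = np.random.default_rng(seed)
    index_cells = sample_index_cells(knn_idx, X, prop, rng)
    members = [np.concatenate([[i], knn_idx[i]]) for i in index_cells]
    sample_codes = pd.Categorical(meta["sample"], categories=samples).codes
    counts = np.zeros((len(index_cells), len(samples)), dtype=int)
    for ni, m in enumerate(members):
        codes = sample_codes[m]
        codes = codes[codes >= 0]
        np.add.at(counts[ni], codes, 1)
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        logger.warning("dropping %d all-zero neighbourhoods", int((~keep).sum()))
    index_cells = index_cells[keep]
    members = [m for m, k in zip(members, keep) if k]
    counts = counts[keep]
    kth = knn_dist[index_cells, -1]
    weights = 1.0 / np.maximum(kth, 1e-12)

    totals = np.array([
        int((sample_codes == s).sum()) for s in range(len(samples))
    ], dtype=float)
    offset = np.log(totals)
    x_cond = (cond_of.loc[samples] == alt).to_numpy().astype(float)
    design = np.column_stack([np.ones(len(samples)), x_cond])

    alphas = np.array([_fit_dispersion(y, design, offset) for y in counts])
    global_alpha = float(alphas.mean())
    logfc, pvals = [], []
    df_resid = len(samples) - design.shape[1]
    null_design = design[:, :1]
    for y, a in zip(counts, alphas):
        a_shr = shrink * a + (1 - shrink) * global_alpha
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.NegativeBinomial(alpha=a_shr)
                full = sm.GLM(y, design, offset=offset, family=fam).fit()
                null = sm.GLM(y, null_design, offset=offset, family=fam).fit()
            beta = float(full.params[1])
            lr = max(0.0, 2.0 * (full.llf - null.llf))
        except Exception:
            beta, lr = 0.0, 0.0
        logfc.append(beta / np.log(2))
        # likelihood-ratio test; robust where Wald collapses under
        # separation (zero counts in one condition)
        pvals.append(float(sps.chi2.sf(lr, 1)))
    pvals = np.array(pvals)
    spatial = weighted_bh(pvals, weights)
    stats_df = pd.DataFrame({
        "index_cell": index_cells,
        "logFC": logfc,
        "p": pvals,
        "spatial_fdr": spatial,
        "significant": spatial < fdr_max,
    })
    counts_df = pd.DataFrame(counts, columns=samples)
    return NeighborhoodSet(index_cells, members, counts_df, weights, stats_df)


def weighted_bh(pvals: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted Benjamini-Hochberg adjustment (spatial FDR).

    With weights w, the adjusted value for the i-th ordered p is
    min over j >= i of p_(j) * sum(w) / cumsum(w)_(j), capped at 1; equal
    weights recover ordinary BH.
    """
    pvals = np.asarray(pvals, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(pvals, kind="mergesort")
    cumw = np.cumsum(weights[order])
    raw = pvals[order] * weights.sum() / cumw
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty_like(pvals)
    out[order] = np.minimum(adj, 1.0)
    return out
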