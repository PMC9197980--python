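"""Ligand-receptor interaction inference between cell clusters.

Interaction probability for (sender s, receiver r, pair) is the product of
the ligand's mean normalised accessibility in the sender cluster and the
receptor's in the receiver (multi-subunit receptors contribute the
geometric mean of their subunit means) — a monotone proxy for signalling
capacity from chromatin accessibility. Significance comes from a cluster
label permutation null: p = (1 + #{permuted probability >= observed}) /
(1 + n_permutations).
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd

from .fragments import FeatureMatrix

logger = logging.getLogger(__name__)

# Miniature VEGF-like toy pathway for tests and examples.
TOY_LR_TABLE = pd.read_csv(io.StringIO(
    "ligand,receptor_subunits,pathway\n"
    "Vegfa,Flt1,VEGF\n"
    "Vegfa,Kdr,VEGF\n"
    "Vegfb,Flt1,VEGF\n"
    "Vegfc,Kdr+Nrp2,VEGF\n"
))


def read_lr_table(path) -> pd.DataFrame:
    """Read a ligand-receptor CSV (ligand, receptor_subunits, pathway);
    multi-subunit receptors join gene ids with '+'."""
    df = pd.read_csv(path)
    required = {"ligand", "receptor_subunits", "pathway"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ligand-receptor table missing columns {sorted(missing)}")
    return df


def _cluster_means(norm, labels: np.ndarray, cluster_ids: list[int]) -> np.ndarray:
    out = np.zeros((len(cluster_ids), norm.shape[1]))
    for i, c in enumerate(cluster_ids):
        rows = np.flatnonzero(labels == c)
        out[i] = np.asarray(norm[rows].mean(axis=0)).ravel()
    return out


def lr_permutation_test(
    gene_fm: FeatureMatrix,
    labels: np.ndarray,
    pairs: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    min_cells: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sender x receiver x pair interaction probabilities with permutation p.

    Clusters smaller than ``min_cells`` are excluded (logged); pairs whose
    ligand or any receptor subunit is absent from the gene matrix are
    skipped (reported). Returns a long DataFrame with columns sender,
    receiver, ligand, receptor, pathway, probability, p, significant.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    labels = np.asarray(labels)
    ids = {g: i for i, g in enumerate(gene_fm.feature_ids)}
    uniq, counts = np.unique(labels, return_counts=True)
    clusters = [int(c) for c, n in zip(uniq, counts) if n >= min_cells]
    dropped = [int(c) for c, n in zip(uniq, counts) if n < min_cells]
    if dropped:
        logger.warning("excluding clusters with < %d cells: %s", min_cells, dropped)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters of sufficient size")
    usable = []
    for r in pairs.itertuples():
        subunits = str(r.receptor_subunits).split("+")
        if r.ligand in ids and all(s in ids for s in subunits):
            usable.append((r.ligand, subunits, r.pathway))
        else:
            logger.info("skipping pair %s -> %s (unresolved gene)", r.ligand, r.receptor_subunits)
    norm = gene_fm.normalized()
    keep_cells = np.isin(labels, clusters)
    norm = norm[np.flatnonzero(keep_cells)]
    labels = labels[keep_cells]

    def probabilities(lbl: np.ndarray) -> np.ndarray:
        means = _cluster_means(norm, lbl, clusters)
        out = np.zeros((len(usable), len(clusters), len(clusters)))
        for pi, (lig, subunits, _) in enumerate(usable):
            lvec = means[:, ids[lig]]
            rvec = np.exp(np.mean(
                [np.log(means[:, ids[s]] + 1e-12) for s in subunits], axis=0))
            rvec = np.where(rvec < 1e-9, 0.0, rvec)
            out[pi] = np.outer(lvec, rvec)
        return out

    obs = probabilities(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        exceed += probabilities(rng.permutation(labels)) >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    rows = []
    for pi, (lig, subunits, pathway) in enumerate(usable):
        for si, s in enumerate(clusters):
            for ri, r in enumerate(clusters):
                prob = float(obs[pi, si, ri])
                p = float(pvals[pi, si, ri]) if prob > 0 else 1.0
                rows.append((s, r, lig, "+".join(subunits), pathway, prob, p, prob > 0 and p < alpha))
    return pd.DataFrame(rows, columns=[
        "sender", "receiver", "ligand", "receptor", "pathway",
        "probability", "p", "significant",
    ])
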