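"""Barcode-level quality control and collision/doublet removal.

QC keeps barcodes with at least ``min_reads`` fragments and a fraction of
reads in peaks (FRiP) of at least ``min_frip``. Doublets are detected the
way combinatorial-indexing collision screens do it: simulate barcode
collisions by pooling random pairs of observed cells, embed real and
simulated cells jointly, and score each real cell by the fraction of its
k nearest neighbours that are simulated; cells above the score cutoff
(default 0.2) are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .fragments import FeatureMatrix, FragmentSet


def percentage(part: float, whole: float) -> float:
    """part / whole as a percentage (0 when whole == 0)."""
    return 0.0 if whole == 0 else 100.0 * part / whole


def mapping_summary(total_read_pairs: int, mapped_read_pairs: int) -> dict:
    """Alignment bookkeeping: the percentage of read pairs that mapped."""
    return {
        "total_read_pairs": int(total_read_pairs),
        "mapped_read_pairs": int(mapped_read_pairs),
        "mapped_percent": percentage(mapped_read_pairs, total_read_pairs),
    }


def removal_summary(removed: int, retained: int) -> dict:
    """Filtering bookkeeping: the percentage of cells a stage removed."""
    return {
        "removed": int(removed),
        "retained": int(retained),
        "removed_percent": percentage(removed, removed + retained),
    }


@dataclass
class QCReport:
    """Per-barcode metrics with pass/fail flags and recomputable summaries."""

    per_barcode: pd.DataFrame  # reads, frip, pass_reads, pass_frip, pass_all
    min_reads: int
    min_frip: float
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pb = self.per_barcode
        n = len(pb)
        retained = int(pb["pass_all"].sum())
        self.summary = {
            "n_barcodes": n,
            "retained": retained,
            "removed": n - retained,
            "removed_percent": percentage(n - retained, n),
            "removed_low_reads": int((~pb["pass_reads"]).sum()),
            "removed_low_frip": int((pb["pass_reads"] & ~pb["pass_frip"]).sum()),
        }

    @property
    def retained_barcodes(self) -> np.ndarray:
        return self.per_barcode.index[self.per_barcode["pass_all"]].to_numpy()


def _merge_intervals(peaks: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for chrom, grp in peaks.groupby("chrom", observed=True):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.array(starts), np.array(ends))
    return merged


def frip(fragments: FragmentSet, peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode total fragments and fraction overlapping any peak."""
    merged = _merge_intervals(peaks)
    df = fragments.df
    in_peak = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", observed=True):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        fs = grp["start"].to_numpy()
        fe = grp["end"].to_numpy()
        # peaks are disjoint and sorted: the only candidate is the last peak
        # starting before the fragment end
        idx = np.searchsorted(starts, fe, side="left") - 1
        ok = idx >= 0
        ok[ok] = ends[idx[ok]] > fs[ok]
        in_peak[grp.index.to_numpy()] = ok
    agg = pd.DataFrame({"barcode": df["barcode"], "in_peak": in_peak}).groupby("barcode")
    out = agg.agg(reads=("in_peak", "size"), in_peak=("in_peak", "sum"))
    out["frip"] = np.where(out["reads"] > 0, out["in_peak"] / out["reads"], np.nan)
    return out


def qc_filter(
    fragments: FragmentSet,
    peaks: pd.DataFrame,
    min_reads: int = 1_000,
    min_frip: float = 0.15,
) -> QCReport:
    """Keep barcodes with reads >= min_reads and FRiP >= min_frip.

    A barcode with zero fragments has undefined FRiP and fails the filter.
    """
    pb = frip(fragments, peaks)
    pb["pass_reads"] = pb["reads"] >= min_reads
    pb["pass_frip"] = pb["frip"].fillna(-1.0) >= min_frip
    pb["pass_all"] = pb["pass_reads"] & pb["pass_frip"]
    return QCReport(pb, min_reads, min_frip)


def simulate_collisions(
    fm: FeatureMatrix,
    n_sim: int | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Append in-silico collision profiles to a feature matrix.

    Each simulated doublet pools two distinct cells sampled uniformly
    (without replacement within the pair): element-wise sum in counts mode,
    logical OR when the matrix is binarized. Returns the augmented matrix,
    a boolean is-simulated label per row, and the (n_sim, 2) parent index
    array.
    """
    n = fm.n_cells
    if n < 2:
        raise ValueError("need at least two cells to simulate collisions")
    if n_sim is None:
        n_sim = max(1, int(round(0.25 * n)))
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    first = rng.integers(0, n, size=n_sim)
    offset = rng.integers(1, n, size=n_sim)
    pairs = np.stack([first, (first + offset) % n], axis=1)
    sim = fm.matrix[pairs[:, 0]] + fm.matrix[pairs[:, 1]]
    sim_totals = fm.totals[pairs[:, 0]] + fm.totals[pairs[:, 1]]
    if fm.binarized:
        sim = sparse.csr_matrix(sim)
        sim.data = np.ones_like(sim.data)
    mat = sparse.vstack([fm.matrix, sim]).tocsr()
    sim_names = np.array([f"SIM_{i:05d}" for i in range(n_sim)])
    aug = FeatureMatrix(
        mat,
        np.concatenate([fm.barcodes, sim_names]),
        fm.feature_ids,
        fm.features,
        fm.binarized,
        np.concatenate([fm.totals, sim_totals]),
    )
    is_sim = np.zeros(n + n_sim, dtype=bool)
    is_sim[n:] = True
    return aug, is_sim, pairs


def downsample_counts(fm: FeatureMatrix, target: int, seed: int = 0) -> FeatureMatrix:
    """Depth-equalise a count matrix by multivariate-hypergeometric
    downsampling of each cell with more than ``target`` counts.

    Removes the library-size axis from within-cluster geometry so that
    profile shape, not depth, drives nearest-neighbour structure.
    """
    rng = np.random.default_rng(seed)
    X = sparse.csr_matrix(fm.matrix, dtype=np.int64).copy()
    for i in range(X.shape[0]):
        row = X.data[X.indptr[i]:X.indptr[i + 1]]
        if row.sum() > target:
            X.data[X.indptr[i]:X.indptr[i + 1]] = rng.multivariate_hypergeometric(row, target)
    X.eliminate_zeros()
    return FeatureMatrix(X.astype(float), fm.barcodes, fm.feature_ids, fm.features)


def detect_doublets(
    fm: FeatureMatrix,
    n_sim: int | None = None,
    k: int = 30,
    cutoff: float = 0.2,
    n_components: int = 10,
    downsample_percentile: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end collision detection on a cell-by-peak count matrix.

    Simulates in-silico collisions (ratio 0.25 by default), equalises depth
    across real and simulated profiles, embeds everything jointly with
    TF-IDF/LSI over all features, and scores each real cell by its
    simulated-neighbour fraction at the given k and cutoff. Returns the
    per-real-cell score table indexed by barcode.
    """
    from .embedding import tfidf_lsi

    aug, is_sim, _ = simulate_collisions(fm, n_sim=n_sim, seed=seed)
    target = int(np.percentile(aug.totals[~is_sim], downsample_percentile))
    eq = downsample_counts(aug, target, seed=seed)
    emb = tfidf_lsi(eq, n_components=n_components, variable_fraction=1.0, seed=seed)
    scores = doublet_scores(emb.matrix(), is_sim, k=k, cutoff=cutoff)
    scores.index = pd.Index(fm.barcodes, name="barcode")
    return scores


def doublet_scores(
    embedding: np.ndarray,
    is_simulated: np.ndarray,
    k: int = 30,
    cutoff: float = 0.2,
) -> pd.DataFrame:
    """Score real cells by the simulated fraction of their k nearest
    neighbours in the joint embedding; flag scores above ``cutoff``.

    Returns a DataFrame (one row per real cell, in embedding order) with
    ``score`` in {0, 1/k, ..., 1} and a boolean ``flagged`` column.
    """
    embedding = np.asarray(embedding, dtype=float)
    n_all = embedding.shape[0]
    if k >= n_all:
        raise ValueError(f"k={k} must be smaller than the number of cells {n_all}")
    is_simulated = np.asarray(is_simulated, dtype=bool)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding[~is_simulated])
    # drop self (a real cell is always its own nearest neighbour)
    idx = idx[:, 1:k + 1]
    score = is_simulated[idx].mean(axis=1)
    return pd.DataFrame({"score": score, "flagged": score > cutoff})
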