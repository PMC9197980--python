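"""Per-cluster aggregate peak calling and cross-cluster merging.

Each cluster's fragments are reduced to Tn5 insertion sites (both fragment
ends); every insertion is expanded to a 200-bp pseudo-read centred on it
(the shift -100 / extsize 200 convention). Candidate regions are maximal
runs of per-base coverage strictly above the genome-wide mean rate; each
candidate is tested against a Poisson null whose rate is the larger of the
genome-wide rate and the local 10-kb rate, with Benjamini-Hochberg control
over candidates. Summits are the leftmost coverage argmax. Cluster peak
sets are merged by extending summits +/-250 bp, dropping blacklist overlaps,
and unioning overlapping or bookended intervals (keeping the best summit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet, interval_overlap

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "score", "pval", "qval", "cluster"]


@dataclass
class PeakSet:
    """Called peaks: intervals with summit, -log10 q score, source cluster."""

    df: pd.DataFrame
    merged: bool = False

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def intervals(self) -> pd.DataFrame:
        return self.df[["chrom", "start", "end"]]

    def to_narrowpeak(self, path) -> None:
        """narrowPeak BED: name, int score, strand '.', signal, -log10 p/q, summit offset."""
        df = self.df
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": [f"peak_{i}" for i in range(len(df))],
            "score": np.minimum(1000, (10 * df["score"]).round().astype(int)),
            "strand": ".",
            "signal": df["score"],
            "pval": -np.log10(np.maximum(df["pval"], 1e-300)),
            "qval": -np.log10(np.maximum(df["qval"], 1e-300)),
            "summit_offset": df["summit"] - df["start"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)


def _insertion_coverage(starts, ends, length: int, ext: int = 100) -> np.ndarray:
    """Per-base coverage of 2*ext-width pseudo-reads centred on both
    fragment ends (insertion sites)."""
    ins = np.concatenate([starts, ends - 1])
    lo = np.clip(ins - ext, 0, length)
    hi = np.clip(ins + ext, 0, length)
    diff = np.bincount(lo, minlength=length + 1).astype(np.int64)
    diff -= np.bincount(hi, minlength=length + 1)
    return np.cumsum(diff[:-1])


def call_cluster_peaks(
    fragments: FragmentSet,
    cluster_of_barcode: dict[str, int],
    chrom_lengths: dict[str, int],
    q_max: float = 0.05,
    ext: int = 100,
    local_window: int = 10_000,
) -> dict[int, PeakSet]:
    """Call peaks independently on each cluster's aggregated fragments."""
    df = fragments.df
    clusters = df["barcode"].map(cluster_of_barcode)
    out: dict[int, PeakSet] = {}
    for cl in sorted(set(cluster_of_barcode.values())):
        sub = df.loc[clusters == cl]
        if not len(sub):
            logger.warning("cluster %s has no fragments; empty peak set", cl)
            out[cl] = PeakSet(pd.DataFrame(columns=PEAK_COLUMNS))
            continue
        out[cl] = _call_peaks_single(sub, chrom_lengths, cl, q_max, ext, local_window)
    return out


def _call_peaks_single(df, chrom_lengths, cluster, q_max, ext, local_window) -> PeakSet:
    total_cov = 0.0
    genome_len = sum(chrom_lengths.values())
    covs: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", observed=True):
        cov = _insertion_coverage(
            grp["start"].to_numpy(), grp["end"].to_numpy(), chrom_lengths[chrom], ext
        )
        covs[chrom] = cov
        total_cov += float(cov.sum())
    lam_genome = total_cov / genome_len
    cand = []
    for chrom, cov in covs.items():
        above = cov > lam_genome
        if not above.any():
            continue
        bounded = np.concatenate([[0], above.astype(np.int8), [0]])
        d = np.diff(bounded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        csum = np.concatenate([[0], np.cumsum(cov)])
        L = len(cov)
        for s, e in zip(run_starts, run_ends):
            seg = cov[s:e]
            summit = s + int(np.argmax(seg))
            height = int(seg.max())
            w0 = max(0, (s + e) // 2 - local_window // 2)
            w1 = min(L, w0 + local_window)
            lam_local = (csum[w1] - csum[w0]) / (w1 - w0)
            lam = max(lam_genome, lam_local)
            # union bound over the bases tested in the region: a long
            # background run's maximum is an extreme over many draws
            pval = float(min(1.0, (e - s) * stats.poisson.sf(height - 1, lam)))
            cand.append((chrom, int(s), int(e), summit, height, pval))
    if not cand:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS))
    cdf = pd.DataFrame(cand, columns=["chrom", "start", "end", "summit", "height", "pval"])
    _, qvals, _, _ = multipletests(cdf["pval"], method="fdr_bh")
    cdf["qval"] = qvals
    cdf = cdf[cdf["qval"] <= q_max].reset_index(drop=True)
    cdf["score"] = -np.log10(np.maximum(cdf["qval"], 1e-300))
    cdf["cluster"] = cluster
    return PeakSet(cdf[PEAK_COLUMNS])


def merge_peaks(
    peaksets: list[PeakSet],
    chrom_lengths: dict[str, int],
    extension: int = 250,
    blacklist: pd.DataFrame | None = None,
) -> PeakSet:
    """Fixed-width merge: summits +/-extension, blacklist drop, union.

    Overlapping or bookended extended peaks become one interval carrying the
    maximum score and that score's summit. The result is non-overlapping.
    """
    frames = [ps.df for ps in peaksets if len(ps.df)]
    if not frames:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS), merged=True)
    allp = pd.concat(frames, ignore_index=True).copy()
    allp["start"] = np.maximum(allp["summit"] - extension, 0)
    allp["end"] = [
        min(int(s) + extension + 1, chrom_lengths[c])
        for c, s in zip(allp["chrom"], allp["summit"])
    ]
    if blacklist is not None and len(blacklist):
        hit, _ = interval_overlap(allp[["chrom", "start", "end"]], blacklist)
        allp = allp.loc[~hit].reset_index(drop=True)
    allp = allp.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    rows = []
    cur = None
    for r in allp.itertuples():
        if cur is not None and r.chrom == cur["chrom"] and r.start <= cur["end"]:
            cur["end"] = max(cur["end"], r.end)
            if r.score > cur["score"]:
                cur["score"], cur["summit"] = r.score, r.summit
                cur["pval"], cur["qval"], cur["cluster"] = r.pval, r.qval, r.cluster
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": r.chrom, "start": int(r.start), "end": int(r.end),
                "summit": int(r.summit), "score": float(r.score),
                "pval": float(r.pval), "qval": float(r.qval), "cluster": r.cluster,
            }
    if cur is not None:
        rows.append(cur)
    return PeakSet(pd.DataFrame(rows, columns=PEAK_COLUMNS), merged=True)
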