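"""TF motif machinery: PWM scanning, per-cell deviation scores, motif
enrichment, TF-module discovery, and Tn5-bias-corrected footprints.

Deviation scores follow the chromVAR recipe: for motif j and cell i with
peak counts X, the observed motif accessibility o = sum_p M_jp X_ip is
compared with the depth-matched expectation e = T_i * sum_p M_jp f_p (f_p
the peak's share of all counts); the raw deviation (o - e) / e is z-scored
against the same statistic computed on GC- and accessibility-matched
background peak sets. A motif's variability is the standard deviation of
its z-scores across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet
from .synthetic import GenomeModel

logger = logging.getLogger(__name__)

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Motif:
    """A position probability matrix (4 x width, rows A/C/G/T)."""

    name: str
    ppm: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.shape[0] != 4:
            raise ValueError(f"motif {self.name}: PPM must have 4 rows")
        colsums = self.ppm.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError(f"motif {self.name}: PPM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.ppm.shape[1]

    def log_odds(self, background: np.ndarray, pseudo: float = 1e-3) -> np.ndarray:
        p = (self.ppm + pseudo) / (1 + 4 * pseudo)
        return np.log2(p / background[:, None])


@dataclass
class MotifSet:
    motifs: list[Motif] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]


def read_jaspar(path) -> MotifSet:
    """Read a JASPAR-format PFM file (via Biopython) into a MotifSet."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        ppm = counts / counts.sum(axis=0, keepdims=True)
        out.append(Motif(rec.name or rec.matrix_id, ppm))
    return MotifSet(out)


def motifset_from_consensus(consensus: dict[str, str], confidence: float = 0.97) -> MotifSet:
    """Near-deterministic PPMs from consensus strings (for planted truth)."""
    rest = (1 - confidence) / 3
    out = []
    for name, seq in consensus.items():
        ppm = np.full((4, len(seq)), rest)
        for j, base in enumerate(seq.upper()):
            ppm[BASE_INDEX[base], j] = confidence
        out.append(Motif(name, ppm))
    return MotifSet(out)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; other characters map to A (synthetic genomes are N-free)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.zeros(len(arr), dtype=np.int8)
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def score_threshold(lodds: np.ndarray, background: np.ndarray,
                    pvalue: float = 5e-5, n_bins: int = 10_000) -> float:
    """Score cutoff achieving the given PWM p-value under the background.

    Dynamic programming over the discretised per-column score distribution:
    column score PMFs (with background base probabilities) are convolved,
    and the threshold is the smallest grid score whose upper tail has
    probability <= ``pvalue``.
    """
    w = lodds.shape[1]
    lo = float(lodds.min(axis=0).sum())
    hi = float(lodds.max(axis=0).sum())
    if hi <= lo:
        return hi
    step = (hi - lo) / n_bins
    pmf = np.zeros(n_bins + 1)
    pmf[0] = 1.0
    offset = 0.0  # accumulated column minima (grid origin)
    for j in range(w):
        col = lodds[:, j]
        cmin = col.min()
        idx = np.round((col - cmin) / step).astype(int)
        colpmf = np.zeros(idx.max() + 1)
        for b in range(4):
            colpmf[idx[b]] += background[b]
        pmf = np.convolve(pmf, colpmf)[: n_bins + 2 * w + 1]
        offset += cmin
    tail = np.cumsum(pmf[::-1])[::-1]
    ok = np.flatnonzero(tail <= pvalue)
    if not len(ok):
        return hi + step
    # margin for per-column rounding so discretisation cannot pull true
    # scores of the next-lower mass level above the threshold
    return offset + ok[0] * step + w * step / 2


def _scan_one(code: np.ndarray, lodds: np.ndarray) -> float:
    """Maximum log-odds score over all offsets of one strand."""
    w = lodds.shape[1]
    if len(code) < w:
        return -np.inf
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    scores = lodds[windows, np.arange(w)].sum(axis=1)
    return float(scores.max())


def _revcomp_lodds(lodds: np.ndarray) -> np.ndarray:
    return lodds[::-1, ::-1]


def scan_motifs(
    peaks: pd.DataFrame,
    genome: GenomeModel,
    motifset: MotifSet,
    background: np.ndarray | None = None,
    pvalue: float = 5e-5,
):
    """Scan peak sequences for motif matches on both strands.

    Returns ``(match, gc)``: a motifs x peaks boolean matrix (match iff the
    best log-odds score reaches the threshold at PWM p-value ``pvalue``
    under the background base composition) and per-peak GC content.
    """
    if background is None:
        background = genome_base_composition(genome)
    seqs = [genome.fetch(r.chrom, int(r.start), int(r.end)) for r in peaks.itertuples()]
    codes = [encode_sequence(s) for s in seqs]
    gc = np.array([((c == 1) | (c == 2)).mean() if len(c) else 0.0 for c in codes])
    match = np.zeros((len(motifset), len(peaks)), dtype=bool)
    short_warned = False
    for mi, motif in enumerate(motifset.motifs):
        lodds = motif.log_odds(background)
        thr = score_threshold(lodds, background, pvalue)
        rc = _revcomp_lodds(lodds)
        for pi, code in enumerate(codes):
            if len(code) < motif.width:
                if not short_warned:
                    logger.warning("some peaks shorter than motif %s; no match", motif.name)
                    short_warned = True
                continue
            best = max(_scan_one(code, lodds), _scan_one(code, rc))
            match[mi, pi] = best >= thr
    return match, gc


def genome_base_composition(genome: GenomeModel) -> np.ndarray:
    counts = np.zeros(4)
    for chrom in genome.chrom_names:
        code = encode_sequence(genome.sequence[chrom])
        counts += np.bincount(code, minlength=4)
    return counts / counts.sum()


@dataclass
class DeviationMatrix:
    """Motifs x cells deviations: raw, z-scores, and per-motif variability."""

    raw: pd.DataFrame
    z: pd.DataFrame
    variability: pd.Series

    @property
    def motifs(self) -> pd.Index:
        return self.z.index


def _background_bins(gc: np.ndarray, mean_acc: np.ndarray, n_grid: int = 10) -> np.ndarray:
    """Assign each peak to a cell of a GC x log-mean-accessibility grid."""
    def qbin(x):
        ranks = stats.rankdata(x, method="average") / (len(x) + 1)
        return np.minimum((ranks * n_grid).astype(int), n_grid - 1)

    return qbin(gc) * n_grid + qbin(np.log1p(mean_acc))


def chromvar_deviations(
    fm,
    match: np.ndarray,
    gc: np.ndarray,
    motif_names: list[str] | None = None,
    n_background: int = 50,
    seed: int = 0,
) -> DeviationMatrix:
    """Bias-corrected per-cell motif deviation z-scores.

    ``fm`` is the cell-by-peak FeatureMatrix, ``match`` a motifs x peaks
    boolean matrix, ``gc`` per-peak GC content. Background sets replace
    each motif peak with a random peak from the same cell of a 10 x 10
    GC x accessibility grid. Motifs with no matched peaks are dropped.
    """
    X = fm.matrix.tocsc().astype(float)
    n_cells, n_peaks = X.shape
    match = np.asarray(match, dtype=bool)
    if motif_names is None:
        motif_names = [f"motif_{i}" for i in range(match.shape[0])]
    keep = match.sum(axis=1) > 0
    if not keep.all():
        dropped = [motif_names[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping motifs with no matched peaks: %s", dropped)
    match = match[keep]
    motif_names = [n for n, k in zip(motif_names, keep) if k]
    T = fm.totals.astype(float)
    total = X.sum()
    f = np.asarray(X.sum(axis=0)).ravel() / total
    mean_acc = np.asarray(X.mean(axis=0)).ravel()
    bins = _background_bins(gc, mean_acc)
    peers = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    rng = np.random.default_rng(seed)

    M = sparse.csr_matrix(match.astype(float))
    obs = np.asarray((X @ M.T).todense()) if sparse.issparse(X @ M.T) else np.asarray(X @ M.T)
    e = np.outer(T, M @ f)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(e > 0, (obs - e) / e, np.nan)

    bg_devs = np.empty((n_background, n_cells, match.shape[0]))
    for b in range(n_background):
        mapping = np.arange(n_peaks)
        for cell_bin, members in peers.items():
            mapping[members] = rng.choice(members, size=len(members), replace=True)
        Mb_rows = []
        for mi in range(match.shape[0]):
            cols = mapping[np.flatnonzero(match[mi])]
            row = np.zeros(n_peaks)
            np.add.at(row, cols, 1.0)
            Mb_rows.append(row)
        Mb = np.array(Mb_rows)
        obs_b = np.asarray(X @ Mb.T)
        e_b = np.outer(T, Mb @ f)
        with np.errstate(divide="ignore", invalid="ignore"):
            bg_devs[b] = np.where(e_b > 0, (obs_b - e_b) / e_b, np.nan)
    bg_mean = np.nanmean(bg_devs, axis=0)
    bg_sd = np.nanstd(bg_devs, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bg_sd > 0, (raw - bg_mean) / bg_sd, np.nan)
    raw_df = pd.DataFrame(raw.T, index=motif_names, columns=fm.barcodes)
    z_df = pd.DataFrame(z.T, index=motif_names, columns=fm.barcodes)
    variability = z_df.std(axis=1, ddof=1)
    return DeviationMatrix(raw_df, z_df, variability)


def raw_deviations(fm, match: np.ndarray) -> np.ndarray:
    """Raw (not background-normalised) deviations; motifs x cells."""
    X = np.asarray(fm.matrix.todense(), dtype=float)
    M = np.asarray(match, dtype=float)
    T = fm.totals.astype(float)
    f = X.sum(axis=0) / X.sum()
    obs = X @ M.T
    e = np.outer(T, M @ f)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(e > 0, (obs - e) / e, np.nan).T


def motif_enrichment(
    fg_index: np.ndarray,
    bg_index: np.ndarray,
    match: np.ndarray,
    motif_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-motif enrichment of a foreground peak set over a background.

    Fold-change of match fractions plus a one-sided hypergeometric p-value
    (drawing the foreground from the pooled fg+bg universe), BH-adjusted
    over motifs. Motifs matching nothing in either set are skipped.
    """
    match = np.asarray(match, dtype=bool)
    if motif_names is None:
        motif_names = [f"motif_{i}" for i in range(match.shape[0])]
    fg = match[:, fg_index]
    bg = match[:, bg_index]
    n_fg, n_bg = fg.shape[1], bg.shape[1]
    rows = []
    for mi in range(match.shape[0]):
        k, m = int(fg[mi].sum()), int(bg[mi].sum())
        if k + m == 0:
            continue
        fold = (k / n_fg) / (m / n_bg) if m > 0 else np.inf
        p = float(stats.hypergeom.sf(k - 1, n_fg + n_bg, k + m, n_fg))
        rows.append((motif_names[mi], k, m, fold, p))
    df = pd.DataFrame(rows, columns=["motif", "fg_matches", "bg_matches", "fold", "p"])
    if len(df):
        _, df["p_adj"], _, _ = multipletests(df["p"], method="fdr_bh")
    else:
        df["p_adj"] = []
    return df


def tf_modules(dev: DeviationMatrix, var_min: float = 1.8, n_modules: int = 3):
    """Hierarchically cluster high-variability motifs into modules.

    Motifs with variability strictly above ``var_min`` enter; average-
    linkage clustering on distance 1 - Pearson r of z-score rows, cut to
    ``n_modules``. Constant rows are dropped with a warning.
    """
    sel = dev.variability.index[dev.variability > var_min]
    Z = dev.z.loc[sel].dropna(axis=1, how="any")
    const = Z.index[Z.std(axis=1) == 0]
    if len(const):
        logger.warning("dropping constant z rows: %s", list(const))
        Z = Z.drop(index=const)
    if len(Z) < 2:
        raise ValueError(
            f"need >= 2 motifs above variability {var_min}; got {len(Z)}"
        )
    corr = np.corrcoef(Z.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=n_modules, criterion="maxclust")
    modules = pd.Series(labels, index=Z.index, name="module")
    corr_df = pd.DataFrame(corr, index=Z.index, columns=Z.index)
    return modules, corr_df


def footprint(
    fragments: FragmentSet,
    sites: pd.DataFrame,
    genome: GenomeModel,
    flank: int = 250,
    kmer: int = 6,
    bias_flank_min: int = 200,
) -> pd.DataFrame:
    """Aggregate Tn5 insertion profile around motif sites, bias-corrected.

    Both fragment ends are insertion positions. The observed profile is the
    mean insertion count per position in [-flank, flank] across sites. The
    Tn5 sequence bias profile is built from a genome-wide k-mer insertion
    frequency table (insertions per k-mer occurrence) evaluated on the site
    sequences, scaled so its flank mean (|position| > ``bias_flank_min``)
    matches the observed flank mean, and subtracted.

    ``sites`` needs columns chrom and center (or start/end, whose midpoint
    is used). Sites too close to a chromosome end are skipped.
    """
    if "center" not in sites.columns:
        sites = sites.assign(center=(sites["start"] + sites["end"]) // 2)
    half = kmer // 2
    ins_counts: dict[str, np.ndarray] = {}
    kmer_ids: dict[str, np.ndarray] = {}
    kmer_count = np.zeros(4 ** kmer)
    kmer_ins = np.zeros(4 ** kmer)
    weights = 4 ** np.arange(kmer - 1, -1, -1)
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        sub = fragments.df[fragments.df["chrom"] == chrom]
        ins = np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy() - 1])
        ins = ins[(ins >= 0) & (ins < L)]
        ins_counts[chrom] = np.bincount(ins, minlength=L).astype(float)
        code = encode_sequence(genome.sequence[chrom]).astype(np.int64)
        win = np.lib.stride_tricks.sliding_window_view(code, kmer)
        ids = win @ weights  # k-mer id at each start position
        # k-mer centred on genomic position p starts at p - half
        centred = np.full(L, -1, dtype=np.int64)
        centred[half: half + len(ids)] = ids
        kmer_ids[chrom] = centred
        valid = centred >= 0
        kmer_count += np.bincount(centred[valid], minlength=4 ** kmer)
        kmer_ins += np.bincount(centred[valid], weights=ins_counts[chrom][valid],
                                minlength=4 ** kmer)
    with np.errstate(divide="ignore", invalid="ignore"):
        bias_table = np.where(kmer_count > 0, kmer_ins / kmer_count, 0.0)

    width = 2 * flank + 1
    obs = np.zeros(width)
    bias = np.zeros(width)
    n_used = 0
    for r in sites.itertuples():
        c = int(r.center)
        L = genome.chrom_lengths[r.chrom]
        if c - flank < 0 or c + flank + 1 > L:
            continue
        obs += ins_counts[r.chrom][c - flank: c + flank + 1]
        ids = kmer_ids[r.chrom][c - flank: c + flank + 1]
        bias += np.where(ids >= 0, bias_table[ids], 0.0)
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable sites (all too close to chromosome ends)")
    obs /= n_used
    bias /= n_used
    pos = np.arange(-flank, flank + 1)
    flank_mask = np.abs(pos) > bias_flank_min
    scale = obs[flank_mask].mean() / bias[flank_mask].mean() if bias[flank_mask].mean() > 0 else 0.0
    corrected = obs - scale * bias
    return pd.DataFrame({
        "position": pos,
        "observed": obs,
        "bias": bias * scale,
        "corrected": corrected,
    })
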