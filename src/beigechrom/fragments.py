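"""Fragment-file I/O, interval arithmetic, and cell-by-feature matrices.

All genomic coordinates are 0-based half-open (BED convention). Fragment
files are BED3 + barcode, tab-separated, optionally gzip-compressed; an
optional fifth (count) column is ignored on read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode"]


class FragmentFileError(ValueError):
    """Malformed fragment file (bad coordinates, wrong column count)."""


@dataclass
class FragmentSet:
    """Deduplicated per-barcode genomic intervals, sorted by (chrom, start).

    Parameters
    ----------
    df
        DataFrame with columns chrom, start, end, barcode. Coordinates are
        0-based half-open and must satisfy start < end.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if list(df.columns[:4]) != FRAGMENT_COLUMNS:
            df = df.iloc[:, :4].set_axis(FRAGMENT_COLUMNS, axis=1)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = int((df["start"] >= df["end"]).idxmax())
            raise FragmentFileError(f"record {bad}: start >= end")
        order_ok = df["chrom"].is_monotonic_increasing or len(df) == 0
        if not order_ok or not _sorted_within_chrom(df):
            df = df.sort_values(["chrom", "start", "end", "barcode"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def barcodes(self) -> np.ndarray:
        """Unique barcodes in first-appearance-free sorted order."""
        return np.asarray(sorted(self.df["barcode"].unique()))

    def barcode_counts(self) -> pd.Series:
        """Number of fragments per barcode."""
        return self.df["barcode"].value_counts().sort_index()

    def subset_barcodes(self, barcodes) -> "FragmentSet":
        keep = self.df["barcode"].isin(set(barcodes))
        return FragmentSet(self.df.loc[keep].reset_index(drop=True))

    def validate_bounds(self, chrom_lengths: dict[str, int]) -> None:
        """Raise if any record exceeds its chromosome bounds."""
        for chrom, grp in self.df.groupby("chrom", observed=True):
            if chrom not in chrom_lengths:
                raise FragmentFileError(f"unknown chromosome {chrom!r}")
            if (grp["start"] < 0).any() or (grp["end"] > chrom_lengths[chrom]).any():
                raise FragmentFileError(f"fragment outside bounds on {chrom}")


def _sorted_within_chrom(df: pd.DataFrame) -> bool:
    if len(df) < 2:
        return True
    same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
    inc = df["start"].to_numpy()[1:] >= df["start"].to_numpy()[:-1]
    return bool(np.all(~same | inc))


def read_fragments(path, on_unsorted: str = "sort") -> FragmentSet:
    """Read a fragment file (TSV: chrom, start, end, barcode[, count]).

    Duplicate (chrom, start, end, barcode) records are collapsed with a
    logged count: deduplication is assumed done upstream, so repeats are
    bookkeeping noise, not signal.

    Parameters
    ----------
    on_unsorted
        ``"sort"`` (default) sorts with a warning; ``"error"`` raises.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    rows = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FragmentFileError(f"line {lineno}: expected >= 4 columns, got {len(parts)}")
            chrom, start_s, end_s, barcode = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FragmentFileError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FragmentFileError(f"line {lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise FragmentFileError(f"line {lineno}: negative start")
            rows.append((chrom, start, end, barcode))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if len(df):
        n0 = len(df)
        df = df.drop_duplicates()
        if len(df) < n0:
            logger.warning("collapsed %d duplicate fragment records", n0 - len(df))
    sorted_ok = df["chrom"].is_monotonic_increasing and _sorted_within_chrom(df)
    if not sorted_ok:
        if on_unsorted == "error":
            raise FragmentFileError("fragment file is not sorted by (chrom, start)")
        logger.warning("fragment file not sorted; sorting")
    return FragmentSet(df)


def write_fragments(fragments: FragmentSet, path) -> None:
    """Write a FragmentSet as a BED3+barcode TSV (gzip if path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fragments.df.to_csv(fh, sep="\t", header=False, index=False)


@dataclass
class FeatureMatrix:
    """Cells x features count (or binary) matrix with cached per-cell totals.

    ``matrix`` is CSR with cells on rows. ``totals`` caches the per-cell sum
    over all features at construction time, so it survives feature
    subsetting (depth normalisation should use the original totals).
    """

    matrix: sparse.csr_matrix
    barcodes: np.ndarray
    feature_ids: np.ndarray
    features: pd.DataFrame | None = None  # interval table for genomic features
    binarized: bool = False
    totals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.barcodes = np.asarray(self.barcodes)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.totals is None:
            self.totals = np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def binarize(self) -> "FeatureMatrix":
        m = self.matrix.copy()
        m.data = np.ones_like(m.data)
        return FeatureMatrix(m, self.barcodes, self.feature_ids, self.features, True, self.totals.copy())

    def subset_cells(self, barcodes) -> "FeatureMatrix":
        idx = {b: i for i, b in enumerate(self.barcodes)}
        rows = np.array([idx[b] for b in barcodes], dtype=int)
        return FeatureMatrix(
            self.matrix[rows], np.asarray(list(barcodes)), self.feature_ids,
            self.features, self.binarized, self.totals[rows],
        )

    def subset_features(self, mask_or_index) -> "FeatureMatrix":
        mask_or_index = np.asarray(mask_or_index)
        feats = None
        if self.features is not None:
            feats = self.features.iloc[np.arange(self.n_features)[mask_or_index] if mask_or_index.dtype == bool else mask_or_index]
            feats = feats.reset_index(drop=True)
        return FeatureMatrix(
            self.matrix[:, mask_or_index], self.barcodes, self.feature_ids[mask_or_index],
            feats, self.binarized, self.totals.copy(),
        )

    def normalized(self, scale: float = 1e4) -> sparse.csr_matrix:
        """Depth-normalised values ln(1 + scale * x / cell_total)."""
        tot = np.where(self.totals > 0, self.totals, 1.0)
        m = self.matrix.tocsr().astype(float)
        m = sparse.diags(scale / tot) @ m
        m.data = np.log1p(m.data)
        return m


def _barcode_codes(fragments: FragmentSet):
    cats = pd.Categorical(fragments.df["barcode"])
    barcodes = np.asarray(cats.categories)
    return cats.codes.astype(np.int64), barcodes


def genome_windows(chrom_lengths: dict[str, int], width: int) -> pd.DataFrame:
    """Tile each chromosome [0, L) with half-open windows of the given width."""
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, width)
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def bin_matrix(
    fragments: FragmentSet,
    chrom_lengths: dict[str, int],
    width: int = 10_000,
    blacklist: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Binary cell-by-window matrix over fixed-width genome tiles.

    A fragment is counted in every window it overlaps; windows intersecting
    a blacklist interval are dropped before binarization.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    windows = genome_windows(chrom_lengths, width)
    if blacklist is not None and len(blacklist):
        hit, _ = interval_overlap(windows, blacklist)
        windows = windows.loc[~hit].reset_index(drop=True)
    # global window index: (chrom offset) + start // width
    offsets: dict[str, int] = {}
    off = 0
    nwin_full: dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = off
        nwin_full[chrom] = int(np.ceil(length / width))
        off += nwin_full[chrom]
    codes, barcodes = _barcode_codes(fragments)
    df = fragments.df
    chrom_off = df["chrom"].map(offsets).to_numpy()
    w0 = df["start"].to_numpy() // width
    w1 = (df["end"].to_numpy() - 1) // width
    span = (w1 - w0 + 1).astype(np.int64)
    rows = np.repeat(codes, span)
    base = np.repeat(chrom_off + w0, span)
    steps = np.concatenate([np.arange(s) for s in span]) if len(span) else np.array([], dtype=np.int64)
    cols = base + steps
    n_cells = len(barcodes)
    mat = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cells, off)
    ).tocsr()
    # restrict to retained (non-blacklisted) windows
    keep_idx = (windows["chrom"].map(offsets) + windows["start"] // width).to_numpy()
    mat = mat[:, keep_idx]
    totals = np.asarray(mat.sum(axis=1)).ravel()
    mat.data = np.ones_like(mat.data)
    ids = np.array([f"{c}:{s}-{e}" for c, s, e in windows.itertuples(index=False)])
    return FeatureMatrix(mat, barcodes, ids, windows, binarized=True, totals=totals)


def feature_matrix(
    fragments: FragmentSet,
    features: pd.DataFrame,
    mode: str = "peaks",
    upstream: int = 2_000,
) -> FeatureMatrix:
    """Cell-by-feature fragment counts.

    ``mode="peaks"`` counts fragments overlapping each interval as given.
    ``mode="genes"`` extends each gene strand-awarely by ``upstream`` bp
    (clipped at 0) before counting; requires a ``strand`` column. A fragment
    overlapping two features counts in both.
    """
    feats = features.reset_index(drop=True).copy()
    if mode == "genes":
        if "strand" not in feats.columns:
            raise ValueError("gene mode requires a strand column")
        plus = feats["strand"] == "+"
        feats.loc[plus, "start"] = np.maximum(feats.loc[plus, "start"] - upstream, 0)
        feats.loc[~plus, "end"] = feats.loc[~plus, "end"] + upstream
    elif mode != "peaks":
        raise ValueError(f"unknown mode {mode!r}")
    codes, barcodes = _barcode_codes(fragments)
    n_cells = len(barcodes)
    rows_out, cols_out = [], []
    df = fragments.df
    for chrom, grp in df.groupby("chrom", observed=True):
        fsel = feats.index[feats["chrom"] == chrom]
        if not len(fsel):
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cell = codes[grp.index.to_numpy()]
        max_len = int((ends - starts).max()) if len(starts) else 0
        for j in fsel:
            fs, fe = int(feats.at[j, "start"]), int(feats.at[j, "end"])
            lo = np.searchsorted(starts, fs - max_len, side="left")
            hi = np.searchsorted(starts, fe, side="left")
            if hi <= lo:
                continue
            mask = ends[lo:hi] > fs
            if mask.any():
                rows_out.append(cell[lo:hi][mask])
                cols_out.append(np.full(int(mask.sum()), j, dtype=np.int64))
    if rows_out:
        rows = np.concatenate(rows_out)
        cols = np.concatenate(cols_out)
    else:
        rows = cols = np.array([], dtype=np.int64)
    mat = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cells, len(feats))
    ).tocsr()
    if "name" in feats.columns:
        ids = feats["name"].to_numpy()
    else:
        ids = np.array([f"{r.chrom}:{r.start}-{r.end}" for r in feats.itertuples()])
    return FeatureMatrix(mat, barcodes, ids, feats, binarized=False)


def interval_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame):
    """Overlap of two half-open interval sets.

    Returns ``(hit, hits)`` where ``hit[i]`` is True if interval i of A
    overlaps any B interval, and ``hits[i]`` lists the B row indices it
    overlaps. Interval a overlaps b iff a.start < b.end and b.start < a.end
    on the same chromosome.
    """
    a = set_a.reset_index(drop=True)
    b = set_b.reset_index(drop=True)
    hit = np.zeros(len(a), dtype=bool)
    hits: list[list[int]] = [[] for _ in range(len(a))]
    for chrom in a["chrom"].unique():
        bi = b.index[b["chrom"] == chrom].to_numpy()
        if not len(bi):
            continue
        bs = b.loc[bi, "start"].to_numpy()
        be = b.loc[bi, "end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        bi, bs, be = bi[order], bs[order], be[order]
        max_blen = int((be - bs).max())
        for i in a.index[a["chrom"] == chrom]:
            astart, aend = int(a.at[i, "start"]), int(a.at[i, "end"])
            lo = np.searchsorted(bs, astart - max_blen, side="left")
            hi = np.searchsorted(bs, aend, side="left")
            if hi <= lo:
                continue
            mask = be[lo:hi] > astart
            if mask.any():
                hit[i] = True
                hits[i] = sorted(bi[lo:hi][mask].tolist())
    return hit, hits
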