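"""The two-pass clustering pipeline: windows -> peaks -> re-cluster.

Initial clusters come from the binarized 10-kb window matrix (TF-IDF/LSI,
components 2-25 by default, SNN Leiden); peaks are then called per cluster
on aggregated fragments, merged across clusters, and the final clustering
repeats on the cell-by-peak matrix (components 2-15). Running peak calling
on initial clusters rather than the pooled cohort keeps peaks of rare
populations from being swamped by the dominant ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import ClusterAssignment, Embedding, snn_cluster, tfidf_lsi
from .fragments import FeatureMatrix, FragmentSet, bin_matrix, feature_matrix
from .peaks import PeakSet, call_cluster_peaks, merge_peaks
from .synthetic import GenomeModel


@dataclass
class TwoPassResult:
    window_matrix: FeatureMatrix
    initial_embedding: Embedding
    initial_clusters: ClusterAssignment
    peaks: PeakSet
    peak_matrix: FeatureMatrix
    embedding: Embedding
    clusters: ClusterAssignment
    knn: tuple[np.ndarray, np.ndarray]


def two_pass_cluster(
    fragments: FragmentSet,
    genome: GenomeModel,
    window_width: int = 10_000,
    variable_fraction: float = 1.0,
    components_pass1: tuple[int, int] = (1, 24),
    components_pass2: tuple[int, int] = (1, 14),
    k: int = 20,
    resolution: float = 0.8,
    q_max: float = 0.05,
    seed: int = 0,
) -> TwoPassResult:
    """Windows -> initial clusters -> per-cluster peaks -> final clusters.

    Component ranges are 0-based inclusive (the depth-tracking component 0
    is dropped, mirroring the drop-the-first-LSI-component rule).
    ``variable_fraction`` defaults to 1.0 here: with a few hundred peaks,
    ranking by total accessibility would discard entire rare-cell-type
    programs, which the same rule never does at genome scale.
    """
    bm = bin_matrix(fragments, genome.chrom_lengths, window_width, genome.blacklist)
    emb1 = tfidf_lsi(bm, n_components=components_pass1[1] + 1,
                     variable_fraction=variable_fraction, seed=seed)
    comps1 = [c for c in emb1.retained if components_pass1[0] <= c <= components_pass1[1]]
    asg1, _ = snn_cluster(emb1, comps1, k=k, resolution=resolution, seed=seed)
    label_of = dict(zip(bm.barcodes, asg1.labels))
    cluster_sets = call_cluster_peaks(fragments, label_of, genome.chrom_lengths, q_max=q_max)
    merged = merge_peaks(list(cluster_sets.values()), genome.chrom_lengths,
                         blacklist=genome.blacklist)
    pm = feature_matrix(fragments, merged.df[["chrom", "start", "end"]]).binarize()
    pm = pm.subset_cells(bm.barcodes)  # keep cell order aligned with pass 1
    emb2 = tfidf_lsi(pm, n_components=components_pass2[1] + 1,
                     variable_fraction=variable_fraction, seed=seed)
    comps2 = [c for c in emb2.retained if components_pass2[0] <= c <= components_pass2[1]]
    asg2, knn = snn_cluster(emb2, comps2, k=k, resolution=resolution, seed=seed)
    return TwoPassResult(bm, emb1, asg1, merged, pm, emb2, asg2, knn)


def cluster_labels_frame(result: TwoPassResult, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Barcode/cluster table, optionally joined with per-cell metadata."""
    df = pd.DataFrame({
        "barcode": result.peak_matrix.barcodes,
        "cluster": result.clusters.labels,
    })
    if metadata is not None:
        df = df.merge(metadata, on="barcode", how="left")
    return df
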