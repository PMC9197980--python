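"""TF-IDF normalisation, LSI embedding, SNN clustering, 2-D layout.

The standard scATAC embedding: rank features by total accessibility and
keep the top fraction, normalise the cell-by-feature matrix by TF-IDF
(value = ln(1 + 1e4 * TF * IDF)), reduce with truncated SVD, and drop
components that track sequencing depth — the first component almost always
does — before graph clustering. Clustering builds a k-nearest-neighbour
graph in the retained LSI space, re-weights edges by the Jaccard overlap of
neighbour sets (shared nearest neighbours), and optimises modularity with
Leiden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy import sparse
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .fragments import FeatureMatrix


@dataclass
class Embedding:
    """Cells x components LSI matrix with depth-correlation bookkeeping."""

    components: np.ndarray
    singular_values: np.ndarray
    depth_correlation: np.ndarray  # Pearson r of each component vs log depth
    retained: list[int]  # components not flagged as depth-correlated
    barcodes: np.ndarray
    log_depth: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.components.shape[0]

    def matrix(self, component_range: list[int] | None = None) -> np.ndarray:
        """Component submatrix; defaults to the retained components."""
        comps = self.retained if component_range is None else list(component_range)
        return self.components[:, comps]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # contiguous ints from 0, ordered by decreasing size
    modularity: float
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sizes = np.bincount(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def tfidf_lsi(
    fm: FeatureMatrix,
    n_components: int = 30,
    variable_fraction: float = 0.5,
    depth_corr_max: float = 0.75,
    seed: int = 0,
) -> Embedding:
    """TF-IDF transform the matrix and embed with truncated SVD.

    TF is the cell-normalised count over the retained features, IDF the
    inverse fraction of cells where the feature is seen; the normalised
    value is ln(1 + 1e4 * TF * IDF). Components whose |Pearson r| against
    log per-cell depth exceeds ``depth_corr_max`` are excluded from
    ``retained`` (generalising the usual drop-the-first-component rule).
    """
    X = fm.matrix.tocsc().astype(float)
    cell_sums = np.asarray(X.sum(axis=1)).ravel()
    if (cell_sums == 0).any():
        bad = fm.barcodes[int(np.argmax(cell_sums == 0))]
        raise ValueError(f"cell {bad!r} has zero counts; it should have failed QC")
    col_totals = np.asarray(X.sum(axis=0)).ravel()
    keep = col_totals > 0
    n_keep = max(1, int(round(variable_fraction * int(keep.sum()))))
    order = np.argsort(col_totals[keep])[::-1]
    keep_idx = np.flatnonzero(keep)[order[:n_keep]]
    keep_idx.sort()
    X = X[:, keep_idx].tocsr()

    n_cells = X.shape[0]
    tf_den = np.asarray(X.sum(axis=1)).ravel()
    tf_den[tf_den == 0] = 1.0
    cells_per_feature = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = n_cells / cells_per_feature
    norm = sparse.diags(1.0 / tf_den) @ X @ sparse.diags(idf)
    norm.data = np.log1p(1e4 * norm.data)

    n_components = min(n_components, min(norm.shape) - 1)
    svd = TruncatedSVD(n_components=n_components, algorithm="arpack", random_state=seed)
    comps = svd.fit_transform(norm)
    log_depth = np.log1p(fm.totals.astype(float))
    corr = np.array([
        _pearson(comps[:, i], log_depth) for i in range(n_components)
    ])
    retained = [i for i in range(n_components) if abs(corr[i]) <= depth_corr_max]
    return Embedding(comps, svd.singular_values_, corr, retained, fm.barcodes, log_depth)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / den) if den > 0 else 0.0


def knn_graph(X: np.ndarray, k: int):
    """Indices and distances of the k nearest neighbours (self excluded)."""
    if k >= X.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of cells {X.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    return idx[:, 1:], dist[:, 1:]


def snn_cluster(
    emb: Embedding,
    component_range: list[int] | None = None,
    k: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
):
    """Shared-nearest-neighbour Leiden clustering on the LSI embedding.

    Edge weights are the Jaccard overlap of the two cells' kNN sets,
    restricted to kNN pairs; community detection maximises RB modularity at
    the given resolution. Returns ``(ClusterAssignment, (knn_idx, knn_dist))``.
    """
    X = emb.matrix(component_range)
    idx, dist = knn_graph(X, k)
    n = X.shape[0]
    # neighbour-set membership incl. self, for Jaccard overlaps
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([np.arange(n)[:, None], idx], axis=1).ravel()
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    shared = A @ A.T  # pairwise shared-neighbour counts
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i and i in idx[j]:
                continue  # count undirected edge once
            s = shared[i, j]
            jac = s / (2 * (k + 1) - s)
            if jac > 0:  # zero-weight edges would fake connectivity
                edges.append((i, j))
                weights.append(float(jac))
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    labels = _relabel_by_size(labels)
    modularity = g.modularity(labels, weights=weights)
    return ClusterAssignment(labels, float(modularity)), (idx, dist)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    sizes = np.bincount(labels)
    order = np.argsort(-sizes, kind="mergesort")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return remap[labels]


def embed2d(emb: Embedding, seed: int = 0, component_range: list[int] | None = None,
            n_neighbors: int = 15) -> np.ndarray:
    """UMAP layout of the retained LSI components (visualisation only)."""
    import umap  # deferred: numba compilation is slow at import

    X = emb.matrix(component_range)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells for a 2-D embedding")
    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    init = "spectral" if X.shape[0] >= 10 else "random"
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed, init=init)
    return np.asarray(reducer.fit_transform(X), dtype=float)
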