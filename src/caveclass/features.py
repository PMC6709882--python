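"""The 28 hand-crafted blob features.

One blob (an N x 3 point cloud in nm) is summarized by 28 numbers in a
frozen order, grouped as:

* size (6): ``n_points, range_x, range_y, range_z, hull_volume, density``
  — axis ranges, 3D convex-hull volume (nm^3) and the regularized point
  density ``N / (hull_volume + 1 nm^3)``.
* shape (7): ``lambda1 >= lambda2 >= lambda3`` — eigenvalues of the sample
  covariance of the mean-centered points — plus the Westin shape
  coefficients ``c_linear = (l1-l2)/sum``, ``c_planar = 2(l2-l3)/sum``,
  ``c_spherical = 3*l3/sum`` (summing to 1) and fractional anisotropy
  ``FA = sqrt(3/2) * ||l - mean(l)|| / ||l||``.
* hollowness (5): ``d_min, d_max, d_mean, d_median, d_std`` of the
  point-to-centroid distances (sample standard deviation).
* proximity-network (10): the blob as a graph whose nodes are points and
  whose edges join pairs within a proximity threshold —
  ``n_edges, mean_degree, max_degree, degree_std, mean_clustering,
  char_path_length, global_efficiency, modularity, degree_assortativity,
  graph_density``.

The proximity threshold is global: the smallest distance at which *every*
blob in the dataset forms one connected component, i.e. the maximum over
blobs of the longest edge of the blob's Euclidean minimum spanning tree
(:func:`connectivity_threshold`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import igraph
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path
from scipy.spatial import ConvexHull, QhullError, cKDTree, distance_matrix
from sklearn.base import BaseEstimator, TransformerMixin

#: Frozen feature order; every exported matrix uses exactly these 28 columns.
FEATURE_NAMES: tuple[str, ...] = (
    "n_points", "range_x", "range_y", "range_z", "hull_volume", "density",
    "lambda1", "lambda2", "lambda3", "c_linear", "c_planar", "c_spherical", "fa",
    "d_min", "d_max", "d_mean", "d_median", "d_std",
    "n_edges", "mean_degree", "max_degree", "degree_std", "mean_clustering",
    "char_path_length", "global_efficiency", "modularity",
    "degree_assortativity", "graph_density",
)

N_FEATURES = len(FEATURE_NAMES)

#: +1 nm^3 in the density denominator keeps degenerate (flat) hulls finite.
DENSITY_REGULARIZER_NM3 = 1.0


@dataclass
class ShapeEigen:
    """Eigen-shape summary of a blob's covariance."""

    eigenvalues: np.ndarray  # descending, nm^2
    c_linear: float
    c_planar: float
    c_spherical: float
    fa: float
    degenerate: bool = False  # True when N < 3 and the sentinel (zeros) was used


def compute_shape(points: np.ndarray) -> ShapeEigen:
    """Eigenvalues of the covariance of mean-centered points + Westin/FA.

    For N < 3 a full 3D covariance is not estimable; all shape features are
    set to the zero sentinel and flagged.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n < 3:
        return ShapeEigen(np.zeros(3), 0.0, 0.0, 0.0, 0.0, degenerate=True)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    lam = np.linalg.eigvalsh(cov)[::-1]  # descending
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        return ShapeEigen(lam, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    c_l = (lam[0] - lam[1]) / total
    c_p = 2.0 * (lam[1] - lam[2]) / total
    c_s = 3.0 * lam[2] / total
    lbar = total / 3.0
    denom = np.sqrt((lam**2).sum())
    fa = float(np.sqrt(1.5) * np.sqrt(((lam - lbar) ** 2).sum()) / denom) if denom > 0 else 0.0
    return ShapeEigen(lam, float(c_l), float(c_p), float(c_s), fa)


def compute_size(points: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(n_points, range_x, range_y, range_z, hull_volume, density).

    Hull volume is the 3D convex-hull volume; coplanar/collinear point sets
    get volume 0. Density is N / (hull_volume + 1 nm^3).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    ranges = pts.max(axis=0) - pts.min(axis=0) if n > 0 else np.zeros(3)
    volume = 0.0
    if n >= 4:
        try:
            volume = float(ConvexHull(pts).volume)
        except QhullError:
            volume = 0.0  # degenerate (coplanar/collinear) hull
    density = n / (volume + DENSITY_REGULARIZER_NM3)
    return float(n), float(ranges[0]), float(ranges[1]), float(ranges[2]), volume, density


def compute_hollowness(points: np.ndarray) -> tuple[float, float, float, float, float]:
    """(min, max, mean, median, sample std) of point-to-centroid distances."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n == 1:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    std = float(d.std(ddof=1)) if n > 1 else 0.0
    return float(d.min()), float(d.max()), float(d.mean()), float(np.median(d)), std


def mst_bottleneck(points: np.ndarray) -> float:
    """Longest edge of the Euclidean minimum spanning tree (0 for N <= 1).

    This is the smallest proximity threshold at which the blob's graph is
    one connected component.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n <= 1:
        return 0.0
    dm = distance_matrix(pts, pts)
    mst = minimum_spanning_tree(dm)
    return float(mst.data.max()) if mst.nnz else 0.0


def connectivity_threshold(blobs_points: Iterable[np.ndarray]) -> float:
    """Smallest global threshold making every blob's proximity graph connected:
    the maximum per-blob MST bottleneck."""
    bottlenecks = [mst_bottleneck(p) for p in blobs_points]
    if not bottlenecks:
        raise ValueError("connectivity_threshold requires at least one blob")
    return float(max(bottlenecks))


def build_proximity_graph(points: np.ndarray, threshold_nm: float) -> np.ndarray:
    """Edge list (E x 2 int array, i < j) of pairs within ``threshold_nm``.

    The boundary is inclusive; a relative 1e-9 tolerance keeps pairs at
    exactly the threshold distance in the graph regardless of how the
    distance was rounded when the threshold was derived.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(threshold_nm * (1.0 + 1e-9), output_type="ndarray")
    return pairs.reshape(-1, 2)


def compute_network_features(
    n_nodes: int, edges: np.ndarray
) -> tuple[float, float, float, float, float, float, float, float, float, float]:
    """The 10 proximity-network measures of a connected graph.

    Returns ``(n_edges, mean_degree, max_degree, degree_std, mean_clustering,
    char_path_length, global_efficiency, modularity, degree_assortativity,
    graph_density)``.

    * clustering: mean local clustering coefficient (nodes of degree < 2
      contribute 0);
    * characteristic path length / global efficiency: means of d and 1/d
      over all ordered node pairs;
    * modularity: Q of the deterministic greedy agglomerative partition;
    * assortativity: Pearson correlation of endpoint degrees over directed
      edges, defined as 0 when either endpoint-degree sequence is constant
      (degree-regular graphs), so the feature stays finite;
    * graph_density: 2E / (N (N-1)).

    Raises on a disconnected graph (the construction contract guarantees
    connectivity); a single-node graph returns the all-zero sentinel.
    """
    n = int(n_nodes)
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    if n == 1:
        return (0.0,) * 10
    if n < 1:
        raise ValueError("graph must have at least one node")

    adj = np.zeros((n, n), dtype=np.float64)
    adj[edges[:, 0], edges[:, 1]] = 1.0
    adj[edges[:, 1], edges[:, 0]] = 1.0
    np.fill_diagonal(adj, 0.0)
    m = int(adj.sum() // 2)

    sp = shortest_path(sparse.csr_matrix(adj), method="D", unweighted=True, directed=False)
    if np.isinf(sp).any():
        raise ValueError("proximity graph is disconnected; increase the threshold")

    deg = adj.sum(axis=1)
    mean_deg = float(deg.mean())
    max_deg = float(deg.max())
    deg_std = float(deg.std(ddof=1)) if n > 1 else 0.0

    # local clustering: triangles through each node / possible neighbor pairs
    tri = np.einsum("ij,jk,ki->i", adj, adj, adj) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        local_cc = np.where(possible > 0, tri / possible, 0.0)
    mean_clustering = float(local_cc.mean())

    offdiag = ~np.eye(n, dtype=bool)
    cpl = float(sp[offdiag].mean())
    global_eff = float((1.0 / sp[offdiag]).mean())

    modularity = _greedy_modularity(n, edges, m)

    # degree assortativity: Pearson over endpoint degree pairs (both directions)
    du = np.concatenate([deg[edges[:, 0]], deg[edges[:, 1]]])
    dv = np.concatenate([deg[edges[:, 1]], deg[edges[:, 0]]])
    if m == 0 or du.std() == 0 or dv.std() == 0:
        assortativity = 0.0
    else:
        assortativity = float(np.corrcoef(du, dv)[0, 1])

    graph_density = 2.0 * m / (n * (n - 1))
    return (
        float(m), mean_deg, max_deg, deg_std, mean_clustering,
        cpl, global_eff, modularity, assortativity, graph_density,
    )


def _greedy_modularity(n: int, edges: np.ndarray, m: int) -> float:
    """Modularity Q of the deterministic greedy (fast-greedy agglomerative)
    community partition."""
    if m == 0:
        return 0.0
    g = igraph.Graph(n=n, edges=[(int(a), int(b)) for a, b in edges])
    dendro = g.community_fastgreedy()
    clustering = dendro.as_clustering()
    return float(g.modularity(clustering.membership))


def featurize(points: np.ndarray, threshold_nm: float) -> np.ndarray:
    """The full 28-value feature vector of one blob (see module docstring).

    ``threshold_nm`` is the proximity threshold for the network block; for a
    dataset use :func:`connectivity_threshold` so every graph is connected.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    size = compute_size(pts)
    shape = compute_shape(pts)
    if shape.degenerate and pts.shape[0] >= 3:
        warnings.warn("degenerate covariance; shape features set to the zero sentinel",
                      stacklevel=2)
    hollow = compute_hollowness(pts)
    edges = build_proximity_graph(pts, threshold_nm)
    net = compute_network_features(pts.shape[0], edges)
    vec = np.array(
        [
            *size,
            shape.eigenvalues[0], shape.eigenvalues[1], shape.eigenvalues[2],
            shape.c_linear, shape.c_planar, shape.c_spherical, shape.fa,
            *hollow,
            *net,
        ],
        dtype=float,
    )
    assert vec.shape == (N_FEATURES,)
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(vec))]
        raise ValueError(f"non-finite features {bad}")
    return vec


class BlobFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: list of point clouds -> (n_blobs, 28) feature matrix.

    Parameters
    ----------
    threshold_nm : float, optional
        Proximity threshold for the network block. ``None`` (default)
        learns the global connectivity threshold from the data passed to
        :meth:`fit` (maximum per-blob MST bottleneck, so every proximity
        graph in the fitted dataset is one connected component).
    per_blob_threshold : bool
        Use each blob's own MST bottleneck instead of a global threshold.

    Attributes
    ----------
    threshold_nm_ : float
        The proximity threshold in effect after ``fit`` (nan in per-blob mode).
    feature_names_out_ : tuple of str
        The frozen 28-name order.
    """

    def __init__(self, threshold_nm: Optional[float] = None, per_blob_threshold: bool = False):
        self.threshold_nm = threshold_nm
        self.per_blob_threshold = per_blob_threshold

    def fit(self, X: Sequence[np.ndarray], y=None) -> "BlobFeaturizer":
        if self.per_blob_threshold:
            self.threshold_nm_ = float("nan")
        elif self.threshold_nm is not None:
            self.threshold_nm_ = float(self.threshold_nm)
        else:
            self.threshold_nm_ = connectivity_threshold(X)
        self.feature_names_out_ = FEATURE_NAMES
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        if not hasattr(self, "threshold_nm_"):
            raise RuntimeError("BlobFeaturizer is not fitted")
        rows = []
        for pts in X:
            thr = mst_bottleneck(pts) if self.per_blob_threshold else self.threshold_nm_
            rows.append(featurize(pts, thr))
        return np.vstack(rows) if rows else np.empty((0, N_FEATURES))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)


def featurize_dataset(
    blobs_points: Sequence[np.ndarray],
    threshold_nm: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Feature matrix for a dataset; returns (matrix, threshold used)."""
    fz = BlobFeaturizer(threshold_nm=threshold_nm).fit(blobs_points)
    return fz.transform(blobs_points), fz.threshold_nm_


def features_to_frame(
    matrix: np.ndarray,
    blob_ids: Optional[Sequence[str]] = None,
    cell_ids: Optional[Sequence[str]] = None,
    labels: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with the frozen column names, plus
    optional blob_id / cell_id / class columns for export."""
    df = pd.DataFrame(matrix, columns=list(FEATURE_NAMES))
    if blob_ids is not None:
        df.insert(0, "blob_id", list(blob_ids))
    if cell_ids is not None:
        df.insert(1, "cell_id", list(cell_ids))
    if labels is not None:
        df["class"] = list(labels)
    return df
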