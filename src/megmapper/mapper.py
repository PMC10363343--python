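"""Mapper graph construction for time x channel matrices.

Mapper summarizes a point cloud as a graph in four steps: (i) a filter
maps every time point to a 2-D value (t-SNE or PCA here); (ii) the filter
range is covered by overlapping rectangular bins; (iii) the time points of
each bin are clustered by single-linkage agglomeration under the Euclidean
metric in the ORIGINAL channel space; (iv) the nerve connects two clusters
whenever they share a time point.

Cover geometry: per filter dimension the coordinate range R is covered by
n equal-length closed intervals of length L = R / (n - (n-1)*o), interval
k starting at min + k*L*(1-o), so consecutive intervals overlap by exactly
o*L and the union equals the range. The 2-D bins are all n^2 interval
cross-products. Points on a shared boundary belong to both bins.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .exceptions import DataError, InvalidConfigError, UsageError
from .preprocessing import AnalysisMatrix

logger = logging.getLogger(__name__)

FILTER_METHODS = ("tsne", "pca")


@dataclass(frozen=True)
class MapperParams:
    """One Mapper parameter triple plus filter settings.

    ``n_intervals`` applies per filter dimension (n^2 bins in 2-D);
    ``overlap_pct`` is the overlap percentage between consecutive
    intervals; ``n_clusters`` is the single-linkage dendrogram cut level
    within each bin. The metric is fixed to Euclidean.
    """

    n_intervals: int
    overlap_pct: float
    n_clusters: int
    filter_method: str = "tsne"
    filter_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise InvalidConfigError("n_intervals must be >= 1")
        if not 0 < self.overlap_pct < 100:
            raise InvalidConfigError("overlap_pct must lie in (0, 100)")
        if self.n_clusters < 1:
            raise InvalidConfigError("n_clusters must be >= 1")
        if self.filter_method not in FILTER_METHODS:
            raise InvalidConfigError(f"filter_method must be one of {FILTER_METHODS}")

    @property
    def triple(self) -> tuple[int, float, int]:
        return (self.n_intervals, self.overlap_pct, self.n_clusters)


@dataclass
class Embedding:
    """2-D filter values, one row per time point."""

    coords: np.ndarray
    method: str
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataError("embedding must be a (n x 2) matrix")
        if not np.isfinite(self.coords).all():
            raise DataError("embedding contains non-finite coordinates")


@dataclass
class CoverBin:
    """One rectangular cover element and its member time indices."""

    bin_id: tuple[int, ...]
    bounds: tuple[tuple[float, float], ...]
    members: np.ndarray


@dataclass
class MapperNode:
    node_id: int
    members: np.ndarray
    bin_id: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MapperGraph:
    """Nerve of the clustered cover: nodes are clusters of time points,
    edges join clusters with nonempty member overlap."""

    nodes: list[MapperNode]
    edges: set[tuple[int, int]]
    params: MapperParams
    n_timepoints: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """Convert to an undirected networkx graph with member-count attrs."""
        import networkx as nx

        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.node_id, size=node.size, bin_id=str(node.bin_id))
        g.add_edges_from(self.edges)
        return g


def compute_filter(matrix: AnalysisMatrix, params: MapperParams) -> Embedding:
    """Project the time points to 2-D with the configured filter.

    t-SNE preserves the local Euclidean similarity structure and is the
    production filter; PCA is the deterministic alternative. Perplexity is
    capped below the sample count for small inputs.
    """
    data = np.asarray(matrix.data, dtype=float)
    if data.size == 0:
        raise DataError("empty analysis matrix")
    if not np.isfinite(data).all():
        raise DataError("analysis matrix contains non-finite values")

    if params.filter_method == "pca":
        if data.shape[1] < 2:
            data = np.hstack([data, np.zeros((data.shape[0], 2 - data.shape[1]))])
        coords = PCA(n_components=2, svd_solver="full").fit_transform(data)
    else:
        n = data.shape[0]
        if n < 3:
            raise DataError("t-SNE needs at least 3 rows")
        perplexity = min(30.0, (n - 1) / 3.0)
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=params.filter_seed,
            init="pca",
        ).fit_transform(data)
    return Embedding(coords=coords, method=params.filter_method, seed=params.filter_seed)


def _dimension_intervals(lo: float, hi: float, n: int, o: float) -> list[tuple[float, float]]:
    """Closed equal-length intervals covering [lo, hi] with overlap fraction o."""
    r = hi - lo
    if r == 0:
        logger.warning("degenerate filter range: dimension collapses to a single interval")
        return [(lo, hi)]
    length = r / (n - (n - 1) * o)
    intervals = []
    for k in range(n):
        start = lo + k * length * (1 - o)
        end = start + length
        if k == n - 1:
            end = hi  # close the cover exactly despite rounding
        intervals.append((start, end))
    return intervals


def build_cover(embedding: Embedding, n_intervals: int, overlap_pct: float) -> list[CoverBin]:
    """Cover the embedding with overlapping rectangular bins.

    Returns the full cross-product of per-dimension intervals; bins may be
    empty (they produce no nodes downstream).
    """
    coords = embedding.coords
    if coords.shape[0] == 0:
        raise DataError("empty embedding")
    o = overlap_pct / 100.0
    per_dim = [
        _dimension_intervals(coords[:, d].min(), coords[:, d].max(), n_intervals, o)
        for d in range(coords.shape[1])
    ]
    bins: list[CoverBin] = []
    for idx in itertools.product(*(range(len(iv)) for iv in per_dim)):
        bounds = tuple(per_dim[d][k] for d, k in enumerate(idx))
        mask = np.ones(coords.shape[0], dtype=bool)
        for d, (lo, hi) in enumerate(bounds):
            mask &= (coords[:, d] >= lo) & (coords[:, d] <= hi)
        bins.append(CoverBin(bin_id=idx, bounds=bounds, members=np.flatnonzero(mask)))
    return bins


def cluster_bin(points: np.ndarray, n_clusters: int) -> list[np.ndarray]:
    """Single-linkage clustering of one bin's rows, cut at min(k, size).

    ``points`` are the bin members' rows in the original channel space;
    the returned index sets (local row indices) partition the bin.
    """
    points = np.asarray(points, dtype=float)
    size = points.shape[0]
    if size == 0:
        return []
    if size == 1:
        return [np.array([0])]
    k = min(n_clusters, size)
    z = linkage(points, method="single", metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def build_nerve(
    clusters: list[tuple[tuple[int, ...], np.ndarray]],
    params: MapperParams,
    n_timepoints: int = 0,
) -> MapperGraph:
    """Connect every pair of clusters sharing at least one time index.

    ``clusters`` is a list of (source bin id, global member indices). The
    intersection test is organised per time index: an index occurring in
    several clusters links all of them pairwise, which reproduces the
    brute-force all-pairs test without quadratic scanning.
    """
    nodes = [
        MapperNode(node_id=i, members=np.asarray(m, dtype=int), bin_id=tuple(b))
        for i, (b, m) in enumerate(clusters)
    ]
    containing: dict[int, list[int]] = {}
    for node in nodes:
        for t in node.members:
            containing.setdefault(int(t), []).append(node.node_id)
    edges: set[tuple[int, int]] = set()
    for node_ids in containing.values():
        for a, b in itertools.combinations(node_ids, 2):
            edges.add((a, b) if a < b else (b, a))
    return MapperGraph(nodes=nodes, edges=edges, params=params, n_timepoints=n_timepoints)


def run_mapper(
    matrix: AnalysisMatrix,
    params: MapperParams,
    embedding: Embedding | None = None,
) -> MapperGraph:
    """Full Mapper pipeline: filter -> cover -> per-bin clustering -> nerve.

    A precomputed ``embedding`` may be supplied (the filter depends only on
    the matrix and filter settings, so a parameter sweep can reuse it).
    Deterministic for fixed (matrix, params, filter seed).
    """
    if embedding is None:
        embedding = compute_filter(matrix, params)
    elif embedding.coords.shape[0] != matrix.n_timepoints:
        raise UsageError("embedding row count does not match the matrix")
    cover = build_cover(embedding, params.n_intervals, params.overlap_pct)
    clusters: list[tuple[tuple[int, ...], np.ndarray]] = []
    for cbin in cover:
        if len(cbin.members) == 0:
            continue
        for local in cluster_bin(matrix.data[cbin.members], params.n_clusters):
            clusters.append((cbin.bin_id, cbin.members[local]))
    return build_nerve(clusters, params, n_timepoints=matrix.n_timepoints)
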