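"""Mapper construction of the topological patient-similarity network.

The network is built in four steps:

1. pairwise **normalized-correlation distances** between patients,
   ``d(i, j) = 1 - Pearson(row_i, row_j)`` across the 16 standardized
   features (range [0, 2]);
2. a two-dimensional **lens**: the first two classical (Torgerson) MDS
   coordinates of the distance matrix;
3. an overlapping **cover** of lens space — ``resolution`` intervals per
   axis, each expanded about its center by the ``gain`` factor (gain 2.1
   means each interval is 2.1x its base width, i.e. ~52% overlap between
   neighbours); with ``equalized`` covers, each axis is first passed
   through its empirical CDF so the base intervals hold equal patient
   counts;
4. **partial clustering**: single-linkage within each cover cell, cut by a
   histogram-gap heuristic, each resulting cluster becoming a network node;
   two nodes are joined by an edge iff they share at least one patient.

Nodes in minor connected components are treated as outliers and dropped,
keeping the component with the most patients.  The construction is fully
deterministic: there is no randomness anywhere in the pipeline.

This is an open implementation of the standard Mapper construction; the
commercial TDA platform used to produce the original network is proprietary
and its within-cell clustering rule is undocumented, so the classical
single-linkage + histogram-gap rule is used here.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances and lenses

def normalized_correlation_distance(features: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between patient rows.

    Each row is centered and scaled across its features before the inner
    product, so the distance is invariant to positive affine transforms of
    a row.  Entries are clipped to [0, 2] against rounding; the diagonal is
    exactly zero.

    Raises ``ValueError`` naming the row if any patient has zero variance
    across features (correlation undefined).
    """
    X = np.asarray(getattr(features, "values", features), dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 feature columns")
    if np.isnan(X).any():
        raise ValueError("distance matrix requires a complete (imputed) matrix")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        raise ValueError(f"patient row(s) {zero_rows.tolist()} have zero variance across features")
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def mds_lens(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling lens coordinates.

    Double-centers ``-0.5 * J D^2 J``, takes the top-``k`` eigenpairs with
    positive eigenvalues and returns coordinates ``eigvec * sqrt(eigval)``.
    Negative eigenvalues (the distances need not be Euclidean) are dropped
    with a logged warning.  Sign convention: each axis is oriented so its
    largest-magnitude coordinate is positive, making the output
    deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    B = D ** 2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    B *= -0.5
    # Symmetric eigendecomposition; only the top-k pairs are needed, so for
    # large cohorts a Lanczos solve replaces the full decomposition.
    if n > 1200 and k + 4 < n:
        from scipy.sparse.linalg import eigsh

        eigvals, eigvecs = eigsh(B, k=k + 4, which="LA")
        low, _ = eigsh(B, k=1, which="SA")
        eigvals = np.concatenate([eigvals, low])
        eigvecs = np.concatenate([eigvecs, np.zeros((n, 1))], axis=1)
    else:
        eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals > max(1e-12, 1e-12 * abs(eigvals[0]))).sum()) if n else 0
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive eigenvalue(s); reduce k from {k} to <= {n_pos}")
    if (eigvals < -1e-8 * max(abs(eigvals[0]), 1.0)).any():
        logger.warning("distance matrix is not Euclidean; negative MDS eigenvalues dropped")
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


# ---------------------------------------------------------------------------
# cover

@dataclass
class CoverConfig:
    """Cover parameters: intervals per lens axis, overlap factor, equalization."""

    resolution: int = 25
    gain: float = 2.1
    equalized: bool = True

    def validate(self) -> None:
        if self.resolution < 1:
            raise ValueError(f"resolution must be >= 1, got {self.resolution}")
        if self.gain < 1:
            raise ValueError(f"gain must be >= 1, got {self.gain}")


@dataclass
class CoverCell:
    """One cell of the 2-D cover: its (i, j) interval index and member points."""

    index: tuple[int, ...]
    members: np.ndarray  # patient indices inside the cell


def _axis_positions(x: np.ndarray, equalized: bool) -> np.ndarray:
    """Map one lens axis to [0, 1] cover space.

    Equalized: empirical CDF via mid-ranks, ``(rank - 0.5) / n`` with average
    ranks for ties, so base intervals hold equal counts.  Otherwise min-max
    scaling (a constant axis maps to 0.5).
    """
    if equalized:
        return (rankdata(x, method="average") - 0.5) / x.size
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full(x.size, 0.5)
    return (x - lo) / (hi - lo)


def build_cover(lens: np.ndarray, cfg: CoverConfig | None = None) -> list[CoverCell]:
    """Overlapping rectangular cover of the lens space.

    Each axis gets ``resolution`` base intervals of width 1/resolution in
    [0, 1] (after CDF equalization if enabled); each interval is expanded
    about its center to width ``gain/resolution``.  A cell is the product of
    one interval per axis; membership uses closed intervals; empty cells are
    dropped.  Every point lies in at least one cell for any gain >= 1.
    """
    cfg = cfg or CoverConfig()
    cfg.validate()
    lens = np.asarray(lens, dtype=float)
    if lens.ndim == 1:
        lens = lens[:, None]
    if lens.ndim != 2:
        raise ValueError("lens must be an n x k matrix")
    if not np.isfinite(lens).all():
        raise ValueError("lens values must be finite")
    n, k = lens.shape
    pos = np.column_stack([_axis_positions(lens[:, j], cfg.equalized) for j in range(k)])

    r, half = cfg.resolution, 0.5 * cfg.gain / cfg.resolution
    centers = (np.arange(r) + 0.5) / r
    # per-axis interval membership: n x r boolean
    axis_member = [
        (np.abs(pos[:, j][:, None] - centers[None, :]) <= half + 1e-12)
        for j in range(k)
    ]
    cells: list[CoverCell] = []
    for idx in itertools.product(range(r), repeat=k):
        inside = axis_member[0][:, idx[0]]
        for j in range(1, k):
            inside = inside & axis_member[j][:, idx[j]]
        members = np.flatnonzero(inside)
        if members.size:
            cells.append(CoverCell(index=idx, members=members))
    return cells


# ---------------------------------------------------------------------------
# within-cell clustering

def cluster_cell(member_indices: np.ndarray, D: np.ndarray, bins: int = 10) -> list[np.ndarray]:
    """Split one cover cell into Mapper nodes by partial single linkage.

    Builds the single-linkage dendrogram on the restricted distance
    submatrix and histograms its merge heights into ``bins`` bins over
    [0, max merge height].  The dendrogram is cut at the first empty bin
    that follows an occupied one (a gap in the merge-height distribution);
    if the histogram has no such gap the cell stays one cluster.
    """
    members = np.asarray(member_indices)
    if members.size == 0:
        raise ValueError("cluster_cell requires >= 1 member")
    if members.size == 1:
        return [members.copy()]
    sub = D[np.ix_(members, members)]
    Z = sch.linkage(ssd.squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    h_max = heights.max()
    if h_max <= 0:  # all duplicates
        return [members.copy()]
    counts, edges = np.histogram(heights, bins=bins, range=(0.0, h_max))
    first_occupied = int(np.argmax(counts > 0))
    empty_after = np.flatnonzero((counts == 0) & (np.arange(bins) > first_occupied))
    if empty_after.size == 0:
        return [members.copy()]
    threshold = edges[empty_after[0]]
    labels = sch.fcluster(Z, t=threshold, criterion="distance")
    return [members[labels == lab] for lab in np.unique(labels)]


# ---------------------------------------------------------------------------
# graph assembly

@dataclass
class MapperNode:
    id: int
    members: frozenset[int]
    cell: tuple[int, ...]


@dataclass
class MapperGraph:
    """Mapper network: nodes are patient-index sets, edges share a patient."""

    nodes: list[MapperNode]
    edges: set[tuple[int, int]]
    node_stats: dict[int, dict] = field(default_factory=dict)
    outliers: list[int] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for node in self.nodes:
            G.add_node(node.id, size=len(node.members),
                       members=sorted(node.members), cell=node.cell,
                       **self.node_stats.get(node.id, {}))
        for u, v in self.edges:
            shared = len(self._member_map[u] & self._member_map[v])
            G.add_edge(u, v, weight=shared)
        return G

    @property
    def _member_map(self) -> dict[int, frozenset[int]]:
        return {node.id: node.members for node in self.nodes}

    @property
    def patients(self) -> set[int]:
        out: set[int] = set()
        for node in self.nodes:
            out |= node.members
        return out

    def write_graphml(self, path) -> None:
        G = self.to_networkx()
        for _, attrs in G.nodes(data=True):
            attrs["members"] = ",".join(map(str, attrs["members"]))
            attrs["cell"] = ",".join(map(str, attrs["cell"]))
        nx.write_graphml(G, path)

    def to_json(self) -> dict:
        return {
            "nodes": [
                {"id": node.id, "members": sorted(node.members),
                 "cell": list(node.cell),
                 **self.node_stats.get(node.id, {})}
                for node in self.nodes
            ],
            "edges": sorted(map(list, self.edges)),
            "outliers": sorted(self.outliers),
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def build_graph(clusters: list[tuple[tuple[int, ...], np.ndarray]]) -> MapperGraph:
    """Assemble the network from per-cell clusters.

    ``clusters`` is a list of (cell index, member indices) in cell-major
    order; node ids are assigned in that order.  An edge joins two nodes iff
    their member sets intersect; no self-loops.
    """
    nodes = [
        MapperNode(id=i, members=frozenset(int(m) for m in members), cell=tuple(cell))
        for i, (cell, members) in enumerate(clusters)
    ]
    edges: set[tuple[int, int]] = set()
    # Invert membership so edge detection is linear in total membership.
    by_patient: dict[int, list[int]] = {}
    for node in nodes:
        for p in node.members:
            by_patient.setdefault(p, []).append(node.id)
    for ids in by_patient.values():
        for u, v in itertools.combinations(sorted(ids), 2):
            edges.add((u, v))
    return MapperGraph(nodes=nodes, edges=edges)


def remove_outliers(graph: MapperGraph) -> MapperGraph:
    """Drop nodes outside the main connected component.

    The main component is the one with the most patients (ties broken by
    node count, then lowest node id).  Patients appearing only in removed
    nodes are recorded as outliers; a patient that also sits in a kept node
    is retained.
    """
    if not graph.nodes:
        raise ValueError("cannot remove outliers from an empty graph")
    G = nx.Graph()
    G.add_nodes_from(node.id for node in graph.nodes)
    G.add_edges_from(graph.edges)
    members = graph._member_map
    components = list(nx.connected_components(G))

    def patient_count(comp: set[int]) -> int:
        out: set[int] = set()
        for nid in comp:
            out |= members[nid]
        return len(out)

    main = max(components, key=lambda c: (patient_count(c), len(c), -min(c)))
    kept_nodes = [node for node in graph.nodes if node.id in main]
    kept_patients = set().union(*(node.members for node in kept_nodes))
    all_patients = graph.patients
    outliers = sorted(all_patients - kept_patients)
    kept_ids = {node.id for node in kept_nodes}
    kept_edges = {(u, v) for (u, v) in graph.edges if u in kept_ids and v in kept_ids}
    return MapperGraph(nodes=kept_nodes, edges=kept_edges,
                       node_stats={i: s for i, s in graph.node_stats.items() if i in kept_ids},
                       outliers=outliers)


def color_nodes(graph: MapperGraph, events: np.ndarray) -> dict[int, dict]:
    """Per-node outcome statistics: member count and crude event rate.

    ``events`` is indexed by patient index; every member must have an
    outcome (NaN raises).
    """
    events = np.asarray(events, dtype=float)
    stats: dict[int, dict] = {}
    for node in graph.nodes:
        idx = np.fromiter(node.members, dtype=int)
        ev = events[idx]
        if np.isnan(ev).any():
            raise ValueError(f"node {node.id} has members without an outcome")
        stats[node.id] = {"n_members": int(idx.size), "event_rate": float(ev.mean())}
    graph.node_stats = stats
    return stats


def build_mapper(features, cfg: CoverConfig | None = None,
                 events: np.ndarray | None = None,
                 drop_outliers: bool = True,
                 cluster_bins: int = 10) -> MapperGraph:
    """End-to-end network construction from a standardized feature matrix."""
    D = normalized_correlation_distance(features)
    lens = mds_lens(D, k=2)
    cells = build_cover(lens, cfg)
    clusters: list[tuple[tuple[int, ...], np.ndarray]] = []
    for cell in cells:
        for cluster in cluster_cell(cell.members, D, bins=cluster_bins):
            clusters.append((cell.index, cluster))
    graph = build_graph(clusters)
    if drop_outliers:
        graph = remove_outliers(graph)
    if events is not None:
        color_nodes(graph, events)
    return graph
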