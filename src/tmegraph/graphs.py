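"""Spatial tumor-microenvironment graphs and the 20 per-pair features.

For a pair of histology classes (A, B), the map's 4-connected same-class
tile clusters are reduced to their centroids; these centroids are the nodes
of a simple undirected, unweighted random geometric graph with an edge
whenever two centroids lie within ``radius`` tile units.  From each pair
graph, 20 features are computed in three blocks:

* texture averages (7): mean hematoxylin GLCM contrast, GLCM homogeneity
  and histogram entropy over the member tiles of each class's clusters
  (3 + 3), plus the node-count ratio |A| / (|A| + |B|);
* spectral / local node configuration (7): mean degree, degree variance,
  mean clustering coefficient, adjacency spectral radius, Laplacian
  algebraic connectivity, normalized-Laplacian energy, cross-class edge
  fraction;
* global connectivity (6): Euclidean-MST total length / map diagonal, mean,
  sd and max MST edge length, connected-component fraction of the geometric
  graph, and mean cross-class nearest-neighbor distance.

A pair with either class absent yields a zero vector flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse.csgraph import connected_components as cc_sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform

from .core import BACKGROUND, HistologyMap

TEXTURE_BLOCK_FEATURES = ("glcm_contrast_a0", "glcm_homogeneity_a0", "hist_entropy")

SPECTRAL_FEATURE_NAMES = (
    "mean_degree",
    "degree_variance",
    "mean_clustering",
    "spectral_radius",
    "algebraic_connectivity",
    "norm_laplacian_energy",
    "cross_class_edge_fraction",
)

MST_FEATURE_NAMES = (
    "mst_total_over_diagonal",
    "mst_mean_edge",
    "mst_sd_edge",
    "mst_max_edge",
    "component_fraction",
    "cross_class_mean_nn_distance",
)


def pair_feature_names() -> list[str]:
    names = [f"texA_{f}" for f in TEXTURE_BLOCK_FEATURES]
    names += [f"texB_{f}" for f in TEXTURE_BLOCK_FEATURES]
    names.append("node_count_ratio")
    names += list(SPECTRAL_FEATURE_NAMES)
    names += list(MST_FEATURE_NAMES)
    return names


PAIR_FEATURE_NAMES = pair_feature_names()
assert len(PAIR_FEATURE_NAMES) == 20


@dataclass
class TileCluster:
    """A 4-connected component of same-class grid cells."""

    class_id: int
    members: list[tuple[int, int]]
    centroid: tuple[float, float]  # (x, y) in tile units, cell centers


@dataclass
class TMEGraph:
    """Random geometric graph over cluster centroids of one class pair."""

    coords: np.ndarray  # (n, 2) x, y
    node_class: np.ndarray  # (n,)
    edges: np.ndarray  # (m, 2) index pairs, i < j
    pair: tuple[int, int]
    radius: float

    @property
    def n_nodes(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A


@dataclass
class PairFeatureVector:
    values: np.ndarray  # (20,)
    names: tuple[str, ...]
    pair: tuple[int, int]
    valid: bool


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_EIGHT_CONN = np.ones((3, 3))


def extract_clusters(
    hmap: HistologyMap, class_id: int, connectivity: int = 4
) -> list[TileCluster]:
    """Connected components of one class; centroids at mean cell centers.

    A cell (row r, col c) has its center at (x, y) = (c + 0.5, r + 0.5).
    """
    if class_id == BACKGROUND:
        raise ValueError("background is never a graph class")
    mask = hmap.class_mask(class_id)
    structure = _FOUR_CONN if connectivity == 4 else _EIGHT_CONN
    labeled, n = ndimage.label(mask, structure=structure)
    clusters = []
    for k in range(1, n + 1):
        cells = np.argwhere(labeled == k)
        cx = float(cells[:, 1].mean() + 0.5)
        cy = float(cells[:, 0].mean() + 0.5)
        clusters.append(
            TileCluster(
                class_id=class_id,
                members=[(int(r), int(c)) for r, c in cells],
                centroid=(cx, cy),
            )
        )
    return clusters


def build_geometric_graph(
    clusters_a: list[TileCluster],
    clusters_b: list[TileCluster],
    radius: float,
    pair: tuple[int, int] | None = None,
    cross_class_only: bool = False,
) -> TMEGraph:
    """Edges between centroid pairs within Euclidean ``radius``.

    By default all node pairs (same- or cross-class) may be linked;
    ``cross_class_only`` restricts edges to A-B pairs.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    clusters = list(clusters_a) + list(clusters_b)
    coords = np.array([c.centroid for c in clusters], dtype=float).reshape(-1, 2)
    classes = np.array([c.class_id for c in clusters], dtype=int)
    if pair is None:
        a = clusters_a[0].class_id if clusters_a else BACKGROUND
        b = clusters_b[0].class_id if clusters_b else BACKGROUND
        pair = (a, b)
    n = coords.shape[0]
    edges = []
    if n >= 2:
        D = squareform(pdist(coords))
        for i in range(n):
            for j in range(i + 1, n):
                if D[i, j] <= radius:
                    if cross_class_only and classes[i] == classes[j]:
                        continue
                    edges.append((i, j))
    return TMEGraph(
        coords=coords,
        node_class=classes,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        pair=pair,
        radius=radius,
    )


# ---------------------------------------------------------------------------
# Spectral block


def spectral_node_features(graph: TMEGraph) -> np.ndarray:
    """Seven local-node-configuration features from the geometric graph."""
    n = graph.n_nodes
    out = np.zeros(len(SPECTRAL_FEATURE_NAMES))
    if n == 0:
        return out
    A = graph.adjacency()
    deg = A.sum(axis=1)
    out[0] = deg.mean()
    out[1] = deg.var()
    G = nx.from_numpy_array(A)
    out[2] = nx.average_clustering(G) if n > 0 else 0.0
    if graph.n_edges > 0:
        out[3] = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    if n >= 2:
        L = np.diag(deg) - A
        lam = np.sort(np.linalg.eigvalsh(L))
        out[4] = max(float(lam[1]), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    Ln = np.eye(n) - (dinv[:, None] * A * dinv[None, :])
    out[5] = float(np.mean(np.abs(np.linalg.eigvalsh(Ln) - 1.0)))
    if graph.n_edges > 0:
        cls = graph.node_class
        cross = sum(1 for i, j in graph.edges if cls[i] != cls[j])
        out[6] = cross / graph.n_edges
    return out


# ---------------------------------------------------------------------------
# Global / MST block


def mst_edge_lengths(coords: np.ndarray) -> np.ndarray:
    """Edge lengths of the Euclidean minimum spanning tree."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = coords.shape[0]
    if n <= 1:
        return np.empty(0)
    D = squareform(pdist(coords))
    T = minimum_spanning_tree(D).toarray()
    return T[T > 0]


def mst_features(graph: TMEGraph, map_diagonal: float) -> np.ndarray:
    """Six global connectivity features (MST + component structure)."""
    out = np.zeros(len(MST_FEATURE_NAMES))
    n = graph.n_nodes
    if n <= 1:
        return out
    lengths = mst_edge_lengths(graph.coords)
    if lengths.size:
        out[0] = lengths.sum() / map_diagonal
        out[1] = lengths.mean()
        out[2] = lengths.std()
        out[3] = lengths.max()
    A = graph.adjacency()
    from scipy.sparse import csr_matrix

    n_comp, _ = cc_sparse(csr_matrix(A), directed=False)
    out[4] = n_comp / n
    a, b = graph.pair
    mask_a = graph.node_class == a
    mask_b = graph.node_class == b
    if mask_a.any() and mask_b.any():
        D = cdist(graph.coords[mask_a], graph.coords[mask_b])
        out[5] = float(
            np.concatenate([D.min(axis=1), D.min(axis=0)]).mean()
        )
    return out


# ---------------------------------------------------------------------------
# Pair features


def _texture_block(
    clusters: list[TileCluster],
    tile_features: np.ndarray,
    feature_indices: dict[str, int],
) -> np.ndarray:
    cells = [cell for cl in clusters for cell in cl.members]
    out = np.zeros(len(TEXTURE_BLOCK_FEATURES))
    if not cells:
        return out
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    for k, name in enumerate(TEXTURE_BLOCK_FEATURES):
        vals = tile_features[rows, cols, feature_indices[name]]
        vals = vals[np.isfinite(vals)]
        out[k] = vals.mean() if vals.size else 0.0
    return out


def pair_features(
    hmap: HistologyMap,
    tile_features: np.ndarray,
    class_a: int,
    class_b: int,
    radius: float = 8.0,
    connectivity: int = 4,
    cross_class_only: bool = False,
) -> PairFeatureVector:
    """The 20 spatial features for one unordered histology class pair.

    Slot A is always the lower class id, so pair_features(a, b) and
    pair_features(b, a) agree.  ``tile_features`` is an (rows, cols, 80)
    array aligned with the map grid.
    """
    from .features import DEFAULT_CATALOG

    if class_a == class_b:
        raise ValueError("pair classes must be distinct")
    a, b = sorted((class_a, class_b))
    names = tuple(PAIR_FEATURE_NAMES)
    clusters_a = extract_clusters(hmap, a, connectivity)
    clusters_b = extract_clusters(hmap, b, connectivity)
    if not clusters_a or not clusters_b:
        return PairFeatureVector(np.zeros(20), names, (a, b), valid=False)
    idx = {n: DEFAULT_CATALOG.index(n) for n in TEXTURE_BLOCK_FEATURES}
    tex_a = _texture_block(clusters_a, tile_features, idx)
    tex_b = _texture_block(clusters_b, tile_features, idx)
    ratio = len(clusters_a) / (len(clusters_a) + len(clusters_b))
    graph = build_geometric_graph(
        clusters_a, clusters_b, radius, pair=(a, b), cross_class_only=cross_class_only
    )
    spectral = spectral_node_features(graph)
    mst = mst_features(graph, hmap.diagonal)
    values = np.concatenate([tex_a, tex_b, [ratio], spectral, mst])
    return PairFeatureVector(values, names, (a, b), valid=True)


def pair_feature_matrix(
    patients,
    class_ids: list[int],
    radius: float = 8.0,
    connectivity: int = 4,
    cross_class_only: bool = False,
) -> pd.DataFrame:
    """Patients x (pairs * 20) feature table with named columns.

    ``patients`` is an iterable of objects with ``patient_id``,
    ``label_map`` and ``tile_features``.  All C(n_classes, 2) unordered
    pairs are emitted; pairs missing a class in a patient's map contribute
    zeros (flagged invalid at the vector level).
    """
    pairs = list(combinations(sorted(class_ids), 2))
    columns = [
        f"pair{a}-{b}|{name}" for a, b in pairs for name in PAIR_FEATURE_NAMES
    ]
    rows = []
    index = []
    for p in patients:
        vec = []
        for a, b in pairs:
            pf = pair_features(
                p.label_map, p.tile_features, a, b, radius, connectivity,
                cross_class_only,
            )
            vec.append(pf.values)
        rows.append(np.concatenate(vec))
        index.append(p.patient_id)
    return pd.DataFrame(rows, index=index, columns=columns)


def export_graph_csv(graph: TMEGraph, node_path: str, edge_path: str) -> None:
    nodes = pd.DataFrame(
        {
            "id": np.arange(graph.n_nodes),
            "class": graph.node_class,
            "x": graph.coords[:, 0],
            "y": graph.coords[:, 1],
        }
    )
    nodes.to_csv(node_path, index=False)
    edges = pd.DataFrame(graph.edges, columns=["u", "v"])
    edges.to_csv(edge_path, index=False)
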