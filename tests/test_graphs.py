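"""TME graph construction and the 20 pair features."""

from itertools import combinations

import numpy as np
import pytest

from tmegraph.core import BACKGROUND, HistologyMap
from tmegraph.graphs import (
    PAIR_FEATURE_NAMES,
    TMEGraph,
    build_geometric_graph,
    extract_clusters,
    mst_edge_lengths,
    mst_features,
    pair_feature_matrix,
    pair_features,
    spectral_node_features,
)


def flood_fill_oracle(grid, class_id):
    """Independent stack-based 4-connected component labelling."""
    seen = set()
    comps = []
    H, W = grid.shape
    for r in range(H):
        for c in range(W):
            if grid[r, c] != class_id or (r, c) in seen:
                continue
            stack, comp = [(r, c)], set()
            while stack:
                rr, cc = stack.pop()
                if (rr, cc) in comp:
                    continue
                comp.add((rr, cc))
                for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < H and 0 <= nc < W and grid[nr, nc] == class_id:
                        if (nr, nc) not in comp:
                            stack.append((nr, nc))
            seen |= comp
            comps.append(frozenset(comp))
    return set(comps)


def test_clusters_match_flood_fill_oracle_on_random_maps():
    rng = np.random.default_rng(8)
    for _ in range(20):
        grid = rng.integers(-1, 4, size=(12, 12))
        hmap = HistologyMap(grid=grid)
        for cid in range(4):
            got = {frozenset(c.members) for c in extract_clusters(hmap, cid)}
            assert got == flood_fill_oracle(grid, cid)


def test_cluster_examples_and_centroids():
    grid = np.zeros((4, 4), dtype=int)
    grid[0, 0] = grid[0, 1] = 7
    grid[3, 3] = 7
    clusters = extract_clusters(HistologyMap(grid=grid), 7)
    members = sorted(sorted(c.members) for c in clusters)
    assert members == [[(0, 0), (0, 1)], [(3, 3)]]
    cents = sorted(c.centroid for c in clusters)
    assert cents == [(1.0, 0.5), (3.5, 3.5)]  # cell centers at (col+.5, row+.5)
    assert extract_clusters(HistologyMap(grid=grid), 9) == []
    uni = extract_clusters(HistologyMap(grid=np.full((2, 2), 3)), 3)
    assert len(uni) == 1 and len(uni[0].members) == 4


def _graph_from_points(pts, classes, radius):
    from tmegraph.graphs import TileCluster

    ca = [TileCluster(classes[i], [(0, 0)], tuple(p))
          for i, p in enumerate(pts) if classes[i] == classes[0]]
    cb = [TileCluster(classes[i], [(0, 0)], tuple(p))
          for i, p in enumerate(pts) if classes[i] != classes[0]]
    return build_geometric_graph(ca, cb, radius)


def test_geometric_graph_edge_rule():
    pts = [(0.0, 0.0), (1.0, 0.0), (3.0, 0.0)]
    g = _graph_from_points(pts, [1, 1, 2], radius=1.5)
    assert g.n_edges == 1 and np.array_equal(g.edges[0], [0, 1])
    assert _graph_from_points(pts, [1, 1, 2], radius=0.5).n_edges == 0
    assert _graph_from_points(pts, [1, 1, 2], radius=10).n_edges == 3
    with pytest.raises(ValueError):
        _graph_from_points(pts, [1, 1, 2], radius=0)


def test_spectral_features_on_known_graphs():
    tri = TMEGraph(np.array([[0.0, 0], [1, 0], [0, 1]]), np.array([1, 1, 2]),
                   np.array([[0, 1], [0, 2], [1, 2]]), (1, 2), 2.0)
    f = spectral_node_features(tri)
    assert f[0] == pytest.approx(2.0)  # mean degree
    assert f[1] == pytest.approx(0.0)  # degree variance
    assert f[2] == pytest.approx(1.0)  # clustering
    assert f[3] == pytest.approx(2.0)  # spectral radius
    assert f[4] == pytest.approx(3.0)  # algebraic connectivity of K3
    assert f[6] == pytest.approx(2 / 3)  # cross-class edges

    path = TMEGraph(np.array([[0.0, 0], [1, 0], [2, 0]]), np.array([1, 1, 2]),
                    np.array([[0, 1], [1, 2]]), (1, 2), 1.5)
    f = spectral_node_features(path)
    assert f[3] == pytest.approx(np.sqrt(2))
    assert f[4] == pytest.approx(1.0)

    edgeless = TMEGraph(np.array([[0.0, 0], [5, 5]]), np.array([1, 2]),
                        np.empty((0, 2), int), (1, 2), 0.1)
    f = spectral_node_features(edgeless)
    assert f[0] == 0 and f[2] == 0 and f[4] == 0


def mst_total_oracle(pts):
    """Exhaustive minimum over all spanning trees (n <= 6)."""
    n = len(pts)
    edges = list(combinations(range(n), 2))
    best = np.inf
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        total = 0.0
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
            total += float(np.hypot(*(np.array(pts[u]) - pts[v])))
        if ok and len({find(i) for i in range(n)}) == 1:
            best = min(best, total)
    return best


def test_mst_matches_exhaustive_enumeration():
    rng = np.random.default_rng(10)
    for n in (3, 4, 5, 6):
        for _ in range(5):
            pts = rng.uniform(0, 10, size=(n, 2))
            assert mst_edge_lengths(pts).sum() == pytest.approx(
                mst_total_oracle(pts), abs=1e-9
            )


def test_mst_feature_examples():
    g = TMEGraph(np.array([[0.0, 0], [3, 0], [0, 4]]), np.array([1, 2, 1]),
                 np.empty((0, 2), int), (1, 2), 1.0)
    f = mst_features(g, map_diagonal=10.0)
    assert f[0] == pytest.approx(0.7)  # total 7 over diagonal 10
    assert f[1] == pytest.approx(3.5)
    assert f[3] == pytest.approx(4.0)
    single = TMEGraph(np.array([[1.0, 1]]), np.array([1]),
                      np.empty((0, 2), int), (1, 2), 1.0)
    assert np.all(mst_features(single, 10.0) == 0)
    corners = TMEGraph(np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]),
                       np.array([1, 1, 2, 2]), np.empty((0, 2), int), (1, 2), 1.0)
    assert mst_features(corners, 1.0)[0] == pytest.approx(3.0)


def test_mst_invariant_under_rigid_motion():
    rng = np.random.default_rng(11)
    pts = rng.uniform(0, 10, size=(8, 2))
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = pts @ R.T + np.array([3.0, -2.0])
    assert mst_edge_lengths(pts).sum() == pytest.approx(
        mst_edge_lengths(moved).sum(), abs=1e-9
    )


def test_pair_features_contract(toy_map):
    tf = np.random.default_rng(0).normal(size=(8, 8, 80))
    pf = pair_features(toy_map, tf, 0, 1, radius=4.0)
    assert pf.values.shape == (20,)
    assert pf.valid
    assert tuple(pf.names) == tuple(PAIR_FEATURE_NAMES)
    # unordered pair: slots keyed by the lower class id first
    pf_swapped = pair_features(toy_map, tf, 1, 0, radius=4.0)
    assert np.array_equal(pf.values, pf_swapped.values)
    # determinism
    assert np.array_equal(pf.values, pair_features(toy_map, tf, 0, 1, 4.0).values)
    # absent class
    pf_missing = pair_features(toy_map, tf, 0, 9, radius=4.0)
    assert not pf_missing.valid and np.all(pf_missing.values == 0)
    with pytest.raises(ValueError):
        pair_features(toy_map, tf, 1, 1, radius=4.0)


def test_sixteen_class_catalog_yields_120_pairs(toy_map):
    class P:
        patient_id = "p0"
        label_map = toy_map
        tile_features = np.zeros((8, 8, 80))

    df = pair_feature_matrix([P()], list(range(16)), radius=4.0)
    assert df.shape == (1, 120 * 20)


def test_background_is_never_a_graph_node(toy_map):
    with pytest.raises(ValueError):
        extract_clusters(toy_map, BACKGROUND)
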