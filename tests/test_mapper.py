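import numpy as np
import pytest

from phenomapper import (
    CoverConfig,
    build_cover,
    build_graph,
    build_mapper,
    cluster_cell,
    color_nodes,
    mds_lens,
    normalized_correlation_distance,
    remove_outliers,
)
from phenomapper.mapper import MapperGraph, MapperNode

from .conftest import canonical_graph
from .oracles import brute_mapper


class TestDistance:
    def test_perfect_correlation_is_zero(self):
        D = normalized_correlation_distance(np.array([[1.0, 2, 3], [2, 4, 6]]))
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation_is_two(self):
        D = normalized_correlation_distance(np.array([[1.0, 2, 3], [3, 2, 1]]))
        assert D[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_half(self):
        # rows (1,2,3) and (1,3,2): Pearson r = 1/2, so d = 0.5
        D = normalized_correlation_distance(np.array([[1.0, 2, 3], [1, 3, 2]]))
        assert D[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_symmetry_zero_diag_and_range(self, rng):
        X = rng.normal(size=(20, 16))
        D = normalized_correlation_distance(X)
        np.testing.assert_allclose(D, D.T)
        assert (np.diag(D) == 0).all()
        assert (D >= 0).all() and (D <= 2).all()

    def test_affine_invariance_of_rows(self, rng):
        X = rng.normal(size=(10, 16))
        Y = X * 3.7 + 11.0  # positive affine transform of every row
        np.testing.assert_allclose(normalized_correlation_distance(X),
                                   normalized_correlation_distance(Y), atol=1e-9)

    def test_constant_row_rejected_with_row_index(self):
        X = np.random.default_rng(0).normal(size=(5, 8))
        X[3] = 2.0
        with pytest.raises(ValueError, match="3"):
            normalized_correlation_distance(X)


class TestLens:
    def test_line_recovery(self):
        # collinear points: d(1,2)=d(2,3)=1, d(1,3)=2 -> axis (-1, 0, 1) up to sign
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        lens = mds_lens(D, k=1)
        coords = lens[:, 0]
        assert sorted(np.round(coords, 8)) == [-1.0, 0.0, 1.0]
        assert coords[1] == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_points_identical_rows(self, rng):
        X = rng.normal(size=(6, 10))
        X[4] = X[1]
        lens = mds_lens(normalized_correlation_distance(X), k=2)
        np.testing.assert_allclose(lens[4], lens[1], atol=1e-8)

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(15, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        lens = mds_lens(D, k=2)
        D2 = np.linalg.norm(lens[:, None] - lens[None, :], axis=-1)
        np.testing.assert_allclose(D, D2, atol=1e-8)

    def test_too_few_positive_eigenvalues(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])  # rank-1 configuration
        with pytest.raises(ValueError, match="reduce k"):
            mds_lens(D, k=2)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(12, 16))
        D = normalized_correlation_distance(X)
        a, b = mds_lens(D, 2), mds_lens(D, 2)
        np.testing.assert_array_equal(a, b)
        for j in range(2):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0


class TestCover:
    def test_quantile_partition_gain_one(self, rng):
        x = rng.normal(size=100)
        cells = build_cover(x, CoverConfig(resolution=4, gain=1.0, equalized=True))
        assert len(cells) == 4
        sizes = sorted(len(c.members) for c in cells)
        assert sizes == [25, 25, 25, 25]
        all_members = np.concatenate([c.members for c in cells])
        assert len(set(all_members)) == 100  # disjoint

    def test_gain_expands_membership_at_median(self, rng):
        # two tied central values give an average-rank CDF position of 0.5,
        # which lies inside exactly the intervals centered at 0.375 and 0.625
        # once they are widened to 2.1/4 = 0.525
        x = np.concatenate([rng.uniform(0, 1, 49), [5.0, 5.0], rng.uniform(9, 10, 49)])
        cells = build_cover(x, CoverConfig(resolution=4, gain=2.1, equalized=True))
        mid = [c.index[0] for c in cells if 49 in c.members]
        assert sorted(mid) == [1, 2]

    def test_uniform_equal_width_partition(self):
        x = np.linspace(0, 1, 101)
        cells = build_cover(x, CoverConfig(resolution=4, gain=1.0, equalized=False))
        union = set()
        for c in cells:
            union |= set(c.members)
        assert union == set(range(101))

    @pytest.mark.parametrize("gain", [1.0, 1.5, 2.1, 3.0])
    @pytest.mark.parametrize("equalized", [True, False])
    def test_every_point_covered(self, rng, gain, equalized):
        lens = rng.normal(size=(60, 2))
        cells = build_cover(lens, CoverConfig(resolution=5, gain=gain, equalized=equalized))
        union = set()
        for c in cells:
            union |= set(c.members)
        assert union == set(range(60))

    def test_degenerate_constant_axis(self):
        lens = np.zeros((10, 2))
        cells = build_cover(lens, CoverConfig(resolution=4, gain=1.0, equalized=True))
        union = set()
        for c in cells:
            union |= set(c.members)
        assert union == set(range(10))


class TestClusterCell:
    def test_singleton(self):
        D = np.zeros((1, 1))
        out = cluster_cell(np.array([0]), D)
        assert len(out) == 1 and list(out[0]) == [0]

    def test_two_tight_groups_split(self):
        # groups {0,1,2} and {3,4,5}: diameters 0.1, mutual distance 1.0
        D = np.full((6, 6), 1.0)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    D[i, j] = 0.0 if i == j else 0.1
        out = cluster_cell(np.arange(6), D)
        assert sorted(sorted(c) for c in out) == [[0, 1, 2], [3, 4, 5]]

    def test_all_equal_distances_one_cluster(self):
        D = np.full((5, 5), 0.7)
        np.fill_diagonal(D, 0.0)
        out = cluster_cell(np.arange(5), D)
        assert len(out) == 1

    def test_duplicates_one_cluster(self):
        D = np.zeros((4, 4))
        out = cluster_cell(np.arange(4), D)
        assert len(out) == 1


class TestGraph:
    def test_shared_member_edge(self):
        g = build_graph([((0,), np.array([1, 2])), ((1,), np.array([2, 3]))])
        assert g.edges == {(0, 1)}

    def test_disjoint_no_edge(self):
        g = build_graph([((0,), np.array([1, 2])), ((1,), np.array([3, 4]))])
        assert g.edges == set()

    def test_edges_match_pairwise_intersection_oracle(self, rng):
        for _ in range(20):
            clusters = [((i,), rng.choice(15, size=rng.integers(1, 5), replace=False))
                        for i in range(rng.integers(2, 10))]
            g = build_graph(clusters)
            expected = set()
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    if set(clusters[a][1]) & set(clusters[b][1]):
                        expected.add((a, b))
            assert g.edges == expected


class TestOutliers:
    def _graph(self, member_sets, edges):
        nodes = [MapperNode(id=i, members=frozenset(m), cell=(i,))
                 for i, m in enumerate(member_sets)]
        return MapperGraph(nodes=nodes, edges=set(edges))

    def test_minor_component_flagged(self):
        g = self._graph([set(range(50)), set(range(50, 53))], [])
        out = remove_outliers(g)
        assert out.outliers == [50, 51, 52]
        assert len(out.nodes) == 1

    def test_connected_graph_no_outliers(self):
        g = self._graph([{0, 1}, {1, 2}], [(0, 1)])
        out = remove_outliers(g)
        assert out.outliers == []

    def test_patient_shared_with_kept_node_retained(self):
        # patient 5 is in a removed node and a kept node -> not an outlier
        g = self._graph([{0, 1, 2, 3, 5}, {5, 9}], [])
        out = remove_outliers(g)
        assert 5 not in out.outliers
        assert out.outliers == [9]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(MapperGraph(nodes=[], edges=set()))


class TestColoring:
    def test_event_rate(self):
        g = MapperGraph(nodes=[MapperNode(0, frozenset({0, 1, 2, 3}), (0,))],
                        edges=set())
        stats = color_nodes(g, np.array([1, 0, 1, 1]))
        assert stats[0]["event_rate"] == pytest.approx(0.75)

    def test_all_censored_zero(self):
        g = MapperGraph(nodes=[MapperNode(0, frozenset({0, 1}), (0,))], edges=set())
        assert color_nodes(g, np.zeros(2))[0]["event_rate"] == 0.0

    def test_missing_outcome_rejected(self):
        g = MapperGraph(nodes=[MapperNode(0, frozenset({0, 1}), (0,))], edges=set())
        with pytest.raises(ValueError, match="outcome"):
            color_nodes(g, np.array([1.0, np.nan]))

    def test_rates_match_recount(self, rng):
        members = [frozenset(rng.choice(30, size=5, replace=False)) for _ in range(6)]
        g = MapperGraph(nodes=[MapperNode(i, m, (i,)) for i, m in enumerate(members)],
                        edges=set())
        events = (rng.random(30) < 0.4).astype(float)
        stats = color_nodes(g, events)
        for i, m in enumerate(members):
            assert stats[i]["event_rate"] == pytest.approx(
                sum(events[j] for j in m) / len(m))


class TestWholeMapper:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        X = rng.normal(size=(n, 5))
        resolution = int(rng.integers(2, 5))
        gain = float(rng.choice([1.0, 1.5, 2.1]))
        equalized = bool(rng.integers(0, 2))
        cfg = CoverConfig(resolution=resolution, gain=gain, equalized=equalized)
        graph = build_mapper(X, cfg, drop_outliers=False)
        impl = canonical_graph([(node.cell, node.members) for node in graph.nodes],
                               list(graph.edges))
        nodes, edges = brute_mapper(X, resolution, gain, equalized)
        ref = canonical_graph(nodes, edges)
        assert impl == ref

    def test_permutation_stability(self, rng):
        X = rng.normal(size=(25, 6))
        cfg = CoverConfig(resolution=3, gain=1.5)
        g1 = build_mapper(X, cfg, drop_outliers=False)
        perm = rng.permutation(25)
        g2 = build_mapper(X[perm], cfg, drop_outliers=False)
        # map permuted patient indices back and compare canonical forms
        def canon(graph, relabel=None):
            out = []
            for node in graph.nodes:
                members = node.members if relabel is None else {relabel[m] for m in node.members}
                out.append((node.cell, tuple(sorted(members))))
            return sorted(out)
        assert canon(g1) == canon(g2, relabel={i: p for i, p in enumerate(perm)})
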