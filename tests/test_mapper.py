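"""Cover construction, in-cell clustering, and the nerve graph."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from phenomap.lens import normalized_correlation_distance
from phenomap.mapper import (
    MapperNetwork,
    build_cover,
    build_graph,
    cluster_cell,
)


def brute_force_nerve(g: nx.Graph) -> set:
    """Independent oracle: edges = all node pairs with intersecting members."""
    edges = set()
    for u, v in combinations(g.nodes, 2):
        shared = g.nodes[u]["members"] & g.nodes[v]["members"]
        if shared:
            edges.add((min(u, v), max(u, v), len(shared)))
    return edges


def graph_edges(g: nx.Graph) -> set:
    return {(min(u, v), max(u, v), d["weight"]) for u, v, d in g.edges(data=True)}


class TestBuildCover:
    def test_resolution_one_single_cell(self, rng):
        lens = rng.normal(size=(25, 2))
        cells = build_cover(lens, resolution=1, gain=1.6)
        assert len(cells) == 1
        assert len(cells[0].members) == 25

    def test_quantile_boundaries_and_extension(self):
        # 10 points at lens-1 = 1..10, lens-2 constant; resolution 2, gain 1.6:
        # base split at the median 5.5, each interval widened by 30% per side.
        lens = np.column_stack([np.arange(1.0, 11.0), np.zeros(10)])
        cells = build_cover(lens, resolution=2, gain=1.6, equalized=True)
        axis1 = sorted({(c.interval_1.lo, c.interval_1.hi) for c in cells})
        (lo1, hi1), (lo2, hi2) = axis1
        assert lo1 == pytest.approx(1 - 0.3 * 4.5)
        assert hi1 == pytest.approx(5.5 + 0.3 * 4.5)
        assert lo2 == pytest.approx(5.5 - 0.3 * 4.5)
        assert hi2 == pytest.approx(10 + 0.3 * 4.5)
        # points 5 and 6 fall in the overlap of the two lens-1 intervals
        first = [c for c in cells if c.interval_1.lo == pytest.approx(lo1)]
        second = [c for c in cells if c.interval_1.lo == pytest.approx(lo2)]
        members1 = set().union(*(set(c.members) for c in first))
        members2 = set().union(*(set(c.members) for c in second))
        assert members1 & members2 == {4, 5}  # zero-based positions of 5, 6

    def test_empty_input(self):
        assert build_cover(np.empty((0, 2)), resolution=3) == []

    @pytest.mark.parametrize("equalized", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_every_patient_covered(self, seed, equalized):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 60)
        lens = rng.normal(size=(n, 2))
        cells = build_cover(lens, resolution=int(rng.integers(1, 6)), gain=1.6,
                            equalized=equalized)
        covered = set().union(*(set(c.members) for c in cells))
        assert covered == set(range(n))

    def test_gain_near_one_partitions(self):
        lens = np.column_stack([np.linspace(0, 1, 40), np.zeros(40)])
        cells = build_cover(lens, resolution=4, gain=1.0 + 1e-9, equalized=False)
        counts = np.zeros(40, int)
        seen1 = {}
        for c in cells:
            for m in c.members:
                seen1.setdefault(c.index[0], set()).add(m)
        all_m = [m for s in seen1.values() for m in s]
        assert sorted(all_m) == list(range(40))  # each point in exactly one column


class TestClusterCell:
    def test_two_members_zero_distance(self):
        D = np.zeros((2, 2))
        out = cluster_cell(np.array([0, 1]), D)
        assert len(out) == 1 and set(out[0]) == {0, 1}

    def test_two_tight_pairs_split(self):
        # {a,b} and {c,d} at 0.01 internally, 1.9 across: the merge-height
        # histogram has a long empty run between 0.01 and 1.9
        D = np.full((4, 4), 1.9)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.01
        D[2, 3] = D[3, 2] = 0.01
        out = cluster_cell(np.arange(4), D)
        assert sorted(sorted(c.tolist()) for c in out) == [[0, 1], [2, 3]]

    def test_singleton(self):
        out = cluster_cell(np.array([3]), np.zeros((5, 5)))
        assert len(out) == 1 and out[0].tolist() == [3]

    def test_empty(self):
        assert cluster_cell(np.array([], dtype=int), np.zeros((0, 0))) == []

    def test_members_preserved(self, rng):
        n = 30
        X = rng.normal(size=(n, 5))
        D = normalized_correlation_distance(X)
        members = np.sort(rng.choice(n, size=12, replace=False))
        out = cluster_cell(members, D)
        assert sorted(int(x) for c in out for x in c) == members.tolist()


class TestBuildGraph:
    def test_disjoint_cells_no_edges(self):
        lens = np.column_stack([np.r_[np.zeros(5), np.ones(5) * 10], np.zeros(10)])
        D = np.zeros((10, 10))
        net = MapperNetwork(resolution=2, gain=1.01).fit(lens, distance=D)
        assert net.graph_.number_of_edges() == 0

    def test_shared_patient_edge_weight(self):
        from phenomap.mapper import CoverCell, CoverInterval

        iv = CoverInterval(0, 1, True)
        cells = [CoverCell((0, 0), iv, iv), CoverCell((1, 0), iv, iv)]
        clusters = [[np.array([1, 2])], [np.array([2, 3])]]
        g = build_graph(cells, clusters)
        assert graph_edges(g) == {(0, 1, 1)}

    def test_no_self_loops_and_members_nonempty(self, separated_cohort):
        _, features, _, _ = separated_cohort
        from phenomap import preprocess
        from phenomap.lens import MDSLens

        clean = preprocess.zscore(preprocess.impute_mean(features.iloc[:200]))
        ml = MDSLens().fit(clean)
        net = MapperNetwork(resolution=5).fit(ml.lens_, distance=ml.distance_)
        assert all(len(d["members"]) > 0 for _, d in net.graph_.nodes(data=True))
        assert all(u != v for u, v in net.graph_.edges)

    @pytest.mark.parametrize("seed", range(12))
    def test_nerve_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        X = rng.normal(size=(n, 4))
        lens = rng.normal(size=(n, 2))
        D = normalized_correlation_distance(X)
        net = MapperNetwork(resolution=int(rng.integers(1, 5))).fit(lens, distance=D)
        assert graph_edges(net.graph_) == brute_force_nerve(net.graph_)

    def test_no_patient_lost(self, rng):
        n = 50
        X = rng.normal(size=(n, 5))
        lens = rng.normal(size=(n, 2))
        D = normalized_correlation_distance(X)
        net = MapperNetwork(resolution=4).fit(lens, distance=D)
        members = set().union(*(d["members"] for _, d in net.graph_.nodes(data=True)))
        assert members == set(range(n))

    def test_node_count_monotone_in_resolution(self, separated_cohort):
        from phenomap import preprocess
        from phenomap.lens import MDSLens

        _, features, _, _ = separated_cohort
        clean = preprocess.zscore(preprocess.impute_mean(features.iloc[:300]))
        ml = MDSLens().fit(clean)
        counts = [
            MapperNetwork(resolution=r).fit(ml.lens_, distance=ml.distance_).n_nodes_
            for r in (2, 4, 8)
        ]
        assert counts[0] <= counts[1] <= counts[2]
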