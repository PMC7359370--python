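"""Correlation graphs: binarization, Pearson matrix, metrics vs oracle."""

import itertools

import numpy as np
import pytest

from caensemble.containers import BinnedRaster
from caensemble.graphs import (
    CorrelationGraph,
    CorrelationGraphBuilder,
    binarize_events,
    build_graph,
    correlation_matrix,
    node_metrics,
    pair_distances,
    pair_persistence,
    shuffle_r_thresholds,
)

from tests.conftest import make_train

# ---------------------------------------------------------------------------
# independent brute-force oracle for the node metrics


def brute_force_metrics(n, edges):
    """Metrics by exhaustive enumeration on nodes 0..n-1.

    Intentionally naive: neighbour sets by scanning the edge list,
    components by breadth-first flood fill, clustering by enumerating
    all neighbour pairs.
    """
    neigh = {i: set() for i in range(n)}
    for a, b in edges:
        neigh[a].add(b)
        neigh[b].add(a)
    pair_ratio = {i: len(neigh[i]) / n for i in range(n)}
    clustering = {}
    for i in range(n):
        nb = sorted(neigh[i])
        if len(nb) < 2:
            clustering[i] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2) if b in neigh[a]
        )
        clustering[i] = links / (len(nb) * (len(nb) - 1) / 2)
    seen, member = set(), {}
    for i in range(n):
        if i in seen:
            continue
        comp, frontier = {i}, [i]
        while frontier:
            cur = frontier.pop()
            for j in neigh[cur]:
                if j not in comp:
                    comp.add(j)
                    frontier.append(j)
        seen |= comp
        for j in comp:
            member[j] = 1 if len(comp) >= 3 else 0
    prob = sum(member.values()) / n
    return pair_ratio, clustering, member, prob


def graph_from_edges(n, edges):
    ids = [f"c{i}" for i in range(n)]
    return CorrelationGraph(
        ids, np.zeros((n, n)), {(f"c{a}", f"c{b}") for a, b in edges}
    )


class TestBinarize:
    def test_two_peaks_one_bin_binary(self):
        raster = binarize_events([make_train("a", [0.2, 0.7])], 10.0)
        assert raster.values[0, 0] == 1
        assert raster.values[0].sum() == 1

    def test_bins_half_open(self):
        raster = binarize_events([make_train("a", [1.0])], 10.0)
        assert raster.values[0, 1] == 1 and raster.values[0, 0] == 0

    def test_bin_count(self):
        raster = binarize_events([make_train("a", [])], 180.0)
        assert raster.n_bins == 180

    def test_event_outside_session_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            binarize_events([make_train("a", [200.0])], 180.0)

    def test_mask_drops_columns(self):
        mask = np.zeros(10, dtype=bool)
        mask[3:6] = True
        raster = binarize_events([make_train("a", [3.5, 8.5])], 10.0, mask=mask)
        assert raster.n_bins == 3
        np.testing.assert_array_equal(raster.values[0], [1, 0, 0])


class TestCorrelationMatrix:
    def raster(self, rows):
        return BinnedRaster(np.array(rows), [f"c{i}" for i in range(len(rows))])

    def test_identical_rasters(self):
        r = correlation_matrix(self.raster([[1, 0, 1, 0], [1, 0, 1, 0]]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_anticorrelated(self):
        r = correlation_matrix(self.raster([[1, 0, 1, 0], [0, 1, 0, 1]]))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_zero_covariance_pair(self):
        r = correlation_matrix(self.raster([[1, 1, 0, 0], [1, 0, 1, 0]]))
        assert r[0, 1] == pytest.approx(0.0)

    def test_constant_series_undefined(self):
        r = correlation_matrix(self.raster([[0, 0, 0, 0], [1, 0, 1, 0]]))
        assert np.isnan(r[0, 1])

    def test_matches_numpy_on_random_rasters(self, rng):
        x = (rng.random((6, 50)) < 0.2).astype(int)
        x[x.sum(axis=1) == 0, 0] = 1
        r = correlation_matrix(BinnedRaster(x, [str(i) for i in range(6)]))
        ref = np.corrcoef(x)
        for i in range(6):
            for j in range(i + 1, 6):
                assert r[i, j] == pytest.approx(ref[i, j])


class TestBuildGraph:
    def test_threshold_rules(self):
        r = np.array([[np.nan, 0.5, 0.3], [0.5, np.nan, -0.2],
                      [0.3, -0.2, np.nan]])
        g = build_graph(r, ["a", "b", "c"])
        assert ("a", "b") in g.edges          # 0.5 > 0.3
        assert ("a", "c") not in g.edges      # exactly 0.3: strict rule
        assert len(g.edges) == 1

    def test_nan_never_edges(self):
        r = np.full((3, 3), np.nan)
        g = build_graph(r, ["a", "b", "c"])
        assert g.edges == set()

    def test_edges_invariant_under_reordering(self, poisson_trains):
        raster = binarize_events(poisson_trains, 180.0)
        g1 = build_graph(correlation_matrix(raster), raster.cell_ids,
                         threshold=0.1)
        perm = np.arange(len(poisson_trains))[::-1]
        trains2 = [poisson_trains[i] for i in perm]
        raster2 = binarize_events(trains2, 180.0)
        g2 = build_graph(correlation_matrix(raster2), raster2.cell_ids,
                         threshold=0.1)
        assert g1.edges == g2.edges


class TestNodeMetrics:
    def test_triangle(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        m = node_metrics(g, 3)
        assert all(v == pytest.approx(2 / 3) for v in m.pair_ratio.values())
        assert all(v == 1.0 for v in m.clustering.values())
        assert m.component_probability == 1.0

    def test_star(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        m = node_metrics(g, 4)
        assert m.clustering["c0"] == 0.0
        assert m.component_probability == 1.0

    def test_dyad_in_fov_of_five(self):
        g = graph_from_edges(5, [(0, 1)])
        m = node_metrics(g, 5)
        assert m.component_member["c0"] == 0  # component size 2 < 3
        assert m.component_probability == 0.0
        assert m.pair_ratio["c0"] == pytest.approx(1 / 5)

    def test_empty_graph_zero_metrics(self):
        m = node_metrics(graph_from_edges(4, []), 4)
        assert all(v == 0 for v in m.pair_ratio.values())
        assert m.component_probability == 0.0

    def test_fov_denominator_includes_silent_cells(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        m = node_metrics(g, 10)
        assert m.pair_ratio["c0"] == pytest.approx(0.2)
        assert m.component_probability == pytest.approx(0.3)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 13))
            p = rng.random() * 0.6
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < p
            ]
            m = node_metrics(graph_from_edges(n, edges), n)
            pr, cc, member, prob = brute_force_metrics(n, edges)
            for i in range(n):
                cid = f"c{i}"
                assert m.pair_ratio[cid] == pytest.approx(pr[i])
                assert m.clustering[cid] == pytest.approx(cc[i])
                assert m.component_member[cid] == member[i]
            assert m.component_probability == pytest.approx(prob)


class TestShuffleThresholds:
    def test_identical_trains_significant(self, rng):
        t = np.sort(rng.random(15) * 180)
        trains = [make_train("a", t), make_train("b", t)]
        raster = binarize_events(trains, 180.0)
        b = CorrelationGraphBuilder(mode="shuffle", random_state=0).fit(raster)
        assert ("a", "b") in b.edges_

    def test_same_seed_same_thresholds(self, poisson_trains):
        raster = binarize_events(poisson_trains, 180.0)
        t1 = shuffle_r_thresholds(raster, n_shuffles=200, seed=5)
        t2 = shuffle_r_thresholds(raster, n_shuffles=200, seed=5)
        np.testing.assert_array_equal(t1, t2)

    def test_constant_cell_untestable(self, rng):
        trains = [make_train("a", np.sort(rng.random(8) * 180)),
                  make_train("b", [])]
        raster = binarize_events(trains, 180.0)
        thr = shuffle_r_thresholds(raster, n_shuffles=200, seed=1)
        assert np.isnan(thr[0, 1])

    def test_too_few_shuffles_rejected(self, poisson_trains):
        raster = binarize_events(poisson_trains, 180.0)
        with pytest.raises(ValueError):
            shuffle_r_thresholds(raster, n_shuffles=50)


class TestPersistence:
    def test_ratios(self):
        a = graph_from_edges(5, [(0, 1), (1, 2), (2, 3)])
        same = graph_from_edges(5, [(0, 1), (1, 2), (2, 3)])
        disjoint = graph_from_edges(5, [(0, 4)])
        assert pair_persistence(a, same) == 1.0
        assert pair_persistence(a, disjoint) == 0.0
        b = graph_from_edges(12, [(i, i + 1) for i in range(10)])
        c = graph_from_edges(12, [(0, 1)])
        assert pair_persistence(b, c) == pytest.approx(0.1)

    def test_empty_reference_undefined(self):
        assert pair_persistence(
            graph_from_edges(3, []), graph_from_edges(3, [(0, 1)])
        ) is None


class TestPairDistances:
    def test_euclidean(self):
        g = graph_from_edges(2, [(0, 1)])
        d = pair_distances(g, {"c0": (0, 0), "c1": (3, 4)})
        assert d["correlated"][0] == pytest.approx(5.0)

    def test_colocated(self):
        g = graph_from_edges(3, [(0, 1)])
        d = pair_distances(g, {f"c{i}": (1.0, 1.0) for i in range(3)})
        assert d["mean_correlated"] == 0.0
        assert d["mean_non_correlated"] == 0.0

    def test_clustered_module_is_closer(self, rng):
        # module cells in a tight patch, others spread out
        cents = {f"c{i}": tuple(rng.random(2) * 300) for i in range(12)}
        for i in range(4):
            cents[f"c{i}"] = (150 + rng.random() * 10, 150 + rng.random() * 10)
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        d = pair_distances(graph_from_edges(12, edges), cents)
        assert d["mean_correlated"] < d["mean_non_correlated"]

    def test_missing_centroid_excluded(self):
        g = graph_from_edges(3, [(0, 1)])
        d = pair_distances(g, {"c0": (0, 0), "c1": (1, 0)})
        assert d["excluded"] == ["c2"]
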