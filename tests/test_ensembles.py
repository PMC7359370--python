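"""Partner partitioning, deltas, bias control, freezing, regression."""

import numpy as np
import pytest

from caensemble.containers import SessionTimeline
from caensemble.ensembles import (
    CLASS_NON_PARTNER,
    CLASS_PARTNER,
    CLASS_SHOCK,
    DeltaMetrics,
    PartitionLabels,
    partition_partners,
    partner_bias_control,
    percent_freezing,
    regress_deltas_on_freezing,
    session_deltas,
    state_masks,
)
from caensemble.graphs import (
    CorrelationGraph,
    GraphMetrics,
    binarize_events,
    build_graph,
    correlation_matrix,
)

from tests.conftest import make_train


def graph(n, edges, ids=None):
    ids = ids or [f"c{i}" for i in range(n)]
    return CorrelationGraph(
        ids, np.zeros((n, n)), {(ids[a], ids[b]) for a, b in edges}
    )


class TestPartition:
    def test_partner_via_edge_to_shock(self):
        g = graph(3, [(0, 1)])
        labels = partition_partners(g, {"c0": 1, "c1": 0, "c2": 0})
        assert labels.classes == {
            "c0": CLASS_SHOCK,
            "c1": CLASS_PARTNER,
            "c2": CLASS_NON_PARTNER,
        }

    def test_shock_cells_never_partners(self):
        g = graph(3, [(0, 1)])
        labels = partition_partners(g, {"c0": 1, "c1": 1, "c2": 0})
        assert labels.classes["c1"] == CLASS_SHOCK
        assert labels.cells_in(CLASS_PARTNER) == []

    def test_no_shock_cells_all_non_partners(self):
        g = graph(3, [(0, 1), (1, 2)])
        labels = partition_partners(g, {f"c{i}": 0 for i in range(3)})
        assert set(labels.classes.values()) == {CLASS_NON_PARTNER}

    def test_classes_exhaustive_and_disjoint(self, rng):
        n = 15
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.15]
        flags = {f"c{i}": int(rng.random() < 0.3) for i in range(n)}
        labels = partition_partners(graph(n, edges), flags)
        assert len(labels.classes) == n


def metrics_from(values, session):
    ids = list(values)
    return GraphMetrics(
        cell_ids=ids,
        pair_ratio={c: v[0] for c, v in values.items()},
        clustering={c: v[1] for c, v in values.items()},
        component_member={c: v[2] for c, v in values.items()},
        session=session,
    )


class TestDeltas:
    def test_simple_differences(self):
        m = {
            "A1": metrics_from({"a": (0.2, 0.5, 0), "b": (0.1, 0.0, 1)}, "A1"),
            "A2": metrics_from({"a": (0.5, 0.5, 1), "b": (0.1, 0.2, 1)}, "A2"),
        }
        d = session_deltas(m)
        assert d.deltas["A2"]["pair_ratio"]["a"] == pytest.approx(0.3)
        assert d.deltas["A2"]["component_member"]["a"] == 1
        assert d.deltas["A2"]["clustering"]["b"] == pytest.approx(0.2)

    def test_identical_graphs_zero_deltas(self):
        gm = metrics_from({"a": (0.2, 0.1, 1)}, "A1")
        m = {"A1": gm, "B": metrics_from({"a": (0.2, 0.1, 1)}, "B")}
        d = session_deltas(m)
        assert all(
            v == 0 for table in d.deltas["B"].values() for v in table.values()
        )

    def test_untracked_cells_excluded_and_counted(self):
        m = {
            "A1": metrics_from({"a": (0.1, 0, 0), "b": (0.1, 0, 0)}, "A1"),
            "A2": metrics_from({"a": (0.2, 0, 0), "c": (0.4, 0, 0)}, "A2"),
        }
        d = session_deltas(m)
        assert set(d.deltas["A2"]["pair_ratio"]) == {"a"}
        assert set(d.missing["A2"]) == {"b", "c"}

    def test_no_shared_cells_error(self):
        m = {
            "A1": metrics_from({"a": (0.1, 0, 0)}, "A1"),
            "A2": metrics_from({"b": (0.1, 0, 0)}, "A2"),
        }
        with pytest.raises(ValueError, match="tracked"):
            session_deltas(m)


class TestBiasControl:
    def make_inputs(self, partner_delta, pool_deltas):
        ids = ["p0"] + [f"n{i}" for i in range(len(pool_deltas))]
        classes = {"p0": CLASS_PARTNER}
        classes.update({f"n{i}": CLASS_NON_PARTNER for i in range(len(pool_deltas))})
        # every cell has one A2 edge so the pool is eligible
        n = len(ids) + 1
        edges = {(cid, "hub") for cid in ids}
        g = CorrelationGraph(ids + ["hub"], np.zeros((n, n)), edges)
        table = {"p0": partner_delta}
        table.update({f"n{i}": d for i, d in enumerate(pool_deltas)})
        deltas = DeltaMetrics(
            deltas={"A2": {m: dict(table) for m in
                           ("pair_ratio", "clustering", "component_member")}}
        )
        return PartitionLabels(classes), deltas, g

    def test_extreme_observation_min_p(self):
        labels, deltas, g = self.make_inputs(5.0, [0.0] * 10)
        p = partner_bias_control(labels, deltas, g, n_iter=10_000, seed=0)
        assert p["pair_ratio"] == pytest.approx(1 / 10_001)

    def test_determinism(self):
        labels, deltas, g = self.make_inputs(0.3, list(np.linspace(-1, 1, 9)))
        p1 = partner_bias_control(labels, deltas, g, n_iter=2000, seed=7)
        p2 = partner_bias_control(labels, deltas, g, n_iter=2000, seed=7)
        assert p1 == p2

    def test_no_partners_error(self):
        labels, deltas, g = self.make_inputs(0.0, [0.0])
        labels.classes["p0"] = CLASS_NON_PARTNER
        with pytest.raises(ValueError, match="partner"):
            partner_bias_control(labels, deltas, g)

    def test_exchangeable_labels_uniform_p(self, rng):
        """Random partner labels among eligible cells give uniform p."""
        rejections = 0
        n_sets = 120
        for k in range(n_sets):
            pool = rng.normal(0, 1, 12)
            labels, deltas, g = self.make_inputs(float(rng.normal()), list(pool))
            p = partner_bias_control(
                labels, deltas, g, n_iter=1500, seed=1000 + k
            )
            rejections += p["pair_ratio"] < 0.05
        rate = rejections / n_sets
        se = np.sqrt(0.05 * 0.95 / n_sets)
        assert abs(rate - 0.05) < 4 * se


class TestFreezing:
    def timeline(self, intervals, duration=180.0):
        return SessionTimeline("A2", duration, freezing_intervals=intervals)

    @pytest.mark.parametrize(
        "intervals,expected",
        [([(0.0, 90.0)], 50.0), ([], 0.0), ([(0.0, 180.0)], 100.0)],
    )
    def test_percentages(self, intervals, expected):
        assert percent_freezing(self.timeline(intervals)) == pytest.approx(expected)

    def test_overlapping_intervals_merged(self):
        tl = self.timeline([(0.0, 60.0), (30.0, 90.0)])
        assert percent_freezing(tl) == pytest.approx(50.0)

    def test_window_restriction(self):
        tl = self.timeline([(0.0, 30.0)])
        assert percent_freezing(tl, (0.0, 60.0)) == pytest.approx(50.0)


class TestStateMasks:
    def test_interval_bins_frozen(self):
        tl = SessionTimeline("A2", 30.0, freezing_intervals=[(10.0, 20.0)])
        freeze, nonfreeze = state_masks(tl)
        assert list(np.flatnonzero(freeze)) == list(range(10, 20))
        np.testing.assert_array_equal(freeze, ~nonfreeze)

    def test_no_freezing_all_nonfreeze(self):
        tl = SessionTimeline("A2", 20.0)
        freeze, nonfreeze = state_masks(tl)
        assert not freeze.any() and nonfreeze.all()

    def test_half_bin_rule(self):
        tl = SessionTimeline("A2", 10.0, freezing_intervals=[(2.4, 3.6)])
        freeze, _ = state_masks(tl)
        # bin 2 overlaps 0.6 s (>0.5): frozen; bin 3 overlaps 0.6 s: frozen
        assert freeze[2] and freeze[3] and not freeze[1] and not freeze[4]

    def test_masked_graph_equals_cropped_raster(self, rng):
        trains = [
            make_train(f"c{i}", np.sort(rng.random(12) * 60)) for i in range(6)
        ]
        tl = SessionTimeline("A2", 60.0, freezing_intervals=[(20.0, 40.0)])
        _, nonfreeze = state_masks(tl)
        masked = binarize_events(trains, 60.0, mask=nonfreeze)
        full = binarize_events(trains, 60.0)
        cropped = full.values[:, nonfreeze]
        np.testing.assert_array_equal(masked.values, cropped)
        g1 = build_graph(correlation_matrix(masked), masked.cell_ids)
        from caensemble.containers import BinnedRaster

        g2 = build_graph(
            correlation_matrix(BinnedRaster(cropped, masked.cell_ids)),
            masked.cell_ids,
        )
        assert g1.edges == g2.edges


class TestRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = regress_deltas_on_freezing(0.5 * x + 0.1, x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.1)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            regress_deltas_on_freezing([1.0, 2.0], [0.0, 1.0])

    def test_zero_variance_predictor(self):
        with pytest.raises(ValueError):
            regress_deltas_on_freezing([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_f_statistic_degrees_of_freedom(self, rng):
        x = np.linspace(0, 1, 12)
        y = 0.4 * x + rng.normal(0, 0.05, 12)
        res = regress_deltas_on_freezing(y, x)
        # F = t^2 for simple regression; p from F(1, n-2)
        import scipy.stats as st

        p = 1 - st.f.cdf(res.f_stat, 1, 10)
        assert res.p_value == pytest.approx(p, rel=1e-6)
        assert res.n == 12

    def test_permuted_responses_low_r_squared(self, rng):
        x = np.linspace(0, 1, 12)
        y = 0.5 * x + rng.normal(0, 0.1, 12)
        r2 = []
        for _ in range(100):
            r2.append(regress_deltas_on_freezing(rng.permutation(y), x).r_squared)
        assert np.mean(r2) < 0.15
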