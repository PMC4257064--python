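"""Friction surfaces and least-cost travel time."""

import math

import numpy as np
import pytest

from forestrisk.access import (AccessibilitySurface, FrictionTable,
                               accessibility_index, build_friction,
                               cost_distance, default_friction_table,
                               read_friction_table, write_friction_table)
from forestrisk.grid import Grid, LandscapeStack


def _stack(land_cover, slope=None, roads=None, rivers=None, towns=None,
           categories={0: "forest", 1: "cleared"}):
    st = LandscapeStack()
    st.add("land_cover", Grid(values=np.asarray(land_cover), categories=dict(categories)))
    shape = np.asarray(land_cover).shape
    if slope is not None:
        st.add("slope", Grid(values=np.asarray(slope, dtype=float)))
    for name, layer in [("roads", roads), ("rivers", rivers), ("towns", towns)]:
        if layer is not None:
            st.add(name, Grid(values=np.asarray(layer, dtype=bool)))
    return st


class TestFriction:
    def test_road_cell_at_60kmh_is_0001_min_per_m(self):
        lc = np.zeros((2, 2), np.int64)
        roads = np.zeros((2, 2), bool)
        roads[0, 0] = True
        st = _stack(lc, roads=roads)
        table = FrictionTable(speeds={0: 2.0}, road_speed=60.0)
        cost = build_friction(st, table)
        assert cost.values[0, 0] == pytest.approx(0.001)
        assert cost.values[1, 1] == pytest.approx(60 / (1000 * 2.0))

    def test_flat_slope_penalty_is_one(self):
        assert FrictionTable(speeds={0: 2.0}).slope_penalty(0.0) == 1.0

    def test_doubling_speeds_halves_costs(self):
        rng = np.random.default_rng(3)
        lc = rng.integers(0, 2, (6, 6))
        slope = rng.random((6, 6)) * 20
        st = _stack(lc, slope=slope)
        t1 = FrictionTable(speeds={0: 2.0, 1: 4.0}, road_speed=60, river_speed=10)
        t2 = FrictionTable(speeds={0: 4.0, 1: 8.0}, road_speed=120, river_speed=20)
        c1 = build_friction(st, t1).values
        c2 = build_friction(st, t2).values
        np.testing.assert_allclose(c2, c1 / 2)

    def test_unknown_category_named_in_error(self):
        st = _stack(np.full((2, 2), 7, np.int64), categories={7: "swamp"})
        with pytest.raises(KeyError, match="swamp"):
            build_friction(st, FrictionTable(speeds={0: 2.0}))

    def test_road_overrides_river(self):
        lc = np.zeros((1, 2), np.int64)
        both = np.ones((1, 2), bool)
        st = _stack(lc, roads=both, rivers=both)
        cost = build_friction(st, FrictionTable(speeds={0: 2.0}, road_speed=60, river_speed=10))
        np.testing.assert_allclose(cost.values, 0.001)

    def test_table_file_round_trip(self, tmp_path):
        t = FrictionTable(speeds={0: 2.0, 1: 4.5}, road_speed=55.0, river_speed=9.0,
                          slope_s0=25.0)
        p = tmp_path / "friction.tsv"
        write_friction_table(t, p, {0: "forest", 1: "cleared"})
        back = read_friction_table(p)
        assert back.speeds == t.speeds
        assert (back.road_speed, back.river_speed, back.slope_s0) == (55.0, 9.0, 25.0)


def _nx_oracle(src_mask, cost, cell):
    """Independent shortest-path oracle on the same move graph."""
    import networkx as nx

    h, w = cost.shape
    g = nx.Graph()
    for i in range(h):
        for j in range(w):
            for di, dj in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                ii, jj = i + di, j + dj
                if 0 <= ii < h and 0 <= jj < w:
                    length = cell * math.hypot(di, dj)
                    g.add_edge((i, j), (ii, jj),
                               weight=length * 0.5 * (cost[i, j] + cost[ii, jj]))
    dist = np.full((h, w), np.inf)
    sources = [tuple(x) for x in np.argwhere(src_mask)]
    lengths = nx.multi_source_dijkstra_path_length(g, sources)
    for (i, j), d in lengths.items():
        dist[i, j] = d
    return dist


class TestCostDistance:
    def test_uniform_friction_gives_octile_times(self):
        cost = np.full((7, 7), 0.01)
        src = np.zeros((7, 7), bool)
        src[3, 3] = True
        tt = cost_distance(src, Grid(values=cost)).values
        assert tt[3, 3] == 0.0
        assert tt[3, 6] == pytest.approx(3 * 100 * 0.01)
        assert tt[0, 0] == pytest.approx(3 * 100 * math.sqrt(2) * 0.01)
        assert tt[1, 3] == pytest.approx(2 * 100 * 0.01)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.uniform(0.001, 0.05, (15, 15))
        src = np.zeros((15, 15), bool)
        n_src = rng.integers(1, 4)
        for _ in range(n_src):
            src[rng.integers(15), rng.integers(15)] = True
        got = cost_distance(src, Grid(values=cost)).values
        np.testing.assert_allclose(got, _nx_oracle(src, cost, 100.0), atol=1e-9)

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError, match="no source"):
            cost_distance(np.zeros((3, 3), bool), Grid(values=np.ones((3, 3))))

    def test_adding_a_source_never_increases_time(self, rng):
        cost = rng.uniform(0.001, 0.05, (12, 12))
        src1 = np.zeros((12, 12), bool)
        src1[0, 0] = True
        src2 = src1.copy()
        src2[11, 11] = True
        t1 = cost_distance(src1, Grid(values=cost)).values
        t2 = cost_distance(src2, Grid(values=cost)).values
        assert (t2 <= t1 + 1e-12).all()

    def test_triangle_property_along_move_graph(self, rng):
        cost = rng.uniform(0.001, 0.05, (10, 10))
        g = Grid(values=cost)
        src_a = np.zeros((10, 10), bool)
        src_a[0, 0] = True
        src_b = np.zeros((10, 10), bool)
        src_b[5, 5] = True
        ta = cost_distance(src_a, g).values
        tb = cost_distance(src_b, g).values
        # time(a -> c) <= time(a -> b) + time(b -> c) for every c
        assert (ta <= ta[5, 5] + tb + 1e-9).all()

    def test_corridor_upgrade_strictly_speeds_up_corridor(self):
        lc = np.zeros((9, 9), np.int64)
        roads = np.zeros((9, 9), bool)
        roads[4, :] = True
        towns = np.zeros((9, 9), bool)
        towns[4, 0] = True
        st = _stack(lc, roads=roads, towns=towns)
        dirt = FrictionTable(speeds={0: 2.0}, road_speed=30.0)
        paved = FrictionTable(speeds={0: 2.0}, road_speed=60.0)
        t_dirt = AccessibilitySurface.from_stack(st, dirt).travel_time.values
        t_paved = AccessibilitySurface.from_stack(st, paved).travel_time.values
        corridor = roads.copy()
        corridor[4, 0] = False  # the source itself stays at 0
        assert (t_paved[corridor] < t_dirt[corridor]).all()

    def test_nodata_cells_are_impassable(self):
        cost = np.full((3, 3), 0.01)
        nod = np.zeros((3, 3), bool)
        nod[:, 1] = True  # wall across the middle
        src = np.zeros((3, 3), bool)
        src[1, 0] = True
        tt = cost_distance(src, Grid(values=cost, nodata_mask=nod)).values
        assert np.isinf(tt[:, 2]).all() and np.isinf(tt[:, 1]).all()


class TestAccessibilityIndex:
    def test_limits_and_monotonicity(self, rng):
        t = rng.uniform(0, 500, (8, 8))
        t[0, 0] = 0.0
        g = Grid(values=t)
        idx = accessibility_index(g, tau=100.0).values
        assert idx[0, 0] == 1.0
        assert accessibility_index(Grid(values=np.full((2, 2), 1e9)), tau=1.0).values.max() < 1e-12
        order_t = np.argsort(t.ravel())
        order_i = np.argsort(idx.ravel())[::-1]
        np.testing.assert_array_equal(order_t, order_i)

    def test_default_tau_is_median_travel_time(self):
        t = np.array([[0.0, 50.0], [100.0, 200.0]])
        idx = accessibility_index(Grid(values=t)).values
        tau = np.median([0.0, 50.0, 100.0, 200.0])
        assert idx[1, 0] == pytest.approx(np.exp(-100.0 / tau))

    def test_default_table_covers_categories(self):
        table = default_friction_table({0: "forest", 1: "cleared", 2: "wetland"})
        assert set(table.speeds) == {0, 1, 2}
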