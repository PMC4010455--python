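import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windpath import (
    CostParams,
    PlumeParams,
    angular_deviation,
    build_cost_graph,
    edge_cost,
    plume_concentration,
)
from windpath.costgraph import NEIGHBOR_DIRECTIONS, NEIGHBOR_OFFSETS
from windpath.windfield import WindRaster, decompose_wind
from windpath.synthetic import make_wind


class TestAngularDeviation:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(90, 90, 0), (10, 350, 20), (0, 180, 180), (359, 1, 2), (45, 225, 180)],
    )
    def test_examples(self, a, b, expected):
        assert angular_deviation(a, b) == pytest.approx(expected)

    @given(a=st.floats(-720, 720), b=st.floats(-720, 720))
    @settings(max_examples=100, deadline=None)
    def test_range_and_symmetry(self, a, b):
        d = angular_deviation(a, b)
        assert 0 <= d <= 180
        assert d == pytest.approx(angular_deviation(b, a))


class TestEdgeCost:
    P = CostParams()  # gamma 4, beta 2

    def test_aligned_wind_costs_geometric_length(self):
        # flow toward east along an eastward edge
        assert edge_cost((2, 0), (2, 0), (500, 0), self.P) == pytest.approx(500.0)

    def test_gamma_zero_disables_penalty(self):
        p = CostParams(gamma=0.0)
        cost = edge_cost((0, -3), (1, 1), (500, 500), p)
        assert cost == pytest.approx(500 * math.sqrt(2))

    def test_opposed_wind_hand_value(self):
        # flow toward west, edge toward east: theta=180 at both ends
        assert edge_cost((-2, 0), (-2, 0), (500, 0), self.P) == pytest.approx(2500.0)

    def test_mean_of_endpoint_deviations(self):
        # tail aligned (0 deg), head opposed (180 deg) -> theta_bar 90
        cost = edge_cost((2, 0), (-2, 0), (500, 0), self.P)
        assert cost == pytest.approx(500 * (1 + 4 * 0.25))

    def test_calm_cells_contribute_no_penalty(self):
        p = CostParams()
        both_calm = edge_cost((0, 0), (0, 0), (500, 0), p)
        assert both_calm == pytest.approx(500.0)
        # one calm endpoint: only the windy endpoint's deviation counts,
        # averaged with zero
        one_calm = edge_cost((0, 0), (-2, 0), (500, 0), p)
        assert one_calm == pytest.approx(500 * (1 + 4 * (90 / 180) ** 2))

    def test_speed_weighting_divides_by_mean_speed(self):
        p = CostParams(speed_weighting=True)
        base = edge_cost((2, 0), (2, 0), (500, 0), CostParams())
        weighted = edge_cost((2, 0), (2, 0), (500, 0), p)
        assert weighted == pytest.approx(base / 2.0)

    def test_non_lattice_vector_rejected(self):
        with pytest.raises(ValueError, match="lattice"):
            edge_cost((1, 0), (1, 0), (500, 300), self.P)

    @given(theta=st.floats(0, 180))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_deviation(self, theta):
        # direct check of the law: cost rises with theta_bar
        u1, v1 = decompose_wind(2.0, (270.0 + theta) % 360)
        lo = edge_cost((2, 0), (2, 0), (500, 0), self.P)
        hi = edge_cost((u1, v1), (u1, v1), (500, 0), self.P)
        assert hi >= lo - 1e-12


class TestPlume:
    P = PlumeParams(Q=100.0, H=0.0, u=2.0, sigma_y=50.0, sigma_z=10.0)

    def test_centreline_maximum(self):
        c = plume_concentration(10.0, 0.0, self.P)
        assert c == pytest.approx(100.0 / (math.pi * 2.0 * 50.0 * 10.0))

    def test_upwind_is_zero(self):
        assert plume_concentration(0.0, 0.0, self.P) == 0.0
        assert plume_concentration(-5.0, 0.0, self.P) == 0.0

    def test_gaussian_tail_vanishes(self):
        assert plume_concentration(10.0, 1e6, self.P) == pytest.approx(0.0, abs=1e-30)

    def test_doubling_wind_speed_halves_concentration(self):
        p2 = PlumeParams(Q=100.0, H=0.0, u=4.0, sigma_y=50.0, sigma_z=10.0)
        assert plume_concentration(10, 20, p2) == pytest.approx(
            plume_concentration(10, 20, self.P) / 2
        )

    def test_decreasing_in_crosswind_and_height(self):
        ys = np.array([0.0, 10.0, 30.0, 90.0])
        cs = plume_concentration(10.0, ys, self.P)
        assert np.all(np.diff(cs) < 0)
        elevated = PlumeParams(Q=100.0, H=30.0, u=2.0, sigma_y=50.0, sigma_z=10.0)
        assert plume_concentration(10, 0, elevated) < plume_concentration(10, 0, self.P)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PlumeParams(Q=1, H=0, u=0.0, sigma_y=1, sigma_z=1)
        with pytest.raises(ValueError):
            PlumeParams(Q=1, H=0, u=1.0, sigma_y=-1, sigma_z=1)


class TestBuildCostGraph:
    def test_calm_2x2_isotropic(self):
        from windpath import GridSpec

        grid = GridSpec(0, 0, 500, 2, 2)
        calm = WindRaster(grid=grid, u=np.zeros((2, 2)), v=np.zeros((2, 2)))
        g = build_cost_graph(calm)
        assert g.n_edges == 12
        for r in range(2):
            for c in range(2):
                for _, cost, length in g.out_edges(r, c):
                    assert cost == pytest.approx(length)

    def test_lattice_topology_counts(self, calm_graph):
        assert len(list(calm_graph.out_edges(2, 2))) == 8
        assert len(list(calm_graph.out_edges(0, 0))) == 3
        assert len(list(calm_graph.out_edges(0, 2))) == 5

    def test_every_edge_matches_edge_cost_oracle(self, easterly_graph):
        g = easterly_graph
        field = make_wind("uniform", g.grid, speed=2.0, direction=270.0)
        for r in range(g.grid.n_rows):
            for c in range(g.grid.n_cols):
                for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < g.grid.n_rows and 0 <= c2 < g.grid.n_cols):
                        assert np.isinf(g.costs[k, r, c])
                        continue
                    expected = edge_cost(
                        (field.u[r, c], field.v[r, c]),
                        (field.u[r2, c2], field.v[r2, c2]),
                        (dc * 500.0, dr * 500.0),
                        g.params,
                    )
                    assert g.costs[k, r, c] == pytest.approx(expected)

    def test_upwind_edges_cost_more_than_downwind(self, easterly_graph):
        g = easterly_graph
        k_e = NEIGHBOR_DIRECTIONS.index(90.0)
        k_w = NEIGHBOR_DIRECTIONS.index(270.0)
        interior = g.costs[:, 1:-1, 1:-1]
        assert np.all(interior[k_w] > interior[k_e])

    def test_cost_bounds(self, easterly_graph):
        g = easterly_graph
        for k in range(8):
            finite = np.isfinite(g.costs[k])
            assert np.all(g.costs[k][finite] >= g.lengths[k] - 1e-9)
            assert np.all(g.costs[k][finite] <= g.lengths[k] * (1 + g.params.gamma) + 1e-9)

    def test_rotational_equivariance_quarter_turn(self, small_grid):
        """Rotating a uniform wind by 90° permutes the 8 star costs exactly."""
        g0 = build_cost_graph(make_wind("uniform", small_grid, 2.0, 200.0))
        g90 = build_cost_graph(make_wind("uniform", small_grid, 2.0, 290.0))
        star0 = g0.costs[:, 2, 2]
        star90 = g90.costs[:, 2, 2]
        # direction k in the rotated field costs what direction k-2 cost before
        assert np.allclose(np.roll(star0, 2), star90)

    def test_reversed_graph_swaps_edges(self, easterly_graph):
        g = easterly_graph
        rev = g.reversed()
        for r in range(g.grid.n_rows):
            for c in range(g.grid.n_cols):
                for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < g.grid.n_rows and 0 <= c2 < g.grid.n_cols:
                        kk = (k + 4) % 8
                        assert rev.costs[kk, r2, c2] == pytest.approx(g.costs[k, r, c])

    def test_edge_dataframe_export(self, calm_graph):
        df = calm_graph.to_edge_dataframe()
        assert list(df.columns) == [
            "from_row", "from_col", "to_row", "to_col", "length_m", "cost"
        ]
        assert len(df) == calm_graph.n_edges

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CostParams(gamma=-1)
        with pytest.raises(ValueError):
            CostParams(beta=0)
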