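import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windpath import (
    GridSpec,
    WindObservation,
    decompose_wind,
    fit_mq_rbf,
    interpolate_wind_field,
    recompose_wind,
)
from windpath.windfield import default_shape_c


class TestDecomposeRecompose:
    @pytest.mark.parametrize(
        "speed,direction,expected",
        [
            (2.0, 180.0, (0.0, 2.0)),  # southerly wind blows toward north
            (0.0, 37.0, (0.0, 0.0)),  # calm has no components
            (3.0, 270.0, (3.0, 0.0)),  # westerly blows toward east
        ],
    )
    def test_meteorological_convention(self, speed, direction, expected):
        u, v = decompose_wind(speed, direction, "from")
        assert u == pytest.approx(expected[0], abs=1e-12)
        assert v == pytest.approx(expected[1], abs=1e-12)

    def test_magnitude_preserved(self):
        u, v = decompose_wind(1.65, 93.4, "from")
        assert math.hypot(u, v) == pytest.approx(1.65, rel=1e-12)

    def test_toward_convention_flips_signs(self):
        uf, vf = decompose_wind(2.0, 45.0, "from")
        ut, vt = decompose_wind(2.0, 45.0, "toward")
        assert (ut, vt) == pytest.approx((-uf, -vf))

    @pytest.mark.parametrize(
        "u,v,convention,expected",
        [
            (0.0, 2.0, "from", (2.0, 180.0)),
            (1.0, 1.0, "toward", (math.sqrt(2), 45.0)),
            (0.0, 0.0, "from", (0.0, 0.0)),  # calm maps to direction 0
        ],
    )
    def test_recompose(self, u, v, convention, expected):
        s, d = recompose_wind(u, v, convention)
        assert s == pytest.approx(expected[0], abs=1e-12)
        assert d == pytest.approx(expected[1], abs=1e-12)

    @given(
        speed=st.floats(0.01, 50.0),
        direction=st.floats(0.0, 359.999),
        convention=st.sampled_from(["from", "toward"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, speed, direction, convention):
        s, d = recompose_wind(*decompose_wind(speed, direction, convention), convention)
        assert s == pytest.approx(speed, abs=1e-10)
        assert min(abs(d - direction), 360 - abs(d - direction)) < 1e-8

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            decompose_wind(-1.0, 90.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            decompose_wind(1.0, float("nan"))
        with pytest.raises(ValueError):
            recompose_wind(float("inf"), 0.0)


class TestWindObservation:
    def test_direction_normalised(self):
        assert WindObservation("a", 0, 0, 1.0, 370.0).direction == pytest.approx(10.0)
        assert WindObservation("b", 0, 0, 1.0, -90.0).direction == pytest.approx(270.0)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            WindObservation("a", 0, 0, -0.1, 0.0)
        with pytest.raises(ValueError):
            WindObservation("a", float("nan"), 0, 1.0, 0.0)


class TestMQRBF:
    def test_single_point_coefficient(self):
        model = fit_mq_rbf([(0.0, 0.0)], [5.0], shape_c=2.0)
        assert model.coefficients[0] == pytest.approx(5.0 / 2.0)
        assert model([(0.0, 0.0)])[0] == pytest.approx(5.0)

    def test_three_points_match_manual_elimination(self):
        pts = [(0.0, 0.0), (3.0, 0.0), (0.0, 4.0)]
        vals = [1.0, 2.0, -1.0]
        c = 1.5
        # independent oracle: build the system explicitly and solve it by
        # hand-rolled Gaussian elimination with partial pivoting
        n = 3
        A = [[math.sqrt((pts[i][0] - pts[j][0]) ** 2
                        + (pts[i][1] - pts[j][1]) ** 2 + c * c)
              for j in range(n)] for i in range(n)]
        b = list(vals)
        for col in range(n):
            piv = max(range(col, n), key=lambda r: abs(A[r][col]))
            A[col], A[piv] = A[piv], A[col]
            b[col], b[piv] = b[piv], b[col]
            for r in range(col + 1, n):
                f = A[r][col] / A[col][col]
                for j in range(col, n):
                    A[r][j] -= f * A[col][j]
                b[r] -= f * b[col]
        lam = [0.0] * n
        for r in range(n - 1, -1, -1):
            lam[r] = (b[r] - sum(A[r][j] * lam[j] for j in range(r + 1, n))) / A[r][r]

        model = fit_mq_rbf(pts, vals, shape_c=c)
        assert model.coefficients == pytest.approx(lam, rel=1e-10)

    def test_exact_interpolation_at_centres(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 10_000, size=(12, 2))
        vals = rng.normal(0, 3, size=12)
        model = fit_mq_rbf(pts, vals, shape_c=2_000.0)
        out = model(pts)
        assert np.allclose(out, vals, rtol=1e-8, atol=1e-8 * max(1, np.abs(vals).max()))

    def test_matches_scipy_legacy_rbf(self):
        # independent library route: scipy's multiquadric spans the same
        # function space (scaled basis), so the interpolant is identical
        from scipy.interpolate import Rbf

        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, size=(8, 2))
        vals = rng.normal(size=8)
        c = 30.0
        model = fit_mq_rbf(pts, vals, shape_c=c)
        oracle = Rbf(pts[:, 0], pts[:, 1], vals, function="multiquadric",
                     epsilon=c, smooth=0.0)
        query = rng.uniform(-20, 120, size=(40, 2))
        assert np.allclose(model(query), oracle(query[:, 0], query[:, 1]), atol=1e-8)

    def test_linearity_in_fitted_values(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, size=(6, 2))
        f = rng.normal(size=6)
        g = rng.normal(size=6)
        a, b = 2.5, -1.25
        query = rng.uniform(0, 100, size=(20, 2))
        lhs = fit_mq_rbf(pts, a * f + b * g, 10.0)(query)
        rhs = a * fit_mq_rbf(pts, f, 10.0)(query) + b * fit_mq_rbf(pts, g, 10.0)(query)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_mq_rbf([(0, 0), (0, 0)], [1.0, 2.0], 1.0)

    def test_ill_conditioned_reports_condition(self):
        # nearly coincident points drive the system towards singularity
        pts = [(0.0, 0.0), (1e-9, 0.0), (0.0, 1e-9)]
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            fit_mq_rbf(pts, [1.0, 2.0, 3.0], shape_c=1000.0)

    def test_default_shape_c_is_mean_nn_spacing(self):
        pts = [(0, 0), (100, 0), (100, 40)]
        # nn distances: 100, 40, 40
        assert default_shape_c(pts, fallback=1.0) == pytest.approx((100 + 40 + 40) / 3)


class TestInterpolateWindField:
    def test_stations_reproduced_exactly(self, wind_stations, small_grid):
        field = interpolate_wind_field(wind_stations, small_grid)
        # oracle: refit the two component models independently and compare
        from windpath.windfield import fit_mq_rbf, default_shape_c

        pts = np.array([(o.x, o.y) for o in wind_stations])
        comps = np.array([o.components() for o in wind_stations])
        c = default_shape_c(pts, small_grid.cell_size)
        mu = fit_mq_rbf(pts, comps[:, 0], c)
        mv = fit_mq_rbf(pts, comps[:, 1], c)
        assert np.allclose(mu(pts), comps[:, 0], atol=1e-8)
        assert np.allclose(mv(pts), comps[:, 1], atol=1e-8)
        # and the raster agrees with the component models at cell centres
        X, Y = small_grid.cell_centers()
        cells = np.column_stack([X.ravel(), Y.ravel()])
        assert np.allclose(field.u.ravel(), mu(cells), atol=1e-10)
        assert np.allclose(field.v.ravel(), mv(cells), atol=1e-10)

    def test_station_at_cell_centre_is_exact(self, small_grid):
        obs = [
            WindObservation("a", *small_grid.cell_center(1, 1), 2.0, 45.0),
            WindObservation("b", *small_grid.cell_center(4, 3), 1.0, 200.0),
        ]
        field = interpolate_wind_field(obs, small_grid)
        for o in obs:
            r, c = small_grid.nearest_cell(o.x, o.y)
            u, v = o.components()
            assert field.u[r, c] == pytest.approx(u, abs=1e-8)
            assert field.v[r, c] == pytest.approx(v, abs=1e-8)

    def test_identical_observations_give_constant_direction(self, small_grid):
        # both component surfaces are the same scalar interpolant scaled by
        # u0 and v0, so the direction is uniform even though plain MQ does
        # not reproduce constant magnitudes between stations
        obs = [
            WindObservation(f"s{i}", x, y, 2.0, 135.0)
            for i, (x, y) in enumerate([(500, 500), (2500, 600), (1500, 2400)])
        ]
        field = interpolate_wind_field(obs, small_grid)
        assert np.allclose(field.direction, 135.0, atol=1e-8)
        assert np.all(field.speed > 0)

    def test_two_opposed_stations_stay_finite(self, small_grid):
        obs = [
            WindObservation("a", 500.0, 1500.0, 2.0, 90.0),
            WindObservation("b", 2500.0, 1500.0, 2.0, 270.0),
        ]
        field = interpolate_wind_field(obs, small_grid)
        assert np.all(np.isfinite(field.u)) and np.all(np.isfinite(field.v))

    def test_translation_invariance(self, wind_stations, small_grid):
        field = interpolate_wind_field(wind_stations, small_grid)
        dx, dy = 10_000.0, -3_000.0
        shifted_obs = [
            WindObservation(o.station_id, o.x + dx, o.y + dy, o.speed, o.direction)
            for o in wind_stations
        ]
        shifted_grid = GridSpec(
            small_grid.x_origin + dx, small_grid.y_origin + dy,
            small_grid.cell_size, small_grid.n_rows, small_grid.n_cols,
        )
        shifted = interpolate_wind_field(shifted_obs, shifted_grid)
        assert np.allclose(field.u, shifted.u, atol=1e-8)
        assert np.allclose(field.v, shifted.v, atol=1e-8)

    def test_empty_observations_rejected(self, small_grid):
        with pytest.raises(ValueError):
            interpolate_wind_field([], small_grid)
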