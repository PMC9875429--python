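"""Grid I/O, bilinear interpolation, weight renormalization and lag metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aircrossover.grids import (
    GridField,
    GridStructureError,
    LagSpec,
    OutOfDomainError,
    bilinear_interpolate,
    bilinear_weights,
    interpolate_points,
    lagged_points,
    lagged_value,
    max_8h_mean,
    read_grid,
    renormalize_weights,
    write_grid_csv,
    write_grid_netcdf,
)

from conftest import make_field


class TestGridIO:
    def test_csv_round_trip(self, tmp_path, rng):
        fld = make_field(rng.normal(10, 2, (2, 2, 2)))
        write_grid_csv(fld, tmp_path / "g.csv")
        back = read_grid(tmp_path / "g.csv", "pm25")
        np.testing.assert_allclose(back.values, fld.values)
        assert (back.dates == fld.dates).all()

    def test_netcdf_and_csv_dialects_agree(self, tmp_path, rng):
        fld = make_field(rng.normal(50, 5, (4, 3, 5)))
        write_grid_csv(fld, tmp_path / "g.csv")
        write_grid_netcdf(fld, tmp_path / "g.nc")
        a = read_grid(tmp_path / "g.csv", "pm25")
        b = read_grid(tmp_path / "g.nc", "pm25")
        np.testing.assert_allclose(a.values, b.values)
        assert (a.dates == b.dates).all()
        np.testing.assert_allclose(a.lats, b.lats)

    def test_date_gap_rejected(self):
        dates = np.array(["2015-01-01", "2015-01-03"], dtype="datetime64[D]")
        with pytest.raises(GridStructureError, match="gap"):
            GridField("x", [30.0, 30.1], [110.0, 110.1], dates, np.zeros((2, 2, 2)))

    def test_non_uniform_spacing_rejected(self):
        dates = np.array(["2015-01-01"], dtype="datetime64[D]")
        with pytest.raises(GridStructureError, match="spacing"):
            GridField("x", [30.0, 30.1, 30.35], [110.0, 110.1], dates, np.zeros((1, 3, 2)))


class TestBilinear:
    def test_constant_field_reproduced(self):
        fld = make_field(np.full((1, 3, 3), 7.25))
        assert bilinear_interpolate(fld, 30.07, 110.13, "2015-01-01") == pytest.approx(7.25)

    def test_node_identity(self, affine_field):
        v = bilinear_interpolate(affine_field, 30.2, 110.1, "2015-01-02")
        assert v == pytest.approx(2 * 30.2 + 3 * 110.1 + 1, abs=1e-12)

    def test_affine_field_exact(self, affine_field, rng):
        # bilinear interpolation is exact for fields affine in lat and lon
        for _ in range(20):
            lat = rng.uniform(30.0, 30.3)
            lon = rng.uniform(110.0, 110.3)
            v = bilinear_interpolate(affine_field, lat, lon, "2015-01-01")
            assert v == pytest.approx(2 * lat + 3 * lon + 1, abs=1e-12)

    def test_quadratic_error_shrinks_4x_when_spacing_halved(self):
        # second-order accuracy: halving the spacing divides the error by ~4
        f = lambda la, lo: (la - 30.0) ** 2 + 0.5 * (lo - 110.0) ** 2

        def max_err(spacing, n):
            lats = 30.0 + spacing * np.arange(n)
            lons = 110.0 + spacing * np.arange(n)
            glat, glon = np.meshgrid(lats, lons, indexing="ij")
            fld = make_field(f(glat, glon)[None, :, :], lats=lats, lons=lons)
            pts = np.linspace(lats[0] + spacing / 3, lats[-1] - spacing / 3, 17)
            errs = [
                abs(bilinear_interpolate(fld, la, lo, "2015-01-01") - f(la, lo))
                for la in pts
                for lo in 110.0 + (pts - 30.0)
            ]
            return max(errs)

        e1 = max_err(0.2, 5)
        e2 = max_err(0.1, 9)
        assert e1 / e2 == pytest.approx(4.0, rel=0.15)

    def test_out_of_domain_rejected(self, affine_field):
        with pytest.raises(OutOfDomainError):
            bilinear_interpolate(affine_field, 30.0 - 0.06, 110.1, "2015-01-01")
        with pytest.raises(KeyError):
            bilinear_interpolate(affine_field, 30.1, 110.1, "2015-02-01")

    def test_half_spacing_clamp_uses_edge_pair(self, affine_field):
        # a point just outside the hull is clamped onto the edge cell pair
        v = bilinear_interpolate(affine_field, 30.34, 110.15, "2015-01-01")
        assert v == pytest.approx(2 * 30.3 + 3 * 110.15 + 1, abs=1e-12)
        _, n = interpolate_points(affine_field, [30.34], [110.15], [0])
        assert n[0] == 2

    @given(
        lat=st.floats(30.0, 30.3),
        lon=st.floats(110.0, 110.3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_weights_sum_to_one_and_bounded(self, lat, lon):
        fld = make_field(np.zeros((1, 4, 4)))
        _, _, w = bilinear_weights(fld, lat, lon)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all() and (w <= 1).all()

    def test_result_within_corner_range(self, rng):
        fld = make_field(rng.uniform(0, 100, (1, 4, 4)))
        for _ in range(20):
            la, lo = rng.uniform(30.0, 30.3), rng.uniform(110.0, 110.3)
            v = bilinear_interpolate(fld, la, lo, "2015-01-01")
            assert fld.values.min() - 1e-9 <= v <= fld.values.max() + 1e-9


class TestRenormalize:
    def test_uniform_with_one_missing(self):
        w = renormalize_weights([0.25] * 4, [True, True, True, False])
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3, 0.0])

    def test_all_available_identity(self):
        w0 = np.array([0.1, 0.2, 0.3, 0.4])
        np.testing.assert_array_equal(renormalize_weights(w0, [True] * 4), w0)

    def test_hand_computed_case(self):
        w = renormalize_weights([0.5, 0.3, 0.1, 0.1], [True, True, False, False])
        np.testing.assert_allclose(w, [0.625, 0.375, 0.0, 0.0])

    def test_no_corner_available_signals_missing(self):
        assert renormalize_weights([0.25] * 4, [False] * 4) is None

    def test_renormalized_weights_sum_to_one(self, rng):
        for _ in range(50):
            w = rng.dirichlet(np.ones(4))
            avail = rng.random(4) < 0.6
            out = renormalize_weights(w, avail)
            if out is not None:
                assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_corner_interpolation(self):
        vals = np.full((1, 2, 2), 10.0)
        vals[0, 1, 1] = np.nan
        fld = make_field(vals, lats=[30.0, 30.1], lons=[110.0, 110.1])
        assert bilinear_interpolate(fld, 30.05, 110.05, "2015-01-01") == pytest.approx(10.0)
        vals[0] = np.nan
        fld2 = make_field(vals, lats=[30.0, 30.1], lons=[110.0, 110.1])
        assert np.isnan(bilinear_interpolate(fld2, 30.05, 110.05, "2015-01-01"))


class TestMax8hMean:
    def test_ramp_brute_force(self):
        hourly = np.arange(24.0)
        # independent oracle: enumerate all 17 within-day windows
        oracle = max(np.mean(hourly[i : i + 8]) for i in range(17))
        assert max_8h_mean(hourly) == pytest.approx(oracle) == pytest.approx(19.5)

    def test_constant(self):
        assert max_8h_mean(np.full(24, 3.3)) == pytest.approx(3.3)

    def test_all_missing_and_partial(self):
        assert np.isnan(max_8h_mean(np.full(24, np.nan)))
        h = np.arange(24.0)
        h[20] = np.nan  # windows 13..16 knocked out -> best is hours 12..19? no, 12..19 has nan
        oracle = max(
            np.mean(h[i : i + 8]) for i in range(17) if np.isfinite(h[i : i + 8]).all()
        )
        assert max_8h_mean(h) == pytest.approx(oracle)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            max_8h_mean(np.zeros(23))


class TestLaggedValue:
    dates = np.arange(np.datetime64("2015-01-01"), np.datetime64("2015-01-11"))

    def test_two_day_moving_average(self):
        vals = np.zeros(10)
        vals[8], vals[9] = 20.0, 10.0  # d-1, d0
        got = lagged_value(self.dates, vals, "2015-01-10", LagSpec.moving_average(0, 1))
        assert got == pytest.approx(15.0)

    def test_single_lag_picks_index(self):
        vals = np.zeros(10)
        vals[9], vals[8], vals[7] = 1.0, 2.0, 7.0
        got = lagged_value(self.dates, vals, "2015-01-10", LagSpec.single(2))
        assert got == pytest.approx(7.0)

    def test_five_day_moving_average(self):
        vals = np.zeros(10)
        vals[5:10] = [11.0, 9.0, 7.0, 5.0, 3.0]  # d-4 ... d0
        got = lagged_value(self.dates, vals, "2015-01-10", LagSpec.moving_average(0, 4))
        assert got == pytest.approx(7.0)

    def test_missing_day_in_window_propagates(self):
        vals = np.ones(10)
        vals[8] = np.nan
        assert np.isnan(
            lagged_value(self.dates, vals, "2015-01-10", LagSpec.moving_average(0, 1))
        )

    def test_insufficient_history(self):
        vals = np.ones(10)
        assert np.isnan(
            lagged_value(self.dates, vals, "2015-01-02", LagSpec.moving_average(0, 4))
        )

    def test_ma00_rejected_but_lag_equals_window_of_one(self):
        with pytest.raises(ValueError):
            LagSpec.moving_average(0, 0)
        # a single lag is the degenerate one-day window
        vals = np.arange(10.0)
        a = lagged_value(self.dates, vals, "2015-01-08", LagSpec.single(0))
        assert a == pytest.approx(vals[7])

    def test_lag_spec_parsing(self):
        assert LagSpec.parse("MA 0-1") == LagSpec.moving_average(0, 1)
        assert LagSpec.parse("lag 2") == LagSpec.single(2)
        assert LagSpec.parse("lag0-4") == LagSpec.moving_average(0, 4)


class TestLinearity:
    def test_interpolate_then_lag_commutes(self, rng):
        """Interpolation and lag-averaging are both linear, so they commute."""
        vals = rng.normal(40, 8, (10, 4, 4))
        fld = make_field(vals)
        spec = LagSpec.moving_average(0, 2)
        lat, lon = 30.17, 110.22
        days = np.array(["2015-01-08"], dtype="datetime64[D]")
        a, _ = lagged_points(fld, [lat], [lon], days, spec)
        # lag-average the grid first, then interpolate
        avg = vals[5:8].mean(axis=0)  # days 6,7,8 (indices 5..7) = lags 2..0
        fld2 = make_field(avg[None], start="2015-01-08")
        b = bilinear_interpolate(fld2, lat, lon, "2015-01-08")
        assert a[0] == pytest.approx(b, abs=1e-12)
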