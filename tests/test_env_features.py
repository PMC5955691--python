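"""Predictor construction: temperature windows, rugosity, aggregation,
grain-size conversion and inverse-distance interpolation, each checked
against an independent brute-force oracle where the spec of the operation
allows one."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given
from hypothesis import strategies as st

from thermhab import env_features as ef


def _series(sst, sbt, start="2000-01"):
    """Single-cell monthly series as a (time, lat, lon) dataset."""
    sst = np.asarray(sst, float)
    t = pd.date_range(start, periods=len(sst), freq="MS")
    mk = lambda v: (("time", "lat", "lon"), np.asarray(v, float)[:, None, None])
    return xr.Dataset(
        {"sst": mk(sst), "sbt": mk(sbt)},
        coords={"time": t, "lat": [40.0], "lon": [-70.0]},
    )


class TestSeasonalMean:
    def test_three_month_mean(self):
        ds = _series([0, 10, 12, 14, 0], [0, 1, 2, 3, 0])
        sst, sbt = ef.seasonal_mean(ds, 40.0, -70.0, 2000, 3)
        assert sst == pytest.approx(12.0)
        assert sbt == pytest.approx(2.0)

    def test_january_wraps_into_previous_december(self):
        sst = np.arange(24, dtype=float)
        ds = _series(sst, sst)
        got, _ = ef.seasonal_mean(ds, 40.0, -70.0, 2001, 1)
        assert got == pytest.approx(np.mean(sst[11:14]))  # Dec, Jan, Feb

    def test_constant_series_identity(self):
        ds = _series([7.5] * 12, [3.25] * 12)
        assert ef.seasonal_mean(ds, 40.0, -70.0, 2000, 6) == (7.5, 3.25)

    def test_incomplete_window_rejected(self):
        ds = _series([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            ef.seasonal_mean(ds, 40.0, -70.0, 2000, 1)


class TestAnnualExtremes:
    def test_min_max_over_trailing_year(self):
        sbt = np.arange(1, 13, dtype=float)
        ds = _series(sbt * 2, sbt)
        lo, hi, sst_hi = ef.annual_extremes(ds, 40.0, -70.0, 2000, 12)
        assert (lo, hi, sst_hi) == (1.0, 12.0, 24.0)

    def test_constant_series(self):
        ds = _series([4.0] * 24, [4.0] * 24)
        assert ef.annual_extremes(ds, 40.0, -70.0, 2001, 6) == (4.0, 4.0, 4.0)

    def test_window_shifts_with_haul_month(self):
        vals = np.arange(24, dtype=float)
        ds = _series(vals, vals)
        a = ef.annual_extremes(ds, 40.0, -70.0, 2000, 12)
        b = ef.annual_extremes(ds, 40.0, -70.0, 2001, 1)
        assert b[0] == a[0] + 1 and b[1] == a[1] + 1

    def test_incomplete_window_rejected(self):
        ds = _series([1.0] * 6, [1.0] * 6)
        with pytest.raises(ValueError):
            ef.annual_extremes(ds, 40.0, -70.0, 2000, 6)

    def test_shift_invariance_under_constant_offset(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 3, 24)
        ds = _series(vals, vals)
        ds_shift = _series(vals + 2.5, vals + 2.5)
        a = np.array(ef.annual_extremes(ds, 40.0, -70.0, 2001, 8))
        b = np.array(ef.annual_extremes(ds_shift, 40.0, -70.0, 2001, 8))
        np.testing.assert_allclose(b, a + 2.5)
        s_a = np.array(ef.seasonal_mean(ds, 40.0, -70.0, 2001, 8))
        s_b = np.array(ef.seasonal_mean(ds_shift, 40.0, -70.0, 2001, 8))
        np.testing.assert_allclose(s_b, s_a + 2.5)


def _rugosity_bruteforce(depth):
    """Independent O(n*8) double-loop oracle."""
    n, m = depth.shape
    out = np.full((n, m), np.nan)
    for i in range(n):
        for j in range(m):
            if not np.isfinite(depth[i, j]):
                continue
            diffs = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n and 0 <= jj < m and np.isfinite(depth[ii, jj]):
                        diffs.append(abs(depth[i, j] - depth[ii, jj]))
            if diffs:
                out[i, j] = sum(diffs) / len(diffs)  # sequential, order-stable
    return out


class TestRugosity:
    def test_flat_field_zero(self):
        assert np.all(ef.compute_rugosity(np.full((5, 5), 30.0)) == 0.0)

    def test_uniform_contrast(self):
        depth = np.full((3, 3), 20.0)
        depth[1, 1] = 10.0
        assert ef.compute_rugosity(depth)[1, 1] == pytest.approx(10.0)

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(1)
        depth = rng.uniform(5, 500, (20, 20))
        depth[rng.random((20, 20)) < 0.1] = np.nan  # scattered land
        np.testing.assert_array_equal(
            ef.compute_rugosity(depth), _rugosity_bruteforce(depth)
        )

    def test_nonnegative_and_zero_iff_flat(self):
        rng = np.random.default_rng(2)
        depth = rng.uniform(5, 100, (10, 10))
        rug = ef.compute_rugosity(depth)
        assert np.nanmin(rug) > 0.0


class TestAggregateGrid:
    def test_uniform_block(self):
        assert ef.aggregate_grid(np.full((5, 5), 3.0), 5)[0, 0] == 3.0

    def test_single_outlier_block_mean(self):
        block = np.zeros((5, 5))
        block[4, 4] = 10.0
        assert ef.aggregate_grid(block, 5)[0, 0] == pytest.approx(0.4)

    def test_all_missing_block_stays_missing(self):
        block = np.full((5, 5), np.nan)
        assert np.isnan(ef.aggregate_grid(block, 5)[0, 0])

    def test_partial_missing_block_ignores_nans(self):
        block = np.full((2, 2), np.nan)
        block[0, 0] = 6.0
        assert ef.aggregate_grid(block, 2)[0, 0] == 6.0

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            ef.aggregate_grid(np.zeros((5, 5)), 2)


class TestGsmToPhi:
    @pytest.mark.parametrize(
        "gsm,expected",
        [((0, 0, 100), 7.5), ((100, 0, 0), -2.7), ((0, 100, 0), 1.7),
         ((0, 50, 50), 4.6)],
    )
    def test_reference_compositions(self, gsm, expected):
        assert ef.gsm_to_phi(*gsm) == pytest.approx(expected)

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError):
            ef.gsm_to_phi(10, 10, 10)
        with pytest.raises(ValueError):
            ef.gsm_to_phi(-5, 55, 50)

    @given(
        g=st.floats(0, 100),
        s=st.floats(0, 100),
    )
    def test_bounded_by_pure_type_anchors(self, g, s):
        if g + s > 100:
            g, s = g * 100 / (g + s), s * 100 / (g + s)
        phi = ef.gsm_to_phi(g, s, max(100 - g - s, 0.0))
        assert ef.PHI_GRAVEL - 1e-9 <= phi <= ef.PHI_MUD + 1e-9

    def test_linear_in_composition(self):
        a = np.array([60.0, 30.0, 10.0])
        b = np.array([10.0, 40.0, 50.0])
        mid = 0.5 * a + 0.5 * b
        assert ef.gsm_to_phi(*mid) == pytest.approx(
            0.5 * ef.gsm_to_phi(*a) + 0.5 * ef.gsm_to_phi(*b)
        )


class TestIDW:
    def test_exact_at_data_point(self):
        got = ef.idw_interpolate([40.0, 41.0], [-70.0, -71.0], [5.0, 9.0],
                                 [40.0], [-70.0])
        assert got[0] == 5.0

    def test_symmetry_midpoint(self):
        got = ef.idw_interpolate([40.0, 42.0], [-70.0, -70.0], [0.0, 10.0],
                                 [41.0], [-70.0])
        assert got[0] == pytest.approx(5.0)

    def test_matches_direct_weight_sum_oracle(self):
        rng = np.random.default_rng(3)
        plat = rng.uniform(30, 50, 30)
        plon = rng.uniform(-80, -60, 30)
        vals = rng.uniform(-3, 8, 30)
        tlat = rng.uniform(31, 49, 10)
        tlon = rng.uniform(-79, -61, 10)
        got = ef.idw_interpolate(plat, plon, vals, tlat, tlon)
        for k in range(10):
            d = ef._haversine_km(tlat[k], tlon[k], plat, plon)
            w = d**-2.0
            expected = np.sum(w * vals) / np.sum(w)
            assert got[k] == pytest.approx(expected, rel=1e-10)

    def test_output_is_convex_combination(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, 12)
        got = ef.idw_interpolate(
            rng.uniform(30, 50, 12), rng.uniform(-80, -60, 12), vals,
            rng.uniform(30, 50, 25), rng.uniform(-80, -60, 25),
        )
        assert np.all(got >= vals.min() - 1e-12)
        assert np.all(got <= vals.max() + 1e-12)

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError):
            ef.idw_interpolate([], [], [], [40.0], [-70.0])


class TestAttachPredictors:
    def test_predictors_join_by_location_and_date(self, small_world,
                                                  static_layers):
        depth_g, rug_g, phi_g = static_layers
        w = small_world
        hauls = pd.DataFrame(
            {
                "haul_id": ["a", "b"],
                "year": [2000, 2010],
                "month": [8, 7],
                "lat": [31.0, 34.0],
                "lon": [-79.0, -78.0],
            }
        )
        out = ef.attach_predictors(hauls, w.climate, rug_g, phi_g)
        assert set(ef.PREDICTORS) <= set(out.columns)
        assert np.isfinite(out[ef.PREDICTORS].to_numpy()).all()
        # oracle: scalar API at the same cell/date
        sst_s, sbt_s = ef.seasonal_mean(w.climate, 31.0, -79.0, 2000, 8)
        assert out.loc[0, "sst_seasonal"] == pytest.approx(sst_s)
        assert out.loc[0, "sbt_seasonal"] == pytest.approx(sbt_s)
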