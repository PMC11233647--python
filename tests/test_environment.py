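"""Day length, ice mapping/rasterization, windows and the mixed model."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tusktrack import environment as env
from tusktrack import synthetic as syn


class TestIceCategories:
    def test_six_printed_mid_values(self):
        assert env.ICE_CATEGORY_CONCENTRATION == {
            "Open water": 5, "Very Open Ice Drift": 25, "Open Ice Drift": 55,
            "Close Ice Drift": 80, "Very Close Ice Drift": 95, "Fast Ice": 100,
        }

    def test_unknown_category_lists_vocabulary(self):
        with pytest.raises(KeyError, match="Open water"):
            env.ice_category_to_concentration("Pancake")


class TestDaylight:
    def test_polar_day_and_night(self):
        assert env.daylight_hours(80.0, 15.0, "2015-06-21") == 24.0
        assert env.daylight_hours(80.0, 15.0, "2015-12-21") == 0.0

    def test_equator_equinox_refraction_lengthened(self):
        assert env.daylight_hours(0.0, 0.0, "2015-03-20") == pytest.approx(
            12.1, abs=0.1)

    def test_hemispheric_antisymmetry(self):
        # the -0.833 deg rise/set altitude lengthens the day in BOTH
        # hemispheres, so opposite latitudes sum to slightly more than 24 h
        for date in ("2015-02-01", "2015-05-01", "2015-08-01"):
            total = (env.daylight_hours(45.0, 0.0, date)
                     + env.daylight_hours(-45.0, 0.0, date))
            assert 24.0 < total < 24.6

    def test_vectorized(self):
        out = env.daylight_hours([0.0, 80.0], 0.0,
                                 ["2015-03-20", "2015-06-21"])
        assert out.shape == (2,)
        assert out[1] == 24.0


class TestRasterizeIce:
    def test_single_polygon_uniform(self):
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        chart = syn.IceChart(pd.Timestamp("2015-01-01"),
                             [(poly, "Close Ice Drift")])
        raster = env.rasterize_ice(chart, cell_deg=0.1)
        assert np.nanmax(raster.values) == 80.0
        assert np.nanmin(raster.values) == 80.0

    def test_two_abutting_polygons(self):
        left = Polygon([(0, 0), (0.5, 0), (0.5, 1), (0, 1)])
        right = Polygon([(0.5, 0), (1, 0), (1, 1), (0.5, 1)])
        chart = syn.IceChart(pd.Timestamp("2015-01-01"),
                             [(left, "Open water"), (right, "Fast Ice")])
        raster = env.rasterize_ice(chart, cell_deg=0.1)
        cx, _ = raster.grid.cell_centers()
        vals = raster.values[0]
        assert (vals[cx < 0.5] == 5.0).all()
        assert (vals[cx > 0.5] == 100.0).all()

    def test_matches_generator_field_at_centres(self):
        spec = syn.SyntheticIceFieldSpec(start_date="2016-02-15",
                                         end_date="2016-02-15", noise_sd=0.0)
        (chart,) = syn.simulate_ice_field(spec, 1)
        raster = env.rasterize_ice(chart, cell_deg=0.05)
        cx, cy = raster.grid.cell_centers()
        doy = pd.Timestamp("2016-02-15").dayofyear
        conc = syn.ice_concentration_fraction(spec, cy, doy)
        cats = syn.quantize_ice(conc, spec.category_edges)
        expected = np.array([env.ice_category_to_concentration(c)
                             for c in cats])
        got = raster.values[:, len(cx) // 2]
        ok = ~np.isnan(got)
        assert ok.mean() > 0.95
        assert (got[ok] == expected[ok]).all()


class TestIceSeries:
    @pytest.fixture(scope="class")
    @staticmethod
    def series():
        spec = syn.SyntheticIceFieldSpec(
            start_date="2016-02-01", end_date="2016-02-10",
            missing_dates=["2016-02-05"])
        charts = syn.simulate_ice_field(spec, 2)
        return env.IceChartSeries.from_charts(charts)

    def test_exact_date_used(self, series):
        assert series.nearest("2016-02-03").date == pd.Timestamp("2016-02-03")

    def test_missing_day_tie_goes_earlier(self, series):
        assert series.nearest("2016-02-05").date == pd.Timestamp("2016-02-04")

    def test_no_chart_within_window(self, series):
        assert series.nearest("2016-04-01", max_days=7) is None

    def test_outside_coverage_missing(self, series):
        vals = series.sample("2016-02-03", [150.0], [10.0])
        assert np.isnan(vals).all()

    def test_positions_annotated(self, series):
        ts = pd.to_datetime(["2016-02-02 06:00", "2016-02-08 12:00"])
        vals = env.ice_at_positions(ts, [25.0, 25.0], [81.5, 77.0], series)
        assert not np.isnan(vals).any()
        assert set(vals).issubset(set(float(v) for v in env.ICE_VALUES))
        assert vals[0] > vals[1]  # higher latitude, icier


class TestDailyCoreIce:
    def test_uniform_field(self):
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        chart = syn.IceChart(pd.Timestamp("2015-01-01"),
                             [(poly, "Close Ice Drift")])
        series = env.IceChartSeries.from_charts([chart])
        mean, (lo, hi) = env.daily_core_ice([0.2, 0.8], [0.5, 0.5],
                                            "2015-01-01", series)
        assert (mean, lo, hi) == (80.0, 80.0, 80.0)

    def test_half_and_half(self):
        left = Polygon([(0, 0), (0.5, 0), (0.5, 1), (0, 1)])
        right = Polygon([(0.5, 0), (1, 0), (1, 1), (0.5, 1)])
        chart = syn.IceChart(pd.Timestamp("2015-01-01"),
                             [(left, "Open water"),
                              (right, "Very Close Ice Drift")])
        series = env.IceChartSeries.from_charts([chart])
        mean, _ = env.daily_core_ice([0.2, 0.8], [0.5, 0.5],
                                     "2015-01-01", series)
        assert mean == pytest.approx(50.0)


class TestDepth:
    def test_lookup_and_land(self):
        bathy = syn.synthetic_bathymetry(15.0, 35.0, 76.0, 82.0)
        d = env.depth_at_positions([20.0], [80.0], bathy)
        assert d[0] > 0
        # off-raster is missing
        assert np.isnan(env.depth_at_positions([0.0], [50.0], bathy)).all()

    def test_land_cell_flagged_invalid(self):
        from tusktrack.geo import Grid, Raster
        r = Raster(Grid(0.0, 0.0, 1.0, 1, 2), np.array([[-5.0, 120.0]]))
        out = env.depth_at_positions([0.5, 1.5], [0.5, 0.5], r)
        assert np.isnan(out[0]) and out[1] == 120.0


class TestPremigrationWindows:
    def track_ice(self, values_by_day, departure):
        rows = []
        for day, val in values_by_day.items():
            for hh in (0, 6, 12, 18):
                rows.append({"timestamp": departure + pd.Timedelta(days=day,
                                                                   hours=hh),
                             "ice_pct": val})
        return pd.DataFrame(rows)

    def test_day_boundaries(self):
        dep = pd.Timestamp("2016-01-15")
        w = env.premigration_windows(
            self.track_ice({d: 50.0 for d in range(-14, 0)}, dep), dep)
        assert set(w["day"]) == set(range(-14, 0))
        assert (w.loc[w["day"] == -8, "period"] == "A").all()
        assert (w.loc[w["day"] == -7, "period"] == "B").all()

    def test_constant_ice_equal_periods(self):
        dep = pd.Timestamp("2016-01-15")
        w = env.premigration_windows(
            self.track_ice({d: 42.0 for d in range(-14, 0)}, dep), dep)
        assert w.groupby("period")["ice_pct"].mean().nunique() == 1

    def test_step_increase_at_minus_seven(self):
        dep = pd.Timestamp("2016-01-15")
        vals = {d: (30.0 if d <= -8 else 50.0) for d in range(-14, 0)}
        w = env.premigration_windows(self.track_ice(vals, dep), dep)
        means = w.groupby("period")["ice_pct"].mean()
        assert means["B"] - means["A"] == pytest.approx(20.0)

    def test_no_coverage_rejected(self):
        dep = pd.Timestamp("2016-01-15")
        df = self.track_ice({-20: 10.0}, dep)
        with pytest.raises(ValueError):
            env.premigration_windows(df, dep)


def simulate_premigration(seed, n_id=6, years=(2015, 2016), phi=0.4, sd=8.0,
                          sd_id=4.0, weights=(1.0, 1.4), delta=0.0, base=50.0):
    """AR1 daily ice series per individual-year with a known period effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_id):
        b = rng.normal(0, sd_id)
        for y, w in zip(years, weights):
            e = np.zeros(14)
            e[0] = rng.normal(0, sd * w)
            for d in range(1, 14):
                e[d] = phi * e[d - 1] + rng.normal(
                    0, sd * w * np.sqrt(1 - phi ** 2))
            days = np.arange(-14, 0)
            period = np.where(days <= -8, "A", "B")
            rows.append(pd.DataFrame({
                "id": f"I{i}", "year": y, "day": days, "period": period,
                "ice_pct": base + b + e + delta * (period == "B")}))
    return pd.concat(rows, ignore_index=True)


class TestPremigrationModel:
    def test_recovers_injected_effect(self):
        fit = env.fit_premigration_model(simulate_premigration(1, delta=12.0))
        row = fit.coefficients.set_index("Predictor").loc["Period"]
        assert row["Value"] == pytest.approx(12.0, abs=3 * row["SE"])
        assert fit.period_p_value < 0.05

    def test_ar1_and_weights_estimated(self):
        fit = env.fit_premigration_model(
            simulate_premigration(2, phi=0.6, weights=(1.0, 2.0)))
        assert 0.3 < fit.ar1 < 0.85
        years = sorted(fit.year_weights)
        assert fit.year_weights[years[1]] > fit.year_weights[years[0]]

    def test_single_year_degenerate_design(self):
        fit = env.fit_premigration_model(
            simulate_premigration(3, years=(2015,), weights=(1.0,)))
        assert set(fit.coefficients["Predictor"]) == {"Intercept", "Period"}
        assert fit.converged

    def test_arcsine_transform_path(self):
        df = simulate_premigration(4, base=20.0, sd=4.0, sd_id=2.0)
        fit = env.fit_premigration_model(df, transform="arcsine_sqrt")
        intercept = fit.coefficients["Value"].iloc[0]
        assert 0.0 < intercept < np.pi / 2  # transformed scale, not %

    def test_two_individuals_required(self):
        df = simulate_premigration(5, n_id=1)
        with pytest.raises(ValueError, match="2 individuals"):
            env.fit_premigration_model(df)

    def test_matches_nlme_oracle(self, tmp_path):
        """Independent oracle: the same random-intercept + continuous-AR1 +
        per-year-variance REML model fitted by R nlme gives the same
        coefficients, SEs and variance parameters."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        df = simulate_premigration(8, n_id=5, years=(2015, 2016),
                                   weights=(1.0, 1.6))
        fit = env.fit_premigration_model(df)
        csv = tmp_path / "premig.csv"
        df.to_csv(csv, index=False)
        rcode = f'''
suppressMessages(library(nlme))
d <- read.csv("{csv}")
d$period <- factor(d$period, levels=c("A","B"))
d$year <- factor(d$year)
m <- lme(ice_pct ~ year + period, random = ~1|id,
         correlation = corCAR1(form = ~ day | id/year),
         weights = varIdent(form = ~1|year), data=d, method="REML")
co <- summary(m)$tTable
cat(co[,"Value"], co[,"Std.Error"],
    coef(m$modelStruct$corStruct, unconstrained=FALSE),
    m$sigma, as.numeric(VarCorr(m)[1,2]),
    coef(m$modelStruct$varStruct, unconstrained=FALSE, allCoef=TRUE),
    sep="\\n")
'''
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr[-500:]
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_se = vals[0:3], vals[3:6]
        r_phi, r_sigma, r_sigma_id = vals[6], vals[7], vals[8]
        r_weights = vals[9:11]
        np.testing.assert_allclose(fit.coefficients["Value"], r_beta,
                                   rtol=1e-3)
        np.testing.assert_allclose(fit.coefficients["SE"], r_se, rtol=1e-3)
        assert fit.ar1 == pytest.approx(r_phi, abs=0.005)
        assert fit.sigma == pytest.approx(r_sigma, rel=0.005)
        assert fit.sigma_id == pytest.approx(r_sigma_id, rel=0.01)
        years = sorted(fit.year_weights)
        np.testing.assert_allclose([fit.year_weights[y] for y in years],
                                   r_weights, rtol=0.005)
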