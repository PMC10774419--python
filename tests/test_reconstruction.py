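"""Fleet gap-filling: logistic fits, proxies, and the unmotorized rules."""

import numpy as np
import pandas as pd
import pytest

from effortmap import reconstruction as rc


def logistic(years, K, r, t0):
    return K / (1.0 + np.exp(-r * (np.asarray(years, float) - t0)))


class TestLogisticFit:
    def test_recovers_parameters_from_noise_free_10_points(self):
        years = np.arange(1960, 2010, 5)
        obs = pd.DataFrame({"year": years, "n_vessels": logistic(years, 1000, 0.2, 1980)})
        fits, series = rc.fit_logistic_series(obs, (1950, 2017))
        assert len(fits) == 1
        assert abs(fits[0].K - 1000) / 1000 < 0.01
        assert len(series) == 68
        assert (series["n_vessels"] >= 0).all()

    def test_constant_series_reconstructed_flat(self):
        obs = pd.DataFrame({"year": [1955, 1970, 1990], "n_vessels": [50.0, 50.0, 50.0]})
        fits, series = rc.fit_logistic_series(obs, (1950, 2000))
        np.testing.assert_allclose(series["n_vessels"], 50.0)
        assert fits[0].method == "constant"

    def test_disruption_year_splits_into_independent_segments(self):
        y1 = np.arange(1950, 1975)
        y2 = np.arange(1975, 2001)
        obs = pd.DataFrame(
            {
                "year": np.concatenate([y1, y2]),
                "n_vessels": np.concatenate(
                    [logistic(y1, 800, 0.3, 1960), logistic(y2, 300, 0.25, 1985)]
                ),
            }
        )
        fits, series = rc.fit_logistic_series(obs, (1950, 2000), disruption_years=[1975])
        assert len(fits) == 2
        assert abs(fits[0].K - 800) / 800 < 0.05
        assert abs(fits[1].K - 300) / 300 < 0.05
        # discontinuity allowed at the split
        assert fits[0].year_end == 1974 and fits[1].year_start == 1975

    def test_refitting_complete_noise_free_series_is_idempotent(self):
        years = np.arange(1950, 2001)
        vals = logistic(years, 500, 0.15, 1975)
        obs = pd.DataFrame({"year": years, "n_vessels": vals})
        _, series = rc.fit_logistic_series(obs, (1950, 2000))
        np.testing.assert_allclose(series["n_vessels"], vals, rtol=1e-6)

    def test_fewer_than_three_points_signals_insufficient_data(self):
        obs = pd.DataFrame({"year": [1960, 1990], "n_vessels": [10.0, 20.0]})
        with pytest.raises(rc.InsufficientDataError, match="insufficient"):
            rc.fit_logistic_series(obs, (1950, 2000))

    def test_observed_years_keep_provenance_and_values(self):
        years = np.arange(1950, 2001, 10)
        obs = pd.DataFrame({"year": years, "n_vessels": logistic(years, 900, 0.1, 1970)})
        _, series = rc.fit_logistic_series(obs, (1950, 2000))
        obs_rows = series[series["provenance"] == "observed"]
        assert set(obs_rows["year"]) == set(years)
        np.testing.assert_allclose(
            obs_rows.sort_values("year")["n_vessels"], obs["n_vessels"]
        )


class TestProxyReconstruction:
    def test_population_doubling_doubles_fleet(self):
        cov = pd.DataFrame(
            {"year": np.arange(1990, 2011), "population": np.linspace(1e6, 2e6, 21)}
        )
        partial = pd.DataFrame({"year": [1990], "n_vessels": [100.0]})
        out = rc.reconstruct_by_proxy(partial, cov, (1990, 2010))
        assert out.set_index("year").loc[2010, "n_vessels"] == pytest.approx(200.0)

    def test_constant_population_gives_constant_series(self):
        cov = pd.DataFrame({"year": np.arange(1990, 2001), "population": 5e5})
        partial = pd.DataFrame({"year": [1995], "n_vessels": [42.0]})
        out = rc.reconstruct_by_proxy(partial, cov, (1990, 2000))
        np.testing.assert_allclose(out["n_vessels"], 42.0)

    def test_two_anchors_piecewise_scaling_hand_case(self):
        # pop grows 10%/yr from 1000; anchors NV=100 @1990 and NV=300 @1994.
        # nearest-anchor rule (ties -> earlier): 1990-1992 use the 1990
        # anchor, 1993-1994 the 1994 anchor.
        pop = 1000 * 1.1 ** np.arange(5)
        cov = pd.DataFrame({"year": np.arange(1990, 1995), "population": pop})
        partial = pd.DataFrame({"year": [1990, 1994], "n_vessels": [100.0, 300.0]})
        out = rc.reconstruct_by_proxy(partial, cov, (1990, 1994)).set_index("year")
        assert out.loc[1991, "n_vessels"] == pytest.approx(100 * pop[1] / pop[0])
        assert out.loc[1992, "n_vessels"] == pytest.approx(100 * pop[2] / pop[0])  # tie -> 1990
        assert out.loc[1993, "n_vessels"] == pytest.approx(300 * pop[3] / pop[4])
        assert out.loc[1994, "n_vessels"] == pytest.approx(300.0)

    def test_no_anchor_raises(self):
        cov = pd.DataFrame({"year": [1990, 1991], "population": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no data for proxy"):
            rc.reconstruct_by_proxy(pd.DataFrame(columns=["year", "n_vessels"]), cov, (1990, 1991))


class TestUnmotorized:
    def _cov(self, years, growth):
        return pd.DataFrame({"year": years, "population": 1e5 * (1 + growth) ** (years - years[0])})

    def test_flat_population_and_motorized_gives_constant(self):
        years = np.arange(1975, 1986)
        cov = self._cov(years, 0.0)
        motor = pd.DataFrame({"year": years, "n_vessels": 500.0})
        partial = pd.DataFrame({"year": [1978], "n_vessels": [200.0]})
        out = rc.reconstruct_unmotorized(partial, motor, cov, (1975, 1985), y_max=1980)
        np.testing.assert_allclose(out["n_vessels"], 200.0)

    def test_rise_then_mirror_motorized_decline_hand_case(self):
        # 6-year toy: pop +2%/yr to Y_max=1980, motorized +10%/yr after,
        # coupling -1 -> unmotorized falls 10%/yr after the peak
        years = np.arange(1977, 1983)
        cov = self._cov(years, 0.02)
        motor = pd.DataFrame({"year": years, "n_vessels": 1000 * 1.1 ** (years - 1977.0)})
        partial = pd.DataFrame({"year": [1977], "n_vessels": [100.0]})
        out = rc.reconstruct_unmotorized(
            partial, motor, cov, (1977, 1982), y_max=1980, coupling=-1.0
        ).set_index("year")["n_vessels"]
        np.testing.assert_allclose(out.loc[1978], 102.0)
        np.testing.assert_allclose(out.loc[1980], 100 * 1.02**3)
        np.testing.assert_allclose(out.loc[1981], 100 * 1.02**3 * 0.9)
        np.testing.assert_allclose(out.loc[1982], 100 * 1.02**3 * 0.81)

    def test_series_continuous_at_ymax(self):
        years = np.arange(1970, 1991)
        cov = self._cov(years, 0.01)
        motor = pd.DataFrame({"year": years, "n_vessels": np.linspace(100, 2000, len(years))})
        partial = pd.DataFrame({"year": [1972], "n_vessels": [300.0]})
        out = rc.reconstruct_unmotorized(partial, motor, cov, (1970, 1990), y_max=1980)
        v = out.set_index("year")["n_vessels"]
        # first post-peak step stays within the motorized relative change
        step = abs(v.loc[1981] - v.loc[1980]) / v.loc[1980]
        m = motor.set_index("year")["n_vessels"]
        assert step == pytest.approx((m.loc[1981] - m.loc[1980]) / m.loc[1980])

    def test_missing_motorized_series_raises(self):
        with pytest.raises(ValueError, match="motorized"):
            rc.reconstruct_unmotorized(
                pd.DataFrame({"year": [1980], "n_vessels": [1.0]}),
                pd.DataFrame(columns=["year", "n_vessels"]),
                self._cov(np.arange(1975, 1986), 0.0),
                (1975, 1985),
                y_max=1980,
            )


class TestYmaxGdpRelation:
    def test_collinear_points_fit_exactly(self):
        df = pd.DataFrame({"gdp_at_ymax": [1000.0, 2000, 3000], "y_max": [1990.0, 1988, 1986]})
        model = rc.fit_ymax_gdp_relation(df)
        assert model.slope == pytest.approx(-0.002)
        assert model.intercept == pytest.approx(1992.0)
        np.testing.assert_allclose(model.residuals, 0, atol=1e-9)

    def test_known_slope_recovered_within_two_stderr(self):
        rng = np.random.default_rng(12)
        gdp = rng.uniform(500, 8000, 40)
        ymax = 1995 - 0.002 * gdp + rng.normal(0, 2, 40)
        model = rc.fit_ymax_gdp_relation(pd.DataFrame({"gdp_at_ymax": gdp, "y_max": ymax}))
        assert abs(model.slope - (-0.002)) < 2 * model.stderr_slope

    def test_prediction_is_rounded_linear_response(self):
        model = rc.UnmotorizedModel(slope=-0.002, intercept=1992.0)
        assert model.predict_ymax(1000.0, (1950, 2017)) == 1990
        assert model.predict_ymax(1250.0, (1950, 2017)) == round(1992 - 0.002 * 1250)

    def test_degenerate_design_raises(self):
        df = pd.DataFrame({"gdp_at_ymax": [1000.0, 1000, 1000], "y_max": [1990.0, 1991, 1992]})
        with pytest.raises(ValueError, match="degenerate"):
            rc.fit_ymax_gdp_relation(df)

    def test_fewer_than_three_points_raises(self):
        df = pd.DataFrame({"gdp_at_ymax": [1.0, 2.0], "y_max": [1990.0, 1991.0]})
        with pytest.raises(ValueError, match="3"):
            rc.fit_ymax_gdp_relation(df)


def test_no_negative_counts_after_reconstruction(small_world):
    from effortmap.pipeline import reconstruct_fleets

    fleets, _ = reconstruct_fleets(small_world)
    for series in fleets.values():
        assert (series["n_vessels"] >= 0).all()
        assert len(series) == small_world.config.year_end - small_world.config.year_start + 1
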