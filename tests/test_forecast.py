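import math

import numpy as np
import pytest

from cdpcast.forecast import (
    ALGORITHMS,
    ArimaForecaster,
    GPForecaster,
    LogNormalNull,
    ModelSpec,
    NormalNull,
    PastAverages,
    RandomForestForecaster,
    SarimaForecaster,
    SarimaxForecaster,
    fit_predict_pa,
)
from cdpcast.records import PrefectureMeteo

from conftest import make_series


def constant_meteo(years, temp=15.0, precip=100.0):
    return PrefectureMeteo(
        "p01",
        {
            (y, m): {"temperature": temp + m, "precipitation": precip}
            for y in years
            for m in range(1, 13)
        },
    )


class TestPastAverages:
    def test_constant_series_any_n(self):
        s = make_series({(y, m): 3.0 for y in (2001, 2002, 2003) for m in (4, 5)})
        for n in (1, 2, 5):
            f = fit_predict_pa(s, n, [(2004, 4), (2004, 5)])
            assert all(v == pytest.approx(3.0) for v in f.predictions.values())

    def test_month_matched_window_mean(self):
        s = make_series({(2001, 4): 9.0, (2002, 4): 2.0, (2003, 4): 4.0})
        f = fit_predict_pa(s, 2, [(2004, 4)])
        assert f.predictions[(2004, 4)] == pytest.approx(3.0)  # mean(2, 4)

    def test_n1_equals_last_year(self):
        s = make_series({(2001, 4): 9.0, (2002, 4): 2.5})
        f = fit_predict_pa(s, 1, [(2003, 4)])
        assert f.predictions[(2003, 4)] == pytest.approx(2.5)

    def test_unseen_month_falls_back_to_window_mean(self):
        s = make_series({(2001, 4): 2.0, (2002, 5): 6.0, (2002, 6): 8.0})
        f = fit_predict_pa(s, 1, [(2003, 4)])  # month 4 absent in window year 2002
        assert f.predictions[(2003, 4)] == pytest.approx(7.0)
        assert any(flag.startswith("month_fallback") for flag in f.flags)

    def test_empty_window_falls_back_to_train_mean(self):
        s = make_series({(1998, 4): 2.0, (1998, 5): 4.0, (2002, 6): 9.0})
        # n = 1 window is year 2002 only; month 4 unseen there, but window
        # non-empty -> window mean = 9.0
        f = fit_predict_pa(s, 1, [(2003, 4)])
        assert f.predictions[(2003, 4)] == pytest.approx(9.0)

    def test_pooled_variant_ignores_month(self):
        s = make_series({(2002, 4): 2.0, (2002, 5): 6.0})
        f = PastAverages(n=1, pooled=True).fit(s).predict([(2003, 4)])
        assert f.predictions[(2003, 4)] == pytest.approx(4.0)

    def test_target_year_must_follow_training(self):
        s = make_series({(2001, 4): 1.0, (2002, 4): 2.0})
        with pytest.raises(ValueError, match="ahead"):
            PastAverages(n=1).fit(s).predict([(2002, 4)])
        with pytest.raises(ValueError, match="single year"):
            PastAverages(n=1).fit(s).predict([(2003, 4), (2004, 4)])

    def test_gap_year_anchor_uses_cutoff_not_last_observation(self):
        # last observation 2002; forecasting 2005 anchors the window at 2004
        s = make_series({(2001, 4): 2.0, (2002, 4): 8.0})
        f = PastAverages(n=1).fit(s).predict([(2005, 4)])
        # window year 2004 is empty -> falls back to the training mean
        assert f.predictions[(2005, 4)] == pytest.approx(5.0)
        assert any(flag.startswith("window_empty") for flag in f.flags)
        f3 = PastAverages(n=3).fit(s).predict([(2005, 4)])
        assert f3.predictions[(2005, 4)] == pytest.approx(8.0)  # window 2002-2004

    def test_reordering_invariance(self):
        obs = {(2001, 4): 1.0, (2001, 7): 3.0, (2002, 4): 5.0, (2002, 7): 2.0}
        items = list(obs.items())
        f1 = fit_predict_pa(make_series(dict(items)), 2, [(2003, 4), (2003, 7)])
        f2 = fit_predict_pa(make_series(dict(items[::-1])), 2, [(2003, 4), (2003, 7)])
        assert f1.predictions == f2.predictions


class TestNulls:
    def test_rand_constant_series_sigma_zero(self):
        s = make_series({(2001, m): 5.0 for m in range(1, 7)})
        f = NormalNull(seed=1).fit(s).predict([(2002, 1), (2002, 2)])
        assert all(v == pytest.approx(5.0) for v in f.predictions.values())

    def test_rand_mean_matches_mu(self):
        s = make_series({(2001, m): float(m) for m in range(1, 11)})
        model = NormalNull(seed=7).fit(s)
        targets = [(2002, 1 + i % 12) for i in range(12)]
        # many seeded prediction rounds: CLT check on the draw mean
        draws = []
        for seed in range(400):
            model.seed = seed
            draws.extend(model.predict(targets).predictions.values())
        draws = np.asarray(draws)
        se = model.sigma_ / math.sqrt(draws.size)
        assert abs(draws.mean() - model.mu_) <= 4 * se

    def test_rand_seed_determinism(self):
        s = make_series({(2001, m): float(m) for m in range(1, 7)})
        t = [(2002, 4), (2002, 5)]
        f1 = NormalNull(seed=3).fit(s).predict(t)
        f2 = NormalNull(seed=3).fit(s).predict(t)
        assert f1.predictions == f2.predictions

    def test_rand_requires_two_points(self):
        with pytest.raises(ValueError):
            NormalNull(seed=0).fit(make_series({(2001, 4): 1.0}))

    def test_logrand_constant_positive_series(self):
        s = make_series({(2001, m): 7.0 for m in range(1, 7)})
        f = LogNormalNull(seed=5).fit(s).predict([(2002, 3)])
        assert f.predictions[(2002, 3)] == pytest.approx(7.0)

    def test_logrand_median_and_floor(self):
        s = make_series(
            {(2000 + i, 1 + j): v for i, row in enumerate([[0.0, 0.5], [2.0, 8.0]])
             for j, v in enumerate(row)}
        )
        model = LogNormalNull(seed=0).fit(s)
        draws = []
        for seed in range(2000):
            model.seed = seed
            draws.extend(model.predict([(2003, 1)] ).predictions.values())
        draws = np.asarray(draws)
        assert (draws >= 0).all()
        expected_median = math.exp(model.mu_log_) - model.epsilon
        # median of exp(Normal) is exp(mu); epsilon shift then floor
        assert np.median(draws) == pytest.approx(expected_median, rel=0.1)


class TestClassical:
    def test_white_noise_forecasts_near_mean(self, rng):
        values = rng.normal(10.0, 1.0, 8 * 12)
        obs = {(2000 + i // 12, 1 + i % 12): float(v) for i, v in enumerate(values)}
        s = make_series(obs)
        f = ArimaForecaster().fit(s).predict([(2008, m) for m in range(1, 4)])
        for v in f.predictions.values():
            assert v == pytest.approx(values.mean(), abs=1.0)

    def test_sarima_tracks_noiseless_seasonal_cycle(self):
        amp = 10.0
        obs = {
            (y, m): 20.0 + amp * math.sin(2 * math.pi * m / 12.0)
            for y in range(2000, 2006)
            for m in range(1, 13)
        }
        s = make_series(obs)
        targets = [(2006, m) for m in range(1, 13)]
        f = SarimaForecaster().fit(s).predict(targets)
        err = np.sqrt(np.mean([
            (f.predictions[(2006, m)] - (20.0 + amp * math.sin(2 * math.pi * m / 12)))
            ** 2
            for m in range(1, 13)
        ]))
        assert err < 0.1 * amp

    def test_sarimax_missing_exog_months_named(self):
        s = make_series(
            {(y, m): float(m) for y in (2001, 2002, 2003) for m in range(1, 13)}
        )
        meteo = constant_meteo([2001, 2002, 2003])  # target year 2004 missing
        model = SarimaxForecaster()
        model.fit(s, exog=meteo)
        with pytest.raises(ValueError, match="2004-01"):
            model.predict([(2004, 1)])

    def test_sarimax_requires_exog(self):
        s = make_series({(2001, m): 1.0 for m in range(1, 13)})
        with pytest.raises(ValueError, match="exog"):
            SarimaxForecaster().fit(s)

    def test_fallback_to_mean_when_all_candidates_fail(self, monkeypatch):
        s = make_series({(2001, m): float(m) for m in range(1, 13)})
        model = ArimaForecaster()
        import statsmodels.tsa.statespace.sarimax as sm

        def boom(*a, **k):
            raise np.linalg.LinAlgError("forced failure")

        monkeypatch.setattr(sm.SARIMAX, "fit", boom)
        model.fit(s)
        f = model.predict([(2002, 1)])
        assert "fit_fallback_mean" in f.flags
        assert f.predictions[(2002, 1)] == pytest.approx(6.5)


class TestGP:
    def test_constant_series(self):
        s = make_series({(2001, m): 4.0 for m in range(1, 13)})
        f = GPForecaster().fit(s).predict([(2002, 3)])
        assert f.predictions[(2002, 3)] == pytest.approx(4.0, abs=1e-6)

    def test_smooth_seasonal_function_held_out(self):
        f_true = lambda m: 30.0 + 20.0 * math.sin(2 * math.pi * m / 12.0)
        obs = {(y, m): f_true(m) for y in range(2000, 2006) for m in range(1, 13)}
        model = GPForecaster().fit(make_series(obs))
        preds = model.predict([(2006, m) for m in range(1, 13)]).predictions
        rng_ = max(map(f_true, range(1, 13))) - min(map(f_true, range(1, 13)))
        for m in range(1, 13):
            assert abs(preds[(2006, m)] - f_true(m)) < 0.1 * rng_

    def test_finite_on_extrapolated_years(self):
        s = make_series({(2001, m): float(m) for m in range(1, 13)})
        f = GPForecaster().fit(s).predict([(2030, 6)])
        assert np.isfinite(f.predictions[(2030, 6)])

    def test_degenerate_features_rejected(self):
        s = make_series({(2001, 4): 1.0, (2001, 4): 2.0})
        with pytest.raises(ValueError):
            GPForecaster().fit(s)


class TestRandomForest:
    def test_constant_di(self):
        s = make_series({(2001, m): 6.0 for m in range(1, 13)})
        meteo = constant_meteo([2001, 2002])
        f = RandomForestForecaster(seed=0).fit(s, exog=meteo).predict([(2002, 4)])
        assert f.predictions[(2002, 4)] == pytest.approx(6.0)

    def test_step_function_of_temperature(self):
        # DI = 2 when temperature <= 20 else 40; exog repeats across years
        meteo = constant_meteo(range(2000, 2008))
        obs = {
            (y, m): 2.0 if meteo.get(y, m, "temperature") <= 20 else 40.0
            for y in range(2000, 2007)
            for m in range(1, 13)
        }
        model = RandomForestForecaster(seed=1).fit(make_series(obs), exog=meteo)
        preds = model.predict([(2007, m) for m in range(1, 13)]).predictions
        for m in range(1, 13):
            expected = 2.0 if meteo.get(2007, m, "temperature") <= 20 else 40.0
            assert preds[(2007, m)] == pytest.approx(expected, rel=0.1)

    def test_seed_determinism(self):
        s = make_series({(2001, m): float(m % 3) for m in range(1, 13)})
        meteo = constant_meteo([2001, 2002])
        f1 = RandomForestForecaster(seed=9).fit(s, exog=meteo).predict([(2002, 5)])
        f2 = RandomForestForecaster(seed=9).fit(s, exog=meteo).predict([(2002, 5)])
        assert f1.predictions == f2.predictions

    def test_missing_exog_rejected(self):
        s = make_series({(2001, 4): 1.0, (2001, 5): 2.0})
        with pytest.raises(ValueError):
            RandomForestForecaster(seed=0).fit(s, exog=None)


class TestContract:
    """All eight algorithms satisfy the shared fit/predict contract."""

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_forecast_covers_every_target(self, algorithm):
        obs = {
            (y, m): float(1 + (m % 4) + 0.1 * (y - 2000))
            for y in range(2000, 2007)
            for m in (4, 5, 6)
        }
        s = make_series(obs)
        meteo = constant_meteo(range(2000, 2008))
        targets = [(2007, 4), (2007, 5), (2007, 6)]
        spec = ModelSpec(algorithm=algorithm, seed=3)
        f = spec.build().fit(s, exog=meteo).predict(targets)
        assert set(f.predictions) == set(targets)
        assert all(np.isfinite(v) for v in f.predictions.values())
        assert f.algorithm == algorithm

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(algorithm="PROPHET")
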