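import numpy as np
import pandas as pd
import pytest

from aedes_ude import oviposition_net as onet
from aedes_ude import training
from aedes_ude.climate import ClimateSeries
from aedes_ude.population import MOISeries
from aedes_ude.training import (FitResult, StageSpec, TrainConfig, fit,
                                gradient_check, correlation_diagnostics)
from aedes_ude.vital_rates import VitalParams


def _tiny_data(seed=0, n_cities=2):
    """Two warm cities, ~3 months daily climate, 4 half-month observations."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2021-01-01", periods=91, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    periods = pd.DatetimeIndex(["2021-02-01", "2021-02-16", "2021-03-01", "2021-03-16"])
    data = {}
    for c in range(n_cities):
        temp = 26.0 + 2.0 * np.sin(2 * np.pi * doy / 40.0 + c) + rng.normal(0, 0.4, 91)
        precip = np.where(rng.random(91) < 0.4, rng.gamma(0.8, 10.0, 91), 0.0)
        series = ClimateSeries(f"c{c}", dates, temp, precip)
        moi = MOISeries(f"c{c}", periods, rng.uniform(5.0, 20.0, 4))
        data[f"c{c}"] = (series, moi)
    return data


def _tiny_cfg(iters=(3, 3, 3), seed=0):
    return TrainConfig(stages=(
        StageSpec(0.01, iters[0], True, True),
        StageSpec(0.001, iters[1], False, True),
        StageSpec(0.01, iters[2], True, False),
    ), seed=seed)


class TestTransforms:
    def test_round_trip(self, default_params):
        u = training.bio_to_unconstrained(default_params)
        back = training.unconstrained_to_bio(u)
        for k, v in default_params.to_dict().items():
            assert getattr(back, k) == pytest.approx(v, rel=1e-5)

    def test_jacobian_matches_finite_differences(self, default_params):
        u = training.bio_to_unconstrained(default_params) + 0.1
        jac = training._transform_jacobian(u)
        h = 1e-6
        names = list(default_params.to_dict())
        for i, name in enumerate(names):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fd = (getattr(training.unconstrained_to_bio(up), name) -
                  getattr(training.unconstrained_to_bio(um), name)) / (2 * h)
            assert jac[i] == pytest.approx(fd, rel=1e-5)


class TestGradientCheck:
    def test_solver_gradients_match_finite_differences(self):
        """Discretize-then-optimize gradients vs central differences < 1e-3."""
        res = gradient_check(seed=0)
        assert res["max_rel_error"] < 1e-3

    def test_dead_diapause_parameter_has_zero_gradient(self):
        # the tiny problem never enters diapause, so delta cannot matter
        res = gradient_check(seed=1)
        assert res["dead_delta_grad"] == 0.0

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_bounded_across_seeds(self, seed):
        assert gradient_check(seed=seed)["max_rel_error"] < 1e-3


class TestFit:
    def test_zero_iteration_stage_rejected(self):
        with pytest.raises(ValueError):
            StageSpec(lr=0.01, iterations=0, train_bio=True, train_net=True)
        with pytest.raises(ValueError):
            StageSpec(lr=-0.1, iterations=5, train_bio=True, train_net=True)

    def test_same_seed_identical_history(self, default_params):
        data = _tiny_data()
        net = onet.init_net(3)
        r1 = fit(data, _tiny_cfg(), default_params, net, eval_start="2021-02-01")
        r2 = fit(data, _tiny_cfg(), default_params, net, eval_start="2021-02-01")
        np.testing.assert_array_equal(r1.loss_history, r2.loss_history)

    def test_freeze_contracts_bitwise(self, default_params):
        """Stage 2 leaves theta1 untouched; stage 3 leaves theta2 untouched."""
        data = _tiny_data()
        res = fit(data, _tiny_cfg(iters=(4, 4, 4)), default_params, onet.init_net(3),
                  eval_start="2021-02-01")
        (u1_s1, net_s1, lam_s1), (u1_s2, net_s2, lam_s2), (u1_s3, net_s3, _) = res.stage_params
        np.testing.assert_array_equal(u1_s1, u1_s2)      # theta1 frozen in stage 2
        np.testing.assert_array_equal(lam_s1, lam_s2)    # scales move with theta1 only
        np.testing.assert_array_equal(net_s2, net_s3)    # theta2 frozen in stage 3
        assert not np.array_equal(net_s1, net_s2)        # ... but stage 2 did train it

    def test_best_loss_non_increasing_across_stages(self, default_params):
        data = _tiny_data()
        res = fit(data, _tiny_cfg(iters=(5, 5, 5)), default_params, onet.init_net(3),
                  eval_start="2021-02-01")
        h = res.loss_history
        bests = [h[:b].min() for b in res.stage_boundaries] + [h.min()]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(bests, bests[1:]))

    def test_loss_decreases_from_start(self, default_params):
        data = _tiny_data()
        res = fit(data, _tiny_cfg(iters=(10, 10, 5)), default_params,
                  onet.init_net(3), eval_start="2021-02-01")
        assert res.loss_history[-1] < res.loss_history[0]
        for r in res.per_city_r.values():
            assert -1.0 <= r <= 1.0

    def test_mismatched_observation_periods_rejected(self, default_params):
        data = _tiny_data()
        series, moi = data["c0"]
        bad = MOISeries("c0", moi.periods[:3], moi.values[:3])
        data["c0"] = (series, bad)
        with pytest.raises(ValueError, match="periods"):
            fit(data, _tiny_cfg(), default_params, onet.init_net(3),
                eval_start="2021-02-01")


class TestCorrelationDiagnostics:
    def _fitres(self, fitted, cities):
        return FitResult(params=VitalParams.default(), net=onet.init_net(0),
                         scales=None, loss_history=np.zeros(1),
                         per_city_r={}, fitted=fitted, cities=cities)

    def test_perfect_and_anti_correlation(self):
        data = _tiny_data()
        obs0 = data["c0"][1].values
        obs1 = data["c1"][1].values
        fitted = {"c0": obs0 * 2.0, "c1": -obs1 + 30.0}
        df = correlation_diagnostics(self._fitres(fitted, ["c0", "c1"]), data)
        r0 = df[df.city == "c0"].pearson_r.iloc[0]
        r1 = df[df.city == "c1"].pearson_r.iloc[0]
        assert r0 == pytest.approx(1.0)
        assert r1 == pytest.approx(-1.0)

    def test_constant_series_reported_nan(self):
        data = _tiny_data()
        fitted = {"c0": np.full(4, 3.0), "c1": data["c1"][1].values}
        df = correlation_diagnostics(self._fitres(fitted, ["c0", "c1"]), data)
        assert np.isnan(df[df.city == "c0"].pearson_r.iloc[0])

    def test_pp_points_track_diagonal_for_normal_residuals(self):
        """Standardized normal residuals give P-P pairs within the 95% band."""
        rng = np.random.default_rng(12)
        n = 400
        dates = pd.date_range("2021-01-01", periods=n, freq="D")
        # synthetic per-city series with i.i.d. normal residuals
        base = rng.uniform(10, 20, n)
        resid = rng.normal(0, 1.0, n)
        periods = pd.DatetimeIndex([pd.Timestamp("2021-02-01")] * 0)
        data = {"c": (None, MOISeries("c", pd.date_range("2000-01-01", periods=n, freq="D").normalize(), base + resid))}
        fitted = {"c": base}
        df = correlation_diagnostics(self._fitres(fitted, ["c"]), data)
        gap = np.abs(df.theoretical_cp - df.empirical_cp)
        # Kolmogorov 95% band for n=400
        assert gap.max() < 1.36 / np.sqrt(n)
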