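import numpy as np
import pandas as pd
import pytest

from vitisim.carbon_balance import CarbonBalanceParams, simulate_season
from vitisim.errors import VitisimError
from vitisim.sugar_model import (
    BrixObservation,
    RegressionFit,
    fit_brix_dm,
    predict_brix,
    run_cluster_scenarios,
)


def sim_table(dm_by_das: dict[int, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {"das": list(dm_by_das), "dm_cumulative": list(dm_by_das.values())}
    )


def ols_oracle(x, y):
    """Closed-form normal equations, independent of scipy."""
    x, y = np.asarray(x), np.asarray(y)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    intercept = ym - slope * xm
    r = np.sum((x - xm) * (y - ym)) / np.sqrt(
        np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)
    )
    return slope, intercept, r**2


class TestFitBrixDm:
    def test_exact_line(self):
        sim = sim_table({100: 10.0, 110: 20.0, 120: 30.0})
        obs = [BrixObservation(100, 12.0), BrixObservation(110, 14.0),
               BrixObservation(120, 16.0)]
        fit = fit_brix_dm(obs, sim)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_brix_gives_flat_fit(self):
        sim = sim_table({100: 10.0, 110: 20.0, 120: 30.0})
        obs = [BrixObservation(d, 15.0) for d in (100, 110, 120)]
        fit = fit_brix_dm(obs, sim)
        assert fit.slope == 0.0
        assert fit.r2 == 0.0

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(5)
        dm = np.linspace(300, 900, 10)
        brix = 15.0 + 0.005 * dm + rng.normal(0, 0.3, 10)
        sim = sim_table({100 + i: v for i, v in enumerate(dm)})
        obs = [BrixObservation(100 + i, float(b)) for i, b in enumerate(brix)]
        fit = fit_brix_dm(obs, sim)
        slope, intercept, r2 = ols_oracle(dm, brix)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r2 == pytest.approx(r2)

    def test_r2_invariant_under_affine_dm_rescaling(self):
        rng = np.random.default_rng(6)
        dm = np.linspace(300, 900, 8)
        brix = 12.0 + 0.004 * dm + rng.normal(0, 0.2, 8)
        obs = [BrixObservation(100 + i, float(b)) for i, b in enumerate(brix)]
        f1 = fit_brix_dm(obs, sim_table({100 + i: v for i, v in enumerate(dm)}))
        f2 = fit_brix_dm(obs, sim_table({100 + i: 3 * v + 50 for i, v in enumerate(dm)}))
        assert f1.r2 == pytest.approx(f2.r2)

    def test_errors(self):
        sim = sim_table({100: 10.0, 110: 10.0, 120: 10.0})
        obs = [BrixObservation(d, b) for d, b in [(100, 12.0), (110, 14.0), (120, 16.0)]]
        with pytest.raises(VitisimError, match="constant"):
            fit_brix_dm(obs, sim)
        with pytest.raises(VitisimError, match="at least 3"):
            fit_brix_dm(obs[:2], sim_table({100: 1.0, 110: 2.0}))
        with pytest.raises(VitisimError, match="outside"):
            fit_brix_dm(obs, sim_table({100: 1.0, 110: 2.0, 125: 3.0}))

    def test_brix_range_validated(self):
        with pytest.raises(VitisimError):
            BrixObservation(100, 40.0)


class TestPredictBrix:
    FIT = RegressionFit(slope=0.2, intercept=10.0, r2=1.0, n=5)

    def test_zero_dm_gives_intercept(self):
        assert predict_brix(self.FIT, [0.0])[0] == 10.0

    def test_linear_prediction(self):
        assert predict_brix(self.FIT, [50.0])[0] == pytest.approx(20.0)

    def test_clamped_at_zero(self):
        fit = RegressionFit(slope=0.2, intercept=-5.0, r2=1.0, n=5)
        assert predict_brix(fit, [0.0])[0] == 0.0

    def test_residual_mean_zero_on_fitting_data(self):
        rng = np.random.default_rng(7)
        dm = np.linspace(200, 800, 10)
        brix = 11.0 + 0.006 * dm + rng.normal(0, 0.3, 10)
        sim = sim_table({100 + i: v for i, v in enumerate(dm)})
        obs = [BrixObservation(100 + i, float(b)) for i, b in enumerate(brix)]
        fit = fit_brix_dm(obs, sim)
        resid = brix - predict_brix(fit, dm)
        assert resid.mean() == pytest.approx(0.0, abs=1e-9)


@pytest.fixture(scope="module")
def setting(season):
    params = CarbonBalanceParams()
    sim = simulate_season(season["weather"], season["canopy"], params)
    fit = fit_brix_dm(season["brix_obs"], sim)
    return season, params, sim, fit


class TestClusterScenarios:

    def test_baseline_count_reproduces_baseline(self, setting):
        season, params, sim, fit = setting
        count = season["canopy"]["clusters"].iloc[0]
        trajs = run_cluster_scenarios(
            season["weather"], season["canopy"], params, fit, [count]
        )
        np.testing.assert_allclose(
            trajs[count]["brix"], predict_brix(fit, sim["dm_cumulative"])
        )

    def test_fewer_clusters_higher_brix(self, setting):
        season, params, _, fit = setting
        trajs = run_cluster_scenarios(
            season["weather"], season["canopy"], params, fit, [6.0, 12.0]
        )
        assert (trajs[6.0]["brix"] >= trajs[12.0]["brix"]).all()

    def test_zero_clusters_is_highest(self, setting):
        season, params, _, fit = setting
        trajs = run_cluster_scenarios(
            season["weather"], season["canopy"], params, fit, [0.0, 6.0, 12.0]
        )
        late = trajs[0.0]["das"] > 30  # once cluster respiration matters
        assert (trajs[0.0]["brix"][late] > trajs[6.0]["brix"][late]).all()
        assert (trajs[0.0]["brix"] >= trajs[6.0]["brix"]).all()

    def test_negative_count_rejected(self, setting):
        season, params, _, fit = setting
        with pytest.raises(VitisimError):
            run_cluster_scenarios(season["weather"], season["canopy"], params, fit, [-1.0])

    def test_default_synthetic_season_regression_quality(self, season):
        """The Brix–DM regression on the default synthetic season is strong."""
        params = CarbonBalanceParams()
        sim = simulate_season(season["weather"], season["canopy"], params)
        fit = fit_brix_dm(season["brix_obs"], sim)
        assert fit.r2 >= 0.90
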