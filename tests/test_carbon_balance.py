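import dataclasses

import numpy as np
import pandas as pd
import pytest

from vitisim.carbon_balance import (
    CarbonBalanceParams,
    calibrate_scale,
    co2_to_dry_matter,
    simulate_season,
)
from vitisim.errors import CoverageError, VitisimError
from vitisim.photosynthesis import PhotosynthesisParams, daily_photosynthesis
from vitisim.respiration import daily_respiration
from vitisim.synthetic import SyntheticConfig, generate_canopy, generate_weather
from vitisim.vine_state import interpolate_canopy


class TestCo2Conversion:
    def test_zero(self):
        assert co2_to_dry_matter(0.0) == 0.0

    def test_stoichiometric_factor(self):
        assert co2_to_dry_matter(44.0, 30 / 44) == pytest.approx(30.0)

    def test_arithmetic(self):
        assert co2_to_dry_matter(10.0, 0.6818) == pytest.approx(6.818)

    def test_sign_preserving(self):
        assert co2_to_dry_matter(-10.0, 0.5) == -5.0

    def test_bad_factor_rejected(self):
        with pytest.raises(VitisimError):
            co2_to_dry_matter(1.0, 1.5)


@pytest.fixture(scope="module")
def inputs():
    cfg = SyntheticConfig(seed=11, n_days=120)
    rng = cfg.rng()
    weather = generate_weather(cfg, rng)
    canopy = interpolate_canopy(generate_canopy(cfg, rng), range(cfg.n_days))
    return weather, canopy


class TestSimulateSeason:
    def test_cumulative_is_exact_running_sum(self, inputs):
        weather, canopy = inputs
        sim = simulate_season(weather, canopy)
        np.testing.assert_allclose(
            sim["dm_cumulative"], np.cumsum(sim["dm_daily"]), rtol=0, atol=0
        )
        np.testing.assert_allclose(
            sim["dm_daily"],
            sim["co2_balance"] * CarbonBalanceParams().co2_to_dm,
        )

    def test_matches_scalar_reference_per_day(self, inputs):
        """Vectorised season loop agrees with day-by-day scalar calls."""
        weather, canopy = inputs
        params = CarbonBalanceParams()
        sim = simulate_season(weather, canopy, params).set_index("das")
        w = weather.data.set_index("das")
        for das in (5, 60, 110):
            row, st = w.loc[das], canopy.loc[das]
            p = daily_photosynthesis(
                (row.tmin + row.tmax) / 2, row.radiation, row.day_length,
                st.light_interception, params.photosynthesis,
            )
            r = daily_respiration(
                row.tmin, row.tmax, row.day_length, st.shoot_surface,
                st.cluster_weight, st.clusters, st.leaf_area_increment,
                params.respiration,
            )
            assert sim.loc[das, "p_gross_vine"] == pytest.approx(p, rel=1e-9)
            assert sim.loc[das, "r_total_vine"] == pytest.approx(r, rel=1e-9)

    def test_zero_radiation_strictly_decreasing(self, inputs):
        weather, canopy = inputs
        df = weather.data.copy()
        df["radiation"] = 0.0
        dark = dataclasses.replace(weather, data=df)
        sim = simulate_season(dark, canopy)
        assert (np.diff(sim["dm_cumulative"]) < 0).all()

    def test_more_radiation_never_less_dry_matter(self, inputs):
        weather, canopy = inputs
        df = weather.data.copy()
        df["radiation"] = df["radiation"] * 1.3
        brighter = dataclasses.replace(weather, data=df)
        a = simulate_season(weather, canopy)["dm_cumulative"].iloc[-1]
        b = simulate_season(brighter, canopy)["dm_cumulative"].iloc[-1]
        assert b >= a

    def test_mismatched_coverage_error_lists_days(self, inputs):
        weather, canopy = inputs
        short = dataclasses.replace(weather, data=weather.data.iloc[:100])
        with pytest.raises(CoverageError, match="das"):
            simulate_season(short, canopy)

    def test_deterministic(self, inputs):
        weather, canopy = inputs
        a = simulate_season(weather, canopy)
        b = simulate_season(weather, canopy)
        pd.testing.assert_frame_equal(a, b)


def _observations(weather, canopy, params, scale, rng=None, noise=0.0):
    scaled = dataclasses.replace(
        params,
        photosynthesis=dataclasses.replace(
            params.photosynthesis, pn_max=params.photosynthesis.pn_max * scale
        ),
    )
    sim = simulate_season(weather, canopy, scaled).set_index("das")["dm_cumulative"]
    das = np.linspace(21, len(sim) - 2, 8).astype(int)
    vals = sim.loc[das].to_numpy()
    if noise > 0:
        vals = vals * (1.0 + rng.normal(0.0, noise, vals.size))
    return list(zip(das, vals))


class TestCalibrateScale:
    def test_self_consistency_recovers_unity(self, inputs):
        weather, canopy = inputs
        params = CarbonBalanceParams()
        obs = _observations(weather, canopy, params, scale=1.0)
        res = calibrate_scale(weather, canopy, params, obs)
        assert res.scale == pytest.approx(1.0, rel=0.01)

    def test_recovers_known_factor_noise_free(self, inputs):
        weather, canopy = inputs
        params = CarbonBalanceParams()
        obs = _observations(weather, canopy, params, scale=1.5)
        res = calibrate_scale(weather, canopy, params, obs)
        assert res.scale == pytest.approx(1.5, rel=0.01)
        assert res.sse < 1.0

    def test_recovers_factor_under_noise(self, inputs):
        weather, canopy = inputs
        params = CarbonBalanceParams()
        rng = np.random.default_rng(202)
        obs = _observations(weather, canopy, params, scale=1.5, rng=rng, noise=0.05)
        res = calibrate_scale(weather, canopy, params, obs)
        assert res.scale == pytest.approx(1.5, rel=0.10)

    def test_needs_three_observations(self, inputs):
        weather, canopy = inputs
        with pytest.raises(VitisimError):
            calibrate_scale(weather, canopy, CarbonBalanceParams(), [(30, 10.0), (60, 50.0)])
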