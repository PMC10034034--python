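"""Closed-loop virtual seasons: weather generation, the soil bucket,
and the end-to-end scheduling dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irrisched.scheduler import Method, Trigger, ZoneConfig
from irrisched.simulate import (
    SimConfig,
    canopy_response,
    default_zone_roster,
    generate_weather,
    run_season,
    step_soil,
)
from irrisched.soil import default_profile, depletion_to_target, profile_swd
from irrisched.weather import ValidationError


@pytest.fixture(scope="module")
def dry_run():
    """A rain-free high-demand season exercising all three methods."""
    cfg = SimConfig(n_days=60, seed=7, rain_prob=0.0)
    return cfg, run_season(cfg)


class TestGenerateWeather:
    def test_same_seed_identical_series(self):
        cfg = SimConfig(n_days=5, seed=11)
        d1, m1 = generate_weather(cfg)
        d2, m2 = generate_weather(cfg)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_zero_rain_probability(self):
        daily, _ = generate_weather(SimConfig(n_days=30, seed=2, rain_prob=0.0))
        assert (daily["precip"] == 0.0).all()

    def test_zero_amplitude_gives_constant_temperature(self):
        cfg = SimConfig(n_days=2, seed=3, t_max_mean=25.0, t_min_mean=25.0,
                        t_sd=0.0)
        _, minute = generate_weather(cfg)
        assert np.allclose(minute["t_air"], 25.0)

    def test_minute_extremes_match_daily(self):
        cfg = SimConfig(n_days=3, seed=5)
        daily, minute = generate_weather(cfg)
        for i in range(3):
            day = minute.iloc[i * 1440:(i + 1) * 1440]
            assert day["t_air"].max() == pytest.approx(daily["t_max"][i], abs=0.01)
            assert day["t_air"].min() == pytest.approx(daily["t_min"][i], abs=0.01)


class TestStepSoil:
    def test_no_flux_is_identity(self):
        p = default_profile(0.28)
        p2, fluxes = step_soil(p, 0.0, 0.0, 0.0)
        assert p2.storage_mm == pytest.approx(p.storage_mm)
        assert fluxes["drainage"] == 0.0 and fluxes["extraction"] == 0.0

    def test_full_profile_overflows_to_drainage(self):
        p = default_profile([0.35, 0.34, 0.33, 0.33])  # at field capacity
        _, fluxes = step_soil(p, 0.0, 0.0, 10.0)
        assert fluxes["drainage"] == pytest.approx(10.0)

    def test_extraction_draws_down_storage_exactly(self):
        p = default_profile(0.30)
        p2, fluxes = step_soil(p, 5.0, 0.0, 0.0)
        assert fluxes["extraction"] == pytest.approx(5.0)
        assert p.storage_mm - p2.storage_mm == pytest.approx(5.0, abs=1e-9)

    def test_extraction_floored_at_wilting_point(self):
        p = default_profile(0.181)  # almost dry
        p2, fluxes = step_soil(p, 50.0, 0.0, 0.0)
        assert fluxes["extraction"] < 50.0
        assert all(l.theta_v >= l.theta_pwp - 1e-12 for l in p2.layers)

    @settings(derandomize=True, max_examples=60)
    @given(
        theta=st.floats(0.19, 0.40),
        et=st.floats(0, 15), irr=st.floats(0, 40), rain=st.floats(0, 40),
    )
    def test_water_balance_closes(self, theta, et, irr, rain):
        p = default_profile(min(theta, 0.40))
        p2, fx = step_soil(p, et, irr, rain)
        ds = p2.storage_mm - p.storage_mm
        assert ds == pytest.approx(
            fx["infiltration"] - fx["extraction"], abs=1e-9)
        assert fx["infiltration"] + fx["drainage"] == pytest.approx(
            irr + rain, abs=1e-9)


class TestCanopyResponse:
    def test_limits_at_extremes(self):
        assert canopy_response(0.0, -2.0, 4.0) == pytest.approx(-2.0)
        assert canopy_response(1.0, -2.0, 4.0) == pytest.approx(4.0)
        assert canopy_response(0.5, -2.0, 4.0) == pytest.approx(1.0)

    def test_monotone_gain_curve(self):
        vals = [canopy_response(d, -2.0, 4.0, gain=1.7)
                for d in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_depletion_rejected(self):
        with pytest.raises(ValidationError):
            canopy_response(1.2, -2.0, 4.0)


class TestRunSeason:
    def test_bitwise_reproducible(self):
        cfg = SimConfig(n_days=20, seed=13, sensor_fail_prob=0.2)
        a, b = run_season(cfg), run_season(cfg)
        pd.testing.assert_frame_equal(a.daily, b.daily)
        assert len(a.decision_log) == len(b.decision_log)
        for pa, pb in zip(a.decision_log, b.decision_log):
            assert pa == pb

    def test_daily_water_balance_closes_everywhere(self, dry_run):
        cfg, state = dry_run
        start = default_profile(cfg.initial_theta).storage_mm
        for zid, grp in state.daily.groupby("zone_id"):
            storage = grp["storage_mm"].to_numpy()
            prev = np.concatenate([[start], storage[:-1]])
            flux = (grp["irrigation_mm"] + grp["precip_mm"]
                    - grp["et_mm"] - grp["drainage_mm"]).to_numpy()
            np.testing.assert_allclose(storage - prev, flux, atol=1e-9)

    def test_ledger_closes_season_totals(self, dry_run):
        cfg, state = dry_run
        for zid, z in state.zones.items():
            led = state.ledger(zid)
            assert led.etc == pytest.approx(z.extraction, abs=1e-9)

    def test_no_stress_signal_never_triggers_plant_feedback(self):
        cfg = SimConfig(n_days=20, seed=5, rain_prob=0.0, crop_gain=0.0)
        state = run_season(cfg)
        tier_triggers = (Trigger.TIER_I, Trigger.TIER_II, Trigger.TIER_III)
        for pmap in state.decision_log:
            for d in pmap.entries:
                if d.zone_id.startswith("C_"):
                    assert d.trigger is Trigger.NONE
                    assert d.depth == 0.0
                elif d.zone_id.startswith("H_"):
                    # soil gates may still act, but never the canopy tiers
                    assert d.trigger not in tier_triggers

    def test_fully_irrigated_zone_refilled_after_irrigation(self, dry_run):
        cfg, state = dry_run
        m100 = (state.daily[state.daily["zone_id"] == "M_100"]
                .reset_index(drop=True))
        irrigated = m100[m100["irrigation_mm"] > 0]
        assert len(irrigated) > 3
        # 100% replenishment refills to the 96%-of-FC target; end-of-day
        # depletion is that target's residual plus at most one day's ET
        target = default_profile([0.96 * fc for fc in (0.35, 0.34, 0.33, 0.33)])
        base_swd = profile_swd(target)
        paw = sum((l.theta_fc - l.theta_pwp) * l.thickness * 10.0
                  for l in default_profile().layers)
        max_et = float(m100["et_mm"].max())
        for idx, row in irrigated.iterrows():
            assert row["swd"] <= base_swd + 1.5 * max_et / paw
            if idx > 0:  # refill undoes the inter-scan drawdown
                assert row["swd"] < m100.loc[idx - 1, "swd"]

    def test_cumulative_irrigation_monotone_across_levels(self, dry_run):
        cfg, state = dry_run
        summary = state.summary().set_index("zone_id")["irrigation_mm"]
        for method in ("M", "C", "H"):
            assert summary[f"{method}_75"] >= summary[f"{method}_50"]
            assert summary[f"{method}_50"] >= summary[f"{method}_25"]

    def test_hybrid_withholds_on_wet_profile_despite_stress(self):
        cfg = SimConfig(n_days=40, seed=3, rain_prob=0.5, rain_mean_mm=18.0)
        state = run_season(cfg)
        withheld = [
            d for pmap in state.decision_log for d in pmap.entries
            if d.trigger is Trigger.WITHHELD_SWD_MIN
        ]
        assert withheld, "wet season should produce soil-gated withholds"
        for d in withheld:
            assert d.depth == 0.0
            assert d.inputs_used["swd"] <= 0.10

    def test_hybrid_closed_loop_depletion_bounded(self, dry_run):
        cfg, state = dry_run
        h75 = state.daily[state.daily["zone_id"] == "H_75"]
        paw = sum((l.theta_fc - l.theta_pwp) * l.thickness * 10.0
                  for l in default_profile().layers)
        max_et = float(h75["et_mm"].max())
        # one scan interval plus the application-day lag of drawdown
        bound = 0.65 + (cfg.scan_cadence_days + 1) * max_et / paw
        assert float(h75["swd"].max()) <= bound

    def test_sensor_failure_forces_icwsi_fallback(self):
        cfg = SimConfig(n_days=15, seed=9, sensor_fail_prob=1.0)
        state = run_season(cfg)
        hybrid = [
            d for pmap in state.decision_log for d in pmap.entries
            if d.zone_id.startswith("H_")
        ]
        assert hybrid
        for d in hybrid:
            assert d.inputs_used["swd"] is None
            assert d.trigger in (Trigger.NONE, Trigger.TIER_I,
                                 Trigger.TIER_II, Trigger.TIER_III)

    def test_duplicate_roster_rejected(self):
        zones = default_zone_roster() + [default_zone_roster()[0]]
        with pytest.raises(ValidationError, match="duplicate"):
            run_season(SimConfig(n_days=2, seed=0), zones)
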