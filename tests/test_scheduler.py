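"""The tiered decision engine: thresholds, gating, and prescription maps."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irrisched.scheduler import (
    Decision,
    Method,
    PrescriptionMap,
    ThresholdTable,
    Tier,
    Trigger,
    ZoneConfig,
    build_prescription_map,
    depth_for,
    hybrid_decision,
    manual_decision,
    plant_feedback_decision,
    tier_for_icwsi,
)
from irrisched.weather import ValidationError

D = date(2021, 8, 10)
C75 = ZoneConfig("C_75", Method.PLANT_FEEDBACK, 75)
C50 = ZoneConfig("C_50", Method.PLANT_FEEDBACK, 50)
C25 = ZoneConfig("C_25", Method.PLANT_FEEDBACK, 25)
H75 = ZoneConfig("H_75", Method.HYBRID, 75, soil_station_id="S5")
H50 = ZoneConfig("H_50", Method.HYBRID, 50, soil_station_id="S8")
M75 = ZoneConfig("M_75", Method.MANUAL, 75)


class TestTierClassification:
    @pytest.mark.parametrize("icwsi, tier", [
        (0.0, Tier.NONE), (149.9, Tier.NONE),
        (150.0, Tier.I), (249.9, Tier.I),
        (250.0, Tier.II), (324.9, Tier.II),
        (325.0, Tier.III), (600.0, Tier.III),
    ])
    def test_half_open_lower_inclusive_bounds(self, icwsi, tier):
        assert tier_for_icwsi(icwsi) is tier

    def test_negative_index_rejected(self):
        with pytest.raises(ValidationError):
            tier_for_icwsi(-1.0)

    def test_table_bounds_must_ascend(self):
        with pytest.raises(ValidationError):
            ThresholdTable(tier_bounds=(250.0, 150.0, 325.0))


class TestDepthLookup:
    @pytest.mark.parametrize("level, tier, mm", [
        (75, Tier.I, 17.0), (75, Tier.II, 25.0), (75, Tier.III, 35.0),
        (50, Tier.I, 12.5), (50, Tier.II, 17.0), (50, Tier.III, 25.0),
        (25, Tier.I, 7.0), (25, Tier.II, 12.5), (25, Tier.III, 17.0),
        (50, Tier.NONE, 0.0),
    ])
    def test_depth_matrix(self, level, tier, mm):
        assert depth_for(level, tier) == mm

    @pytest.mark.parametrize("level", [100, 0])
    def test_non_tier_levels_rejected(self, level):
        with pytest.raises(ValidationError):
            depth_for(level, Tier.I)


class TestPlantFeedback:
    @pytest.mark.parametrize("zone, icwsi, depth, trigger", [
        (C75, 300.0, 25.0, Trigger.TIER_II),
        (C25, 100.0, 0.0, Trigger.NONE),
        (C50, 400.0, 25.0, Trigger.TIER_III),
    ])
    def test_tier_composition(self, zone, icwsi, depth, trigger):
        d = plant_feedback_decision(zone, icwsi, D)
        assert (d.depth, d.trigger) == (depth, trigger)
        assert d.inputs_used["icwsi"] == icwsi

    def test_wrong_method_rejected(self):
        with pytest.raises(ValidationError):
            plant_feedback_decision(H75, 300.0, D)


class TestHybridGating:
    def test_wet_profile_withholds_despite_stress(self):
        d = hybrid_decision(H75, swd=0.05, icwsi=400.0, date=D)
        assert d.depth == 0.0
        assert d.trigger is Trigger.WITHHELD_SWD_MIN

    def test_dry_profile_applies_maximum_depth(self):
        d = hybrid_decision(H75, swd=0.70, icwsi=0.0, date=D)
        assert d.depth == 35.0
        assert d.trigger is Trigger.SWD_MAX

    def test_mid_range_defers_to_tiers(self):
        d = hybrid_decision(H50, swd=0.30, icwsi=200.0, date=D)
        assert d.depth == 12.5
        assert d.trigger is Trigger.TIER_I

    @pytest.mark.parametrize("swd", [0.10, 0.65])
    def test_gate_boundaries_inclusive(self, swd):
        d = hybrid_decision(H75, swd=swd, icwsi=200.0, date=D)
        if swd == 0.10:
            assert d.trigger is Trigger.WITHHELD_SWD_MIN
        else:
            assert (d.depth, d.trigger) == (35.0, Trigger.SWD_MAX)

    def test_missing_soil_reading_falls_back_to_tiers(self):
        rng = np.random.default_rng(42)
        pf75 = ZoneConfig("H_75", Method.PLANT_FEEDBACK, 75)
        for icwsi in rng.uniform(0.0, 600.0, 1000):
            h = hybrid_decision(H75, swd=None, icwsi=icwsi, date=D)
            c = plant_feedback_decision(pf75, icwsi, D)
            assert (h.depth, h.trigger) == (c.depth, c.trigger)

    def test_out_of_range_swd_rejected(self):
        with pytest.raises(ValidationError):
            hybrid_decision(H75, swd=1.2, icwsi=100.0, date=D)

    def test_hybrid_requires_station(self):
        with pytest.raises(ValidationError):
            ZoneConfig("H_bad", Method.HYBRID, 75)


class TestManual:
    @pytest.mark.parametrize("level, depletion, depth", [
        (100, 40.0, 40.0), (50, 40.0, 20.0), (75, 33.3, 25.0),
    ])
    def test_percent_replenishment(self, level, depletion, depth):
        z = ZoneConfig(f"M_{level}", Method.MANUAL, level)
        d = manual_decision(z, depletion, D)
        assert d.depth == pytest.approx(depth)
        assert d.trigger is Trigger.MANUAL

    def test_negative_depletion_rejected(self):
        with pytest.raises(ValidationError):
            manual_decision(M75, -1.0, D)

    def test_zero_depletion_gives_no_trigger(self):
        d = manual_decision(M75, 0.0, D)
        assert (d.depth, d.trigger) == (0.0, Trigger.NONE)


class TestPrescriptionMap:
    ZONES = [C75, H50, ZoneConfig("M_0", Method.MANUAL, 0)]

    def test_three_zone_composition(self):
        state = {"C_75": {"icwsi": 300.0},
                 "H_50": {"icwsi": 0.0, "swd": 0.70},
                 "M_0": {}}
        pmap = build_prescription_map(self.ZONES, state, D)
        assert [d.depth for d in pmap.entries] == [25.0, 25.0, 0.0]

    def test_unstressed_field_gets_all_zero_map(self):
        state = {"C_75": {"icwsi": 10.0},
                 "H_50": {"icwsi": 10.0, "swd": 0.30},
                 "M_0": {}}
        pmap = build_prescription_map(self.ZONES, state, D)
        assert all(d.depth == 0.0 for d in pmap.entries)

    def test_duplicate_zone_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_prescription_map([C75, C75], {"C_75": {"icwsi": 0.0}}, D)

    def test_missing_state_names_zone_and_variable(self):
        with pytest.raises(ValidationError, match="H_50.*swd"):
            build_prescription_map(self.ZONES, {
                "C_75": {"icwsi": 0.0}, "H_50": {"icwsi": 0.0}, "M_0": {},
            }, D)

    def test_level_100_zone_replenishes_fully(self):
        zones = [ZoneConfig("M_100", Method.MANUAL, 100)]
        pmap = build_prescription_map(zones, {"M_100": {"depletion_mm": 31.4}}, D)
        assert pmap.entries[0].depth == pytest.approx(31.4)

    @settings(derandomize=True, max_examples=80)
    @given(
        icwsi=st.floats(0, 600), bump=st.floats(0, 100),
        swd=st.floats(0, 1), swd_bump=st.floats(0, 0.3),
    )
    def test_depth_monotone_in_stress_and_depletion(
        self, icwsi, bump, swd, swd_bump,
    ):
        zc = ZoneConfig("C", Method.PLANT_FEEDBACK, 75)
        assert (plant_feedback_decision(zc, icwsi + bump, D).depth
                >= plant_feedback_decision(zc, icwsi, D).depth)
        zh = ZoneConfig("H", Method.HYBRID, 75, soil_station_id="S")
        hi = hybrid_decision(zh, min(swd + swd_bump, 1.0), icwsi, D).depth
        lo = hybrid_decision(zh, swd, icwsi, D).depth
        assert hi >= lo

    @settings(derandomize=True, max_examples=80)
    @given(
        icwsi=st.floats(0, 600),
        swd=st.one_of(st.none(), st.floats(0, 1)),
        level=st.sampled_from([75, 50, 25]),
    )
    def test_emitted_depths_come_from_the_table(self, icwsi, swd, level):
        table = ThresholdTable()
        allowed = {0.0} | set(table.depths[level])
        zh = ZoneConfig("H", Method.HYBRID, level, soil_station_id="S")
        assert hybrid_decision(zh, swd, icwsi, D).depth in allowed
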