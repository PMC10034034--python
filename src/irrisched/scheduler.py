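"""The irrigation decision engine.

Maps each management zone's sensor state to a prescribed depth under
one of three scheduling methods:

* **manual** — replenish a percentage (the zone's level) of the soil
  water depletion measured in the fully irrigated reference plots;
* **plant_feedback** — trigger from the daily integrated crop water
  stress index (iCWSI) against three tiered thresholds, each tier
  carrying a fixed depth per irrigation level;
* **hybrid** — gate the plant-feedback logic with soil water depletion
  (SWD): withhold when the profile is wet (SWD <= 0.10), apply the
  level's maximum depth when critically dry (SWD >= 0.65), and fall
  back to the iCWSI tiers in between or when the soil sensor is down.

A scheduling pass over all zones yields a prescription map: one
decision per zone, each recording its trigger and the sensor inputs it
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from enum import Enum

from .weather import ValidationError

__all__ = [
    "Method",
    "Tier",
    "Trigger",
    "ThresholdTable",
    "ZoneConfig",
    "Decision",
    "PrescriptionMap",
    "tier_for_icwsi",
    "depth_for",
    "plant_feedback_decision",
    "hybrid_decision",
    "manual_decision",
    "build_prescription_map",
    "SWD_MIN_GATE",
    "SWD_MAX_GATE",
]

#: Hybrid-method soil water depletion gates (fractions of
#: plant-available water): withhold at or below the minimum, apply the
#: level's maximum depth at or above the maximum.
SWD_MIN_GATE = 0.10
SWD_MAX_GATE = 0.65

#: Emitted depths are rounded to this many decimals (0.1 mm).
DEPTH_DECIMALS = 1


class Method(str, Enum):
    MANUAL = "manual"
    PLANT_FEEDBACK = "plant_feedback"
    HYBRID = "hybrid"


class Tier(str, Enum):
    NONE = "none"
    I = "I"
    II = "II"
    III = "III"


class Trigger(str, Enum):
    NONE = "none"
    TIER_I = "tier_I"
    TIER_II = "tier_II"
    TIER_III = "tier_III"
    SWD_MAX = "swd_max"
    MANUAL = "manual"
    WITHHELD_SWD_MIN = "withheld_swd_min"


_TIER_TRIGGER = {Tier.I: Trigger.TIER_I, Tier.II: Trigger.TIER_II,
                 Tier.III: Trigger.TIER_III}

#: Irrigation levels scheduled through the tier table.
TIER_SCHEDULED_LEVELS = (75, 50, 25)


@dataclass(frozen=True)
class ThresholdTable:
    """iCWSI tier cut points and the depth (mm) per level x tier.

    Defaults: tiers open at 150 (minimum stress), 250 (medium) and 325
    (maximum); depths 17/25/35 mm at the 75% level, 12.5/17/25 at 50%,
    and 7/12.5/17 at 25%.
    """

    tier_bounds: tuple[float, float, float] = (150.0, 250.0, 325.0)
    depths: dict = field(default_factory=lambda: {
        75: (17.0, 25.0, 35.0),
        50: (12.5, 17.0, 25.0),
        25: (7.0, 12.5, 17.0),
    })

    def __post_init__(self) -> None:
        b = self.tier_bounds
        if not (b[0] < b[1] < b[2]):
            raise ValidationError(f"tier bounds must ascend, got {b}")
        for level, row in self.depths.items():
            if len(row) != 3:
                raise ValidationError(f"level {level}: need 3 tier depths")
            if any(d < 0 for d in row):
                raise ValidationError(f"level {level}: negative depth")
            if not (row[0] <= row[1] <= row[2]):
                raise ValidationError(
                    f"level {level}: depths must not decrease across tiers"
                )


@dataclass(frozen=True)
class ZoneConfig:
    """A management zone: identity, scheduling method, and level.

    ``level`` is the percent-of-full irrigation target (100, 75, 50, 25
    or 0); hybrid zones name the soil station whose SWD gates them.
    ``geometry`` (start/end angle deg, inner/outer radius m of an
    annular sector) is carried as metadata only.
    """

    zone_id: str
    method: Method
    level: int
    soil_station_id: str | None = None
    geometry: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        if self.level not in (100, 75, 50, 25, 0):
            raise ValidationError(
                f"zone {self.zone_id}: level must be one of 100/75/50/25/0, "
                f"got {self.level}"
            )
        if self.method is Method.HYBRID and not self.soil_station_id:
            raise ValidationError(
                f"hybrid zone {self.zone_id} must reference a soil station"
            )


@dataclass(frozen=True)
class Decision:
    """One zone's prescribed depth for one day, with its provenance."""

    zone_id: str
    date: _date
    depth: float
    trigger: Trigger
    inputs_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        zero_triggers = (Trigger.NONE, Trigger.WITHHELD_SWD_MIN)
        if (self.depth == 0) != (self.trigger in zero_triggers):
            raise ValidationError(
                f"zone {self.zone_id}: depth {self.depth} inconsistent with "
                f"trigger {self.trigger.value}"
            )


@dataclass(frozen=True)
class PrescriptionMap:
    """One scheduling pass: exactly one decision per configured zone."""

    date: _date
    entries: tuple[Decision, ...]

    def __post_init__(self) -> None:
        ids = [d.zone_id for d in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({z for z in ids if ids.count(z) > 1})
            raise ValidationError(f"duplicate zone(s) in map: {dupes}")

    def depth_for_zone(self, zone_id: str) -> float:
        for d in self.entries:
            if d.zone_id == zone_id:
                return d.depth
        raise KeyError(zone_id)


# ---------------------------------------------------------------------------
# tier logic
# ---------------------------------------------------------------------------

def tier_for_icwsi(icwsi: float, table: ThresholdTable | None = None) -> Tier:
    """Classify a daily iCWSI into a stress tier.

    Bounds are half-open, lower-inclusive: below the first cut point is
    no stress; at or above the last is tier III (maximum stress).
    """
    if icwsi < 0:
        raise ValidationError(f"icwsi must be >= 0, got {icwsi}")
    b = (table or ThresholdTable()).tier_bounds
    if icwsi < b[0]:
        return Tier.NONE
    if icwsi < b[1]:
        return Tier.I
    if icwsi < b[2]:
        return Tier.II
    return Tier.III


def depth_for(level: int, tier: Tier, table: ThresholdTable | None = None) -> float:
    """Look up the prescribed depth (mm) for a tier-scheduled level."""
    if level not in TIER_SCHEDULED_LEVELS:
        raise ValidationError(
            f"level {level} is not tier-scheduled (expected one of "
            f"{TIER_SCHEDULED_LEVELS})"
        )
    if tier is Tier.NONE:
        return 0.0
    row = (table or ThresholdTable()).depths[level]
    return float(row[{Tier.I: 0, Tier.II: 1, Tier.III: 2}[tier]])


def _round_depth(depth: float) -> float:
    return round(depth, DEPTH_DECIMALS)


# ---------------------------------------------------------------------------
# per-method decisions
# ---------------------------------------------------------------------------

def plant_feedback_decision(
    zone: ZoneConfig,
    icwsi: float,
    date: _date | None = None,
    table: ThresholdTable | None = None,
) -> Decision:
    """Decide from the iCWSI tiers alone (the plant-feedback method)."""
    if zone.method is not Method.PLANT_FEEDBACK:
        raise ValidationError(
            f"zone {zone.zone_id} is {zone.method.value}, not plant_feedback"
        )
    return _tier_decision(zone, icwsi, date, table, inputs={"icwsi": icwsi})


def _tier_decision(zone, icwsi, date, table, inputs) -> Decision:
    tier = tier_for_icwsi(icwsi, table)
    depth = _round_depth(depth_for(zone.level, tier, table))
    trigger = _TIER_TRIGGER.get(tier, Trigger.NONE)
    if depth == 0:
        trigger = Trigger.NONE
    return Decision(
        zone_id=zone.zone_id, date=date or _date.today(),
        depth=depth, trigger=trigger, inputs_used=dict(inputs),
    )


def hybrid_decision(
    zone: ZoneConfig,
    swd: float | None,
    icwsi: float,
    date: _date | None = None,
    table: ThresholdTable | None = None,
) -> Decision:
    """Decide from SWD gating with iCWSI fallback (the hybrid method).

    Wet profile (SWD <= 0.10): withhold regardless of canopy stress.
    Critically dry (SWD >= 0.65): apply the level's tier-III (maximum)
    depth.  In between — or when the soil reading is missing through
    sensor or communication failure — defer to the iCWSI tiers.
    """
    if zone.method is not Method.HYBRID:
        raise ValidationError(
            f"zone {zone.zone_id} is {zone.method.value}, not hybrid"
        )
    d = date or _date.today()
    inputs = {"icwsi": icwsi, "swd": swd}
    if swd is None:
        return _tier_decision(zone, icwsi, d, table, inputs)
    if not 0.0 <= swd <= 1.0:
        raise ValidationError(
            f"zone {zone.zone_id}: swd {swd} outside [0, 1]"
        )
    if swd <= SWD_MIN_GATE:
        return Decision(
            zone_id=zone.zone_id, date=d, depth=0.0,
            trigger=Trigger.WITHHELD_SWD_MIN, inputs_used=inputs,
        )
    if swd >= SWD_MAX_GATE:
        depth = _round_depth(depth_for(zone.level, Tier.III, table))
        return Decision(
            zone_id=zone.zone_id, date=d, depth=depth,
            trigger=Trigger.SWD_MAX, inputs_used=inputs,
        )
    return _tier_decision(zone, icwsi, d, table, inputs)


def manual_decision(
    zone: ZoneConfig,
    depletion_mm: float,
    date: _date | None = None,
) -> Decision:
    """Replenish the zone's level percentage of reference-plot depletion.

    ``depletion_mm`` is the mean root-zone deficit to near field
    capacity measured in the fully irrigated reference plots; a 75%
    zone receives three quarters of it.
    """
    if zone.method is not Method.MANUAL:
        raise ValidationError(
            f"zone {zone.zone_id} is {zone.method.value}, not manual"
        )
    if depletion_mm < 0:
        raise ValidationError(
            f"zone {zone.zone_id}: negative depletion {depletion_mm}"
        )
    depth = _round_depth(zone.level / 100.0 * depletion_mm)
    trigger = Trigger.MANUAL if depth > 0 else Trigger.NONE
    return Decision(
        zone_id=zone.zone_id, date=date or _date.today(), depth=depth,
        trigger=trigger, inputs_used={"depletion_mm": depletion_mm},
    )


# ---------------------------------------------------------------------------
# prescription map
# ---------------------------------------------------------------------------

def build_prescription_map(
    zones: list[ZoneConfig],
    state: dict,
    date: _date | None = None,
    table: ThresholdTable | None = None,
) -> PrescriptionMap:
    """Assemble one decision per zone from per-zone sensor state.

    ``state`` maps zone_id to a dict with the keys the zone's method
    needs: ``icwsi`` for plant-feedback and hybrid, ``swd`` for hybrid
    (present-but-None records a sensor outage and falls back to the
    iCWSI tiers), ``depletion_mm`` for manual zones.  Level-100 zones
    replenish fully; level-0 zones never receive scheduled water.
    """
    d = date or _date.today()
    ids = [z.zone_id for z in zones]
    if len(set(ids)) != len(ids):
        dupes = sorted({z for z in ids if ids.count(z) > 1})
        raise ValidationError(f"duplicate zone(s) configured: {dupes}")

    decisions = []
    for zone in zones:
        zs = state.get(zone.zone_id, {})
        if zone.level == 0:
            dec = Decision(zone.zone_id, d, 0.0, Trigger.NONE, {})
        elif zone.method is Method.MANUAL or zone.level == 100:
            if "depletion_mm" not in zs:
                raise ValidationError(
                    f"zone {zone.zone_id}: missing required state 'depletion_mm'"
                )
            mz = zone if zone.method is Method.MANUAL else ZoneConfig(
                zone.zone_id, Method.MANUAL, zone.level
            )
            dec = manual_decision(mz, zs["depletion_mm"], d)
        elif zone.method is Method.PLANT_FEEDBACK:
            if "icwsi" not in zs:
                raise ValidationError(
                    f"zone {zone.zone_id}: missing required state 'icwsi'"
                )
            dec = plant_feedback_decision(zone, zs["icwsi"], d, table)
        else:  # hybrid
            if "icwsi" not in zs:
                raise ValidationError(
                    f"zone {zone.zone_id}: missing required state 'icwsi'"
                )
            if "swd" not in zs:
                raise ValidationError(
                    f"zone {zone.zone_id}: missing required state 'swd' "
                    "(use None to record a sensor outage)"
                )
            dec = hybrid_decision(zone, zs["swd"], zs["icwsi"], d, table)
        decisions.append(dec)
    return PrescriptionMap(date=d, entries=tuple(decisions))
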