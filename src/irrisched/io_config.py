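"""Run configuration and prescription-map serialization.

The run configuration is a single YAML file holding the site constants
(threshold table, energy-balance parameters, soil retention constants),
the zone roster, optional replicate pooling groups, and the scan
cadence.  Prescription maps round-trip through JSON or flat CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path

import pandas as pd
import yaml

from .scheduler import (
    Decision,
    Method,
    PrescriptionMap,
    ThresholdTable,
    Trigger,
    ZoneConfig,
)
from .soil import (
    DEFAULT_THETA_FC,
    DEFAULT_THETA_PWP,
    TDR_LAYER_BOUNDS_CM,
    SoilLayer,
    SoilProfile,
)
from .weather import EnergyBalanceParams, ValidationError

__all__ = [
    "RunConfig",
    "SoilConstants",
    "PoolingGroup",
    "load_config",
    "write_prescription",
    "read_prescription",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SoilConstants:
    """Layer partition and retention constants shared by all stations."""

    layer_bounds_cm: tuple = TDR_LAYER_BOUNDS_CM
    theta_fc: tuple = DEFAULT_THETA_FC
    theta_pwp: float = DEFAULT_THETA_PWP

    def __post_init__(self) -> None:
        b = self.layer_bounds_cm
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValidationError(f"soil.layer_bounds_cm must ascend, got {b}")
        if len(self.theta_fc) != len(b) - 1:
            raise ValidationError(
                "soil.theta_fc must supply one value per layer "
                f"({len(b) - 1}), got {len(self.theta_fc)}"
            )

    def profile(self, theta_v) -> SoilProfile:
        """Build a profile from per-layer volumetric water contents."""
        b = self.layer_bounds_cm
        layers = tuple(
            SoilLayer(
                depth_top=b[i], depth_bottom=b[i + 1],
                theta_fc=self.theta_fc[i], theta_pwp=self.theta_pwp,
                theta_v=float(theta_v[i]),
            )
            for i in range(len(b) - 1)
        )
        return SoilProfile(layers)


@dataclass(frozen=True)
class PoolingGroup:
    """Replicate zones sharing one soil station and a pooled iCWSI."""

    zones: tuple
    soil_station_id: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Validated site + roster configuration for a scheduling run."""

    zones: tuple
    table: ThresholdTable = field(default_factory=ThresholdTable)
    ebp: EnergyBalanceParams = field(default_factory=EnergyBalanceParams)
    soil: SoilConstants = field(default_factory=SoilConstants)
    reference_zones: tuple = ()
    pooling: tuple = ()
    scan_cadence_days: int = 3
    fc_fraction: float = 0.96
    manual_max_depth_cm: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        dupes = sorted({z for z in ids if ids.count(z) > 1})
        if dupes:
            raise ValidationError(f"zones: duplicate zone_id {dupes}")
        known = set(ids)
        for r in self.reference_zones:
            if r not in known:
                raise ValidationError(f"reference_zones: unknown zone {r!r}")
        for g in self.pooling:
            for z in g.zones:
                if z not in known:
                    raise ValidationError(f"pooling: unknown zone {z!r}")

    def zone(self, zone_id: str) -> ZoneConfig:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)


def _as_tuple3(v, key):
    try:
        t = tuple(float(x) for x in v)
    except (TypeError, ValueError):
        raise ValidationError(f"{key}: expected a list of numbers, got {v!r}")
    return t


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unset sections fall back to the packaged defaults (tier table,
    energy-balance parameters, Pullman soil constants).  Errors name
    the offending key path.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")

    try:
        table = ThresholdTable(
            tier_bounds=_as_tuple3(
                raw.get("thresholds", {}).get("tier_bounds", (150, 250, 325)),
                "thresholds.tier_bounds",
            ),
            depths={
                int(k): tuple(float(x) for x in v)
                for k, v in raw.get("thresholds", {}).get("depths", {
                    75: (17, 25, 35), 50: (12.5, 17, 25), 25: (7, 12.5, 17),
                }).items()
            },
        )
    except (TypeError, ValueError) as e:
        raise ValidationError(f"thresholds: {e}") from e

    eb = raw.get("energy_balance", {})
    try:
        ebp = EnergyBalanceParams(**{
            k: float(v) for k, v in eb.items()
            if k in ("ra", "rcp", "gamma", "rho_cp", "rn_g_coeff", "rn_minus_g")
        })
    except (TypeError, ValueError) as e:
        raise ValidationError(f"energy_balance: {e}") from e

    sc = raw.get("soil", {})
    soil = SoilConstants(
        layer_bounds_cm=tuple(sc.get("layer_bounds_cm", TDR_LAYER_BOUNDS_CM)),
        theta_fc=tuple(sc.get("theta_fc", DEFAULT_THETA_FC)),
        theta_pwp=float(sc.get("theta_pwp", DEFAULT_THETA_PWP)),
    )

    zones = []
    for i, zr in enumerate(raw.get("zones", [])):
        if not isinstance(zr, dict) or "zone_id" not in zr:
            raise ValidationError(f"zones[{i}]: each zone needs a zone_id")
        method = zr.get("method", "manual")
        if method not in Method._value2member_map_:
            raise ValidationError(
                f"zones[{i}].method: unknown method {method!r} "
                f"(expected one of {[m.value for m in Method]})"
            )
        try:
            zones.append(ZoneConfig(
                zone_id=str(zr["zone_id"]),
                method=Method(method),
                level=int(zr.get("level", 0)),
                soil_station_id=zr.get("soil_station_id"),
                geometry=tuple(zr["geometry"]) if "geometry" in zr else None,
            ))
        except (TypeError, ValueError) as e:
            raise ValidationError(f"zones[{i}]: {e}") from e
    if not zones:
        raise ValidationError("zones: at least one zone is required")

    pooling = tuple(
        PoolingGroup(
            zones=tuple(g.get("zones", ())),
            soil_station_id=g.get("soil_station_id"),
        )
        for g in raw.get("pooling", [])
    )

    manual = raw.get("manual", {})
    return RunConfig(
        zones=tuple(zones),
        table=table,
        ebp=ebp,
        soil=soil,
        reference_zones=tuple(raw.get("reference_zones", ())),
        pooling=pooling,
        scan_cadence_days=int(raw.get("scan_cadence_days", 3)),
        fc_fraction=float(manual.get("fc_fraction", 0.96)),
        manual_max_depth_cm=float(manual.get("max_depth_cm", 150.0)),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# prescription-map serialization
# ---------------------------------------------------------------------------

def _map_records(pmap: PrescriptionMap) -> list[dict]:
    return [
        {
            "zone_id": d.zone_id,
            "depth_mm": d.depth,
            "trigger": d.trigger.value,
            "inputs_used": {
                k: (None if v is None else round(float(v), 6))
                for k, v in d.inputs_used.items()
            },
        }
        for d in pmap.entries
    ]


def write_prescription(pmap: PrescriptionMap, path, format: str = "json") -> None:
    """Write a prescription map as JSON or flat CSV (round-trip safe)."""
    path = Path(path)
    if format == "json":
        payload = {"date": pmap.date.isoformat(), "entries": _map_records(pmap)}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        rows = []
        for r in _map_records(pmap):
            row = {"date": pmap.date.isoformat(), "zone_id": r["zone_id"],
                   "depth_mm": r["depth_mm"], "trigger": r["trigger"]}
            for k, v in r["inputs_used"].items():
                row[f"input_{k}"] = v
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown prescription format {format!r}")


def read_prescription(path, format: str | None = None) -> PrescriptionMap:
    """Read a prescription map written by :func:`write_prescription`."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "json")
    if fmt == "json":
        payload = json.loads(path.read_text())
        date = _date.fromisoformat(payload["date"])
        entries = tuple(
            Decision(
                zone_id=r["zone_id"], date=date, depth=float(r["depth_mm"]),
                trigger=Trigger(r["trigger"]),
                inputs_used={k: v for k, v in r.get("inputs_used", {}).items()
                             if v is not None},
            )
            for r in payload["entries"]
        )
        return PrescriptionMap(date=date, entries=entries)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: empty prescription CSV")
    date = _date.fromisoformat(str(df["date"].iloc[0]))
    entries = []
    for _, row in df.iterrows():
        inputs = {
            c[len("input_"):]: float(row[c])
            for c in df.columns if c.startswith("input_") and not pd.isna(row[c])
        }
        entries.append(Decision(
            zone_id=str(row["zone_id"]), date=date,
            depth=float(row["depth_mm"]), trigger=Trigger(row["trigger"]),
            inputs_used=inputs,
        ))
    return PrescriptionMap(date=date, entries=tuple(entries))
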