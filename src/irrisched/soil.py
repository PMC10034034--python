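"""Layered soil-water accounting.

Three bookkeeping views of the same profile serve three scheduling
methods: a depth-weighted fractional depletion of plant-available water
over the sensed layers (the hybrid method's SWD gate), a millimetre
deficit to a near-field-capacity target over the root zone (the manual
method's replenishment amount), and a seasonal water balance closing to
crop evapotranspiration (ET_c = I + P + F - dS - R).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .weather import ValidationError

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SeasonLedger",
    "layer_fractional_depletion",
    "profile_swd",
    "depletion_to_target",
    "seasonal_etc",
    "default_profile",
    "read_soil_csv",
    "TDR_SENSOR_DEPTHS_CM",
    "DEFAULT_THETA_FC",
    "DEFAULT_THETA_PWP",
]

#: TDR installation depths (cm) and the midpoint layer partition they
#: imply over a 60 cm sensed profile.
TDR_SENSOR_DEPTHS_CM = (10.0, 20.0, 30.0, 50.0)
TDR_LAYER_BOUNDS_CM = (0.0, 15.0, 25.0, 40.0, 60.0)

#: Default field capacity per sensed layer and common wilting point,
#: m3 m-3 (Pullman clay loam).
DEFAULT_THETA_FC = (0.35, 0.34, 0.33, 0.33)
DEFAULT_THETA_PWP = 0.18

#: Physical upper bound on volumetric water content (porosity), m3 m-3.
POROSITY_BOUND = 0.60

#: mm of water per (cm of soil x m3 m-3 of content).
MM_PER_CM_THETA = 10.0


@dataclass(frozen=True)
class SoilLayer:
    """One horizontal soil layer with water-retention constants.

    Depths in cm from the surface; water contents volumetric (m3 m-3).
    """

    depth_top: float
    depth_bottom: float
    theta_fc: float
    theta_pwp: float
    theta_v: float

    def __post_init__(self) -> None:
        if self.depth_bottom <= self.depth_top:
            raise ValidationError(
                f"layer bottom {self.depth_bottom} must exceed top {self.depth_top}"
            )
        if self.theta_fc <= self.theta_pwp:
            raise ValidationError(
                f"theta_fc ({self.theta_fc}) must exceed theta_pwp ({self.theta_pwp})"
            )
        if not 0.0 <= self.theta_v <= POROSITY_BOUND:
            raise ValidationError(
                f"theta_v ({self.theta_v}) outside [0, {POROSITY_BOUND}]"
            )

    @property
    def thickness(self) -> float:
        """Layer thickness, cm."""
        return self.depth_bottom - self.depth_top

    @property
    def storage_mm(self) -> float:
        """Water stored in the layer, mm."""
        return self.theta_v * self.thickness * MM_PER_CM_THETA


@dataclass(frozen=True)
class SoilProfile:
    """Ordered, contiguous stack of soil layers from the surface down."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError("profile must contain at least one layer")
        if self.layers[0].depth_top != 0.0:
            raise ValidationError("first layer must start at the surface")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if lower.depth_top != upper.depth_bottom:
                raise ValidationError(
                    f"layers not contiguous at {upper.depth_bottom} cm"
                )

    @property
    def depth_cm(self) -> float:
        return self.layers[-1].depth_bottom

    @property
    def storage_mm(self) -> float:
        """Total profile water storage, mm."""
        return sum(l.storage_mm for l in self.layers)

    def with_theta(self, theta_v) -> "SoilProfile":
        """Copy of the profile with per-layer water contents replaced."""
        theta = np.broadcast_to(np.asarray(theta_v, dtype=float), (len(self.layers),))
        return SoilProfile(
            tuple(replace(l, theta_v=float(t)) for l, t in zip(self.layers, theta))
        )


def default_profile(theta_v=0.30) -> SoilProfile:
    """The four-layer sensed profile implied by TDRs at 10/20/30/50 cm.

    Midpoint layer bounds 0-15, 15-25, 25-40, 40-60 cm with the default
    Pullman retention constants; ``theta_v`` may be a scalar or one
    value per layer.
    """
    theta = np.broadcast_to(np.asarray(theta_v, dtype=float), (4,))
    layers = tuple(
        SoilLayer(
            depth_top=TDR_LAYER_BOUNDS_CM[i],
            depth_bottom=TDR_LAYER_BOUNDS_CM[i + 1],
            theta_fc=DEFAULT_THETA_FC[i],
            theta_pwp=DEFAULT_THETA_PWP,
            theta_v=float(theta[i]),
        )
        for i in range(4)
    )
    return SoilProfile(layers)


# ---------------------------------------------------------------------------
# depletion
# ---------------------------------------------------------------------------

def layer_fractional_depletion(layer: SoilLayer) -> float:
    """Fraction of the layer's plant-available water already consumed.

    ``(theta_fc - theta_v) / (theta_fc - theta_pwp)`` clamped to [0, 1]:
    0 at field capacity, 1 at the permanent wilting point.
    """
    f = (layer.theta_fc - layer.theta_v) / (layer.theta_fc - layer.theta_pwp)
    return float(np.clip(f, 0.0, 1.0))


def profile_swd(profile: SoilProfile) -> float:
    """Soil water depletion: thickness-weighted mean fractional depletion.

    ``sum(l_i * f_i) / sum(l_i)`` over the sensed layers, a
    dimensionless fraction in [0, 1] comparable against the 0.10
    (withhold) and 0.65 (maximum-depth) scheduling gates.
    """
    weights = np.array([l.thickness for l in profile.layers])
    fracs = np.array([layer_fractional_depletion(l) for l in profile.layers])
    return float(np.dot(weights, fracs) / weights.sum())


def depletion_to_target(
    profile: SoilProfile, fc_fraction: float = 0.96, max_depth: float = 150.0
) -> float:
    """Millimetres needed to refill the root zone to near field capacity.

    Sums ``max(0, fc_fraction * theta_fc - theta_v) * thickness`` over
    layers within ``max_depth`` cm, pro-rating a layer straddling the
    boundary; layers wetter than their target contribute nothing.  The
    0.96 default reflects refilling to 96% of field capacity.
    """
    if not 0.0 < fc_fraction <= 1.0:
        raise ValidationError(f"fc_fraction must be in (0, 1], got {fc_fraction}")
    if max_depth <= 0:
        raise ValidationError(f"max_depth must be > 0, got {max_depth}")
    total = 0.0
    for l in profile.layers:
        overlap = min(l.depth_bottom, max_depth) - l.depth_top
        if overlap <= 0:
            break
        deficit = max(0.0, fc_fraction * l.theta_fc - l.theta_v)
        total += deficit * overlap * MM_PER_CM_THETA
    return total


# ---------------------------------------------------------------------------
# seasonal water balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonLedger:
    """Season water balance, all in mm.

    ``delta_s`` is end-of-season minus start-of-season profile storage,
    so a season that draws the profile down (negative ``delta_s``) adds
    to crop evapotranspiration.
    """

    irrigation: float
    precip: float
    delta_s: float
    flux: float = 0.0
    runoff: float = 0.0

    def __post_init__(self) -> None:
        if self.irrigation < 0 or self.precip < 0:
            raise ValidationError("irrigation and precip must be >= 0")

    @property
    def etc(self) -> float:
        """Seasonal crop evapotranspiration: I + P + F - dS - R."""
        return self.irrigation + self.precip + self.flux - self.delta_s - self.runoff


def seasonal_etc(
    irrigation: float,
    precip: float,
    delta_s: float,
    flux: float = 0.0,
    runoff: float = 0.0,
) -> SeasonLedger:
    """Assemble a season ledger; boundary flux and runoff default to zero."""
    return SeasonLedger(
        irrigation=irrigation,
        precip=precip,
        delta_s=delta_s,
        flux=flux,
        runoff=runoff,
    )


# ---------------------------------------------------------------------------
# CSV reader
# ---------------------------------------------------------------------------

def read_soil_csv(path) -> pd.DataFrame:
    """Read a soil-moisture CSV: ``timestamp, station_id, depth_cm, theta_v``."""
    df = pd.read_csv(path)
    missing = [
        c for c in ("timestamp", "station_id", "depth_cm", "theta_v")
        if c not in df.columns
    ]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if ((df["theta_v"] < 0) | (df["theta_v"] > POROSITY_BOUND)).any():
        raise ValidationError(f"{path}: theta_v outside [0, {POROSITY_BOUND}]")
    return df
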