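"""Seasonal performance metrics.

Crop water productivity (CWP) converts seed-cotton yield per hectare
and seasonal water use in millimetres to kg of yield per cubic metre of
water; irrigation water use efficiency (IWUE) is the marginal yield per
marginal unit of crop evapotranspiration relative to a minimally
irrigated control; percent water saving compares a treatment's
cumulative irrigation with the fully irrigated control.
"""

from __future__ import annotations

from dataclasses import dataclass

from .soil import SeasonLedger
from .weather import ValidationError

__all__ = [
    "HarvestRecord",
    "crop_water_productivity",
    "irrigation_water_use_efficiency",
    "percent_water_saving",
    "KG_HA_MM_TO_KG_M3",
]

#: (kg ha-1) / mm -> kg m-3: 1 kg ha-1 = 1e-4 kg m-2, 1 mm = 1e-3 m.
KG_HA_MM_TO_KG_M3 = 0.1


@dataclass(frozen=True)
class HarvestRecord:
    """Seed-cotton yield (kg ha-1) and the season water ledger for a zone."""

    zone_id: str
    seed_cotton_yield: float
    ledger: SeasonLedger

    def __post_init__(self) -> None:
        if self.seed_cotton_yield < 0:
            raise ValidationError(
                f"zone {self.zone_id}: negative yield {self.seed_cotton_yield}"
            )


def crop_water_productivity(yield_kg_ha: float, water_mm: float) -> float:
    """CWP (kg m-3): yield per unit of seasonal water use.

    ``0.1 * yield / water`` for yield in kg ha-1 and water in mm.  The
    water term is precipitation + irrigation + storage drawdown — equal
    to seasonal crop evapotranspiration when boundary flux and runoff
    are zero — and is supplied by the caller.
    """
    if water_mm <= 0:
        raise ValidationError(f"water must be > 0 mm, got {water_mm}")
    return KG_HA_MM_TO_KG_M3 * yield_kg_ha / water_mm


def irrigation_water_use_efficiency(
    yield_p: float, yield_0: float, etc_p: float, etc_0: float
) -> float:
    """IWUE (kg m-3): marginal yield over marginal crop water use.

    ``0.1 * (yield_p - yield_0) / (etc_p - etc_0)`` against a minimally
    irrigated control; negative when the treatment yields less than the
    control despite using more water.
    """
    if etc_p == etc_0:
        raise ValidationError(
            "IWUE undefined: treatment and control ET_c are equal"
        )
    return KG_HA_MM_TO_KG_M3 * (yield_p - yield_0) / (etc_p - etc_0)


def percent_water_saving(control_mm: float, treatment_mm: float) -> int:
    """Percent less irrigation than the control, to the nearest integer.

    ``100 (control - treatment) / control``; negative if the treatment
    received more water than the control.
    """
    if control_mm <= 0:
        raise ValidationError(f"control must be > 0 mm, got {control_mm}")
    if treatment_mm < 0:
        raise ValidationError(f"treatment must be >= 0 mm, got {treatment_mm}")
    return round(100.0 * (control_mm - treatment_mm) / control_mm)
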