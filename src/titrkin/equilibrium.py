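"""Gas-liquid oxygen equilibrium via a calibrated Henry's-law model.

The tube-in-tube reactor controls dissolved oxygen through the gas-side
absolute pressure and O2 mole fraction.  At the operating temperature the
equilibrium dissolved concentration is linear in the O2 partial pressure
(Henry's law); the proportionality constant is anchored to a measured
solubility rather than taken from a generic correlation, because published
solubilities for real buffers differ from pure-water values.

Two literature anchors are supported out of the box:

* ``air_anchor`` — water in equilibrium with air at 1 atm holds 276 uM O2.
* ``high_pressure_anchor`` — 7.13 mM dissolved O2 under pure O2 at 6 bar.

The two anchors are *not* mutually consistent under a single linear law
(linear extrapolation of the air value to pure O2 at 6 bar gives ~7.8 mM,
not 7.13 mM), plausibly reflecting buffer salting-out or a different
tabulated constant.  They are therefore kept as distinct first-class
calibrations and never merged; every computation states which one it uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "GasCondition",
    "HenryCalibration",
    "AIR_O2_FRACTION",
    "P_ATM_BAR",
    "o2_partial_pressure",
    "saturation_concentration",
    "saturation_ratio",
    "water_vapor_pressure_bar",
]

#: Mole fraction of O2 in dry air.
AIR_O2_FRACTION = 0.2095
#: Standard atmosphere in bar.
P_ATM_BAR = 1.01325


def water_vapor_pressure_bar(temperature_C: float) -> float:
    """Saturation vapor pressure of water, Antoine equation (1-100 degC).

    log10(P/mmHg) = 8.07131 - 1730.63 / (233.426 + T).  Returns bar.
    """
    if not 0.0 < temperature_C < 100.0:
        raise ValueError(f"Antoine correlation valid for 0-100 degC, got {temperature_C}")
    p_mmHg = 10.0 ** (8.07131 - 1730.63 / (233.426 + temperature_C))
    return p_mmHg * 1.01325 / 760.0


@dataclass(frozen=True)
class GasCondition:
    """Gas-side state: absolute pressure [bar], O2 mole fraction, temperature [degC]."""

    pressure_bar: float
    o2_fraction: float
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if not self.pressure_bar > 0:
            raise ValueError(f"pressure must be > 0 bar, got {self.pressure_bar}")
        if not 0.0 <= self.o2_fraction <= 1.0:
            raise ValueError(f"o2_fraction must lie in [0, 1], got {self.o2_fraction}")


#: Air at one standard atmosphere, 25 degC.
AIR_1ATM = GasCondition(P_ATM_BAR, AIR_O2_FRACTION, 25.0)
#: Pure oxygen at 6 bar absolute, 25 degC.
PURE_O2_6BAR = GasCondition(6.0, 1.0, 25.0)


def o2_partial_pressure(gas: GasCondition, correct_vapor: bool = False) -> float:
    """O2 partial pressure [bar]; optionally subtract water vapor first.

    With ``correct_vapor`` the gas is assumed saturated with water at the
    operating temperature (the feed gas is wetted to avoid stripping water
    through the membrane), so the dry-gas fraction applies to
    ``pressure - p_vap`` only.
    """
    p = gas.pressure_bar
    if correct_vapor:
        p = p - water_vapor_pressure_bar(gas.temperature_C)
        if p <= 0:
            raise ValueError(
                "total pressure does not exceed water vapor pressure: "
                f"{gas.pressure_bar:.4f} bar at {gas.temperature_C} degC"
            )
    return p * gas.o2_fraction


@dataclass(frozen=True)
class HenryCalibration:
    """Solubility law c_sat = H * pO2, anchored to one measured point.

    mode
        ``air_anchor``, ``high_pressure_anchor`` or ``explicit_constant``.
    anchor_concentration_mM, anchor_condition
        The measured dissolved O2 and the gas condition it corresponds to
        (anchor modes only).
    constant_mM_per_bar
        The Henry constant directly (explicit mode only).
    water_vapor_correction
        Whether partial pressures (anchor and query alike) are vapor-corrected.
        Off by default.
    """

    mode: Literal["air_anchor", "high_pressure_anchor", "explicit_constant"]
    anchor_concentration_mM: float | None = None
    anchor_condition: GasCondition | None = None
    constant_mM_per_bar: float | None = None
    temperature_C: float = 25.0
    water_vapor_correction: bool = False

    def __post_init__(self) -> None:
        if self.mode == "explicit_constant":
            if self.constant_mM_per_bar is None or not self.constant_mM_per_bar > 0:
                raise ValueError("explicit_constant mode requires constant_mM_per_bar > 0")
        else:
            if self.anchor_concentration_mM is None or not self.anchor_concentration_mM > 0:
                raise ValueError(f"{self.mode} mode requires anchor_concentration_mM > 0")
            if self.anchor_condition is None:
                raise ValueError(f"{self.mode} mode requires an anchor_condition")

    @classmethod
    def air_anchor(
        cls,
        anchor_concentration_mM: float = 0.276,
        anchor_condition: GasCondition = AIR_1ATM,
        water_vapor_correction: bool = False,
    ) -> "HenryCalibration":
        """Calibration through the air-saturation point (276 uM at 1 atm)."""
        return cls(
            mode="air_anchor",
            anchor_concentration_mM=anchor_concentration_mM,
            anchor_condition=anchor_condition,
            temperature_C=anchor_condition.temperature_C,
            water_vapor_correction=water_vapor_correction,
        )

    @classmethod
    def high_pressure_anchor(
        cls,
        anchor_concentration_mM: float = 7.13,
        anchor_condition: GasCondition = PURE_O2_6BAR,
        water_vapor_correction: bool = False,
    ) -> "HenryCalibration":
        """Calibration through the pressurized point (7.13 mM, pure O2, 6 bar)."""
        return cls(
            mode="high_pressure_anchor",
            anchor_concentration_mM=anchor_concentration_mM,
            anchor_condition=anchor_condition,
            temperature_C=anchor_condition.temperature_C,
            water_vapor_correction=water_vapor_correction,
        )

    @classmethod
    def explicit(cls, constant_mM_per_bar: float, temperature_C: float = 25.0) -> "HenryCalibration":
        return cls(
            mode="explicit_constant",
            constant_mM_per_bar=constant_mM_per_bar,
            temperature_C=temperature_C,
        )

    @property
    def henry_constant_mM_per_bar(self) -> float:
        """Dissolved O2 per bar of O2 partial pressure."""
        if self.mode == "explicit_constant":
            return self.constant_mM_per_bar  # type: ignore[return-value]
        p_anchor = o2_partial_pressure(self.anchor_condition, self.water_vapor_correction)
        if p_anchor <= 0:
            raise ValueError("anchor condition has zero O2 partial pressure")
        return self.anchor_concentration_mM / p_anchor  # type: ignore[operator]


def saturation_concentration(gas: GasCondition, cal: HenryCalibration) -> float:
    """Equilibrium dissolved O2 [mM] for ``gas`` under calibration ``cal``.

    The calibration is valid only at its own temperature: querying another
    temperature raises rather than extrapolating silently.
    """
    if not math.isclose(gas.temperature_C, cal.temperature_C, abs_tol=1e-9):
        raise ValueError(
            f"calibration anchored at {cal.temperature_C} degC cannot be applied at "
            f"{gas.temperature_C} degC; supply an explicit constant for that temperature"
        )
    return cal.henry_constant_mM_per_bar * o2_partial_pressure(gas, cal.water_vapor_correction)


def saturation_ratio(
    gas_a: GasCondition,
    gas_b: GasCondition,
    cal_a: HenryCalibration,
    cal_b: HenryCalibration,
) -> float:
    """Fold difference saturation(gas_a)/saturation(gas_b).

    Used for claims such as the fold-increase of pressurized pure O2 over
    air-saturated water.  The two conditions may carry different
    calibrations (see module docstring on the anchor inconsistency).
    """
    denom = saturation_concentration(gas_b, cal_b)
    if denom <= 0:
        raise ZeroDivisionError("reference condition has zero equilibrium O2")
    return saturation_concentration(gas_a, cal_a) / denom
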