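"""Richmann law-of-mixtures calculations for sizing cold-water additions.

When two bodies of water at different temperatures are combined, the
equilibrium temperature is the heat-capacity-weighted mean

    T_f = (m1 c1 T1 + m2 c2 T2) / (m1 c1 + m2 c2).

Unit contract: water density is fixed at 1.0 g/cm^3, so volumes in litres are
used interchangeably with masses in kilograms. Specific heat defaults to
4.18 J/(g degC); for water-water mixtures at a shared c the value cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "WATER_SPECIFIC_HEAT",
    "MixtureComponent",
    "mixture_final_temp",
    "required_cold_volume",
    "required_cold_temp",
    "tabulate_drops",
    "round_half_up",
]

#: Specific heat capacity of liquid water, J/(g degC).
WATER_SPECIFIC_HEAT = 4.18


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (0.005 -> 0.01), not to even."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MixtureComponent:
    """A body of water entering a mixture.

    mass is in litres-of-water treated as kg; temperature in deg C (must be
    liquid water, 0-100); specific_heat in J/(g degC).
    """

    mass: float
    temperature: float
    specific_heat: float = WATER_SPECIFIC_HEAT

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be non-negative")
        if self.specific_heat <= 0:
            raise ValueError("specific_heat must be positive")
        if not 0.0 <= self.temperature <= 100.0:
            raise ValueError(
                f"temperature {self.temperature} degC outside liquid-water band [0, 100]"
            )

    @property
    def heat_capacity(self) -> float:
        """m * c, the weight this component carries in the mixture mean."""
        return self.mass * self.specific_heat


def mixture_final_temp(components: Iterable[MixtureComponent]) -> float:
    """Equilibrium temperature of a mixture of water bodies, deg C.

    Raises ``ValueError`` when every component has zero mass (the mixture is
    undefined). The result always lies within [min, max] of the component
    temperatures.
    """
    comps = list(components)
    if not comps:
        raise ValueError("mixture needs at least one component")
    total_capacity = sum(c.heat_capacity for c in comps)
    if total_capacity == 0.0:
        raise ValueError("undefined mixture: all component masses are zero")
    return sum(c.heat_capacity * c.temperature for c in comps) / total_capacity


def required_cold_volume(
    bath_mass: float, bath_temp: float, cold_temp: float, target_final: float
) -> float:
    """Litres of cold water at ``cold_temp`` that bring the bath to ``target_final``.

    Algebraic inversion of the mixture law under equal specific heats:
    m2 = m1 (T1 - Tf) / (Tf - T2). The target must lie strictly between the
    cold-water and bath temperatures, otherwise it is unreachable by mixing.
    """
    if bath_mass <= 0:
        raise ValueError("bath_mass must be positive")
    if not cold_temp < target_final < bath_temp:
        raise ValueError(
            f"target {target_final} degC unreachable by mixing: must lie in "
            f"({cold_temp}, {bath_temp}) degC"
        )
    return bath_mass * (bath_temp - target_final) / (target_final - cold_temp)


def required_cold_temp(
    bath_mass: float, bath_temp: float, cold_volume: float, target_final: float
) -> float:
    """Temperature the added water must have for a fixed addition volume.

    Second inversion of the mixture law under equal specific heats:
    T2 = (Tf (m1 + m2) - m1 T1) / m2. Emits a ``UserWarning`` when the result
    is below 0 degC, i.e. infeasible with liquid water and the volume needs
    readjusting.
    """
    if bath_mass <= 0:
        raise ValueError("bath_mass must be positive")
    if cold_volume <= 0:
        raise ValueError("cold_volume must be positive")
    if target_final > bath_temp:
        raise ValueError("target_final cannot exceed the bath temperature")
    t2 = (target_final * (bath_mass + cold_volume) - bath_mass * bath_temp) / cold_volume
    if t2 < 0.0:
        warnings.warn(
            f"required cold-water temperature {t2:.2f} degC is below freezing; "
            "infeasible with liquid water -- increase the addition volume",
            UserWarning,
            stacklevel=2,
        )
    return t2


def tabulate_drops(
    bath_mass: float,
    bath_temp: float,
    cold_temp: float,
    volumes: Sequence[float],
    specific_heat: float = WATER_SPECIFIC_HEAT,
) -> pd.DataFrame:
    """Mixture-law final temperatures and drops for a series of addition volumes.

    Returns a DataFrame with columns ``volume_L``, ``final_temp_C``, ``drop_C``
    (full precision; apply :func:`round_half_up` for a 2-dp printed table).
    ``final_temp_C`` is strictly decreasing in volume whenever the cold water
    is colder than the bath.
    """
    if len(volumes) == 0:
        raise ValueError("volumes must be non-empty")
    if any(v <= 0 for v in volumes):
        raise ValueError("each addition volume must be positive")
    bath = MixtureComponent(bath_mass, bath_temp, specific_heat)
    rows = []
    for v in volumes:
        tf = mixture_final_temp([bath, MixtureComponent(v, cold_temp, specific_heat)])
        rows.append((float(v), tf, bath_temp - tf))
    return pd.DataFrame(rows, columns=["volume_L", "final_temp_C", "drop_C"])
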