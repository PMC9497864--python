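"""Process energy consumption of a convective drying run.

The electrical-heater energy to hold the drying air at temperature T for
time t across a tray of area A is

    ET [kWh] = A * v * rho_a * Ca * dT * t,

with the air volumetric flow A*v (m^3/s), ideal-gas air density rho_a
(kg/m^3), dry-air specific heat Ca (kJ/(kg K)), temperature lift dT above
ambient (K) and t in hours (A*v*rho_a*Ca*dT is a power in kW).  The
specific energy Es = ET / Wi normalises by the fresh load.

Air properties are evaluated at the drying-air absolute temperature:
rho_a = 101.325 / (0.287 Tabs) and a quartic dry-air cp correlation valid
over 250-450 K.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DryerConfig",
    "EnergyResult",
    "air_density",
    "air_specific_heat",
    "total_energy",
    "specific_energy",
    "energy_for_run",
]

_CP_COEFFS = (1.04841, -3.83719e-4, 9.45378e-7, -5.49031e-10, 7.92981e-14)


@dataclass(frozen=True)
class DryerConfig:
    """Dryer geometry and loading.

    tray_area has no universal default (it is rig-specific) and must be
    supplied explicitly.  ambient_temperature is the reference for the
    temperature lift dT, degC.
    """

    tray_area: float  # m^2
    air_velocity: float = 1.5  # m/s
    ambient_temperature: float = 25.0  # degC
    initial_load: float = 0.88  # kg

    def __post_init__(self) -> None:
        for name in ("tray_area", "air_velocity", "initial_load"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EnergyResult:
    run_id: str
    air_density: float  # kg/m^3
    specific_heat: float  # kJ/(kg K)
    total_energy: float  # kWh
    specific_energy: float  # kWh/kg
    absolute_temperature: float  # K
    drying_time_h: float


def air_density(tabs: float) -> float:
    """Ideal-gas density of dry air at absolute temperature tabs (K)."""
    if tabs <= 0:
        raise ValueError("absolute temperature must be positive")
    return 101.325 / (0.287 * tabs)


def air_specific_heat(tabs: float) -> float:
    """Dry-air specific heat (kJ/(kg K)) from a quartic in Tabs, 250-450 K."""
    if not 250.0 <= tabs <= 450.0:
        raise ValueError(f"specific-heat correlation valid for 250-450 K, got {tabs} K")
    c0, c1, c2, c3, c4 = _CP_COEFFS
    return c0 + c1 * tabs + c2 * tabs**2 + c3 * tabs**3 + c4 * tabs**4


def total_energy(
    config: DryerConfig,
    drying_temperature: float,
    drying_time_h: float,
    rho_a: float | None = None,
    c_a: float | None = None,
) -> float:
    """Heater energy ET (kWh) for one run at the given air temperature.

    Air density and specific heat are evaluated at the drying-air
    temperature unless overridden (overrides are convenient for worked
    examples with round-number properties).
    """
    if drying_time_h < 0:
        raise ValueError("drying time must be non-negative")
    dt = drying_temperature - config.ambient_temperature
    if dt <= 0:
        raise ValueError(
            f"drying temperature ({drying_temperature} degC) must exceed ambient "
            f"({config.ambient_temperature} degC)"
        )
    tabs = drying_temperature + 273.15
    rho = air_density(tabs) if rho_a is None else rho_a
    cp = air_specific_heat(tabs) if c_a is None else c_a
    power_kw = config.tray_area * config.air_velocity * rho * cp * dt
    return power_kw * drying_time_h


def specific_energy(et_kwh: float, initial_load: float) -> float:
    """Specific energy Es = ET / Wi (kWh per kg of fresh load)."""
    if initial_load <= 0:
        raise ValueError("initial load must be positive")
    return et_kwh / initial_load


def energy_for_run(config: DryerConfig, run_id: str, drying_temperature: float,
                   drying_time_h: float, initial_load: float | None = None) -> EnergyResult:
    """Full energy report for one run under a dryer configuration."""
    tabs = drying_temperature + 273.15
    et = total_energy(config, drying_temperature, drying_time_h)
    wi = config.initial_load if initial_load is None else initial_load
    return EnergyResult(
        run_id=run_id,
        air_density=air_density(tabs),
        specific_heat=air_specific_heat(tabs),
        total_energy=et,
        specific_energy=specific_energy(et, wi),
        absolute_temperature=tabs,
        drying_time_h=drying_time_h,
    )
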