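"""Drying-curve primitives: weight series -> moisture content, moisture
ratio, and drying rate.

A drying run records the weight of a tray of slices at scheduled times.
Dry-basis moisture content is ``(W - W_dry) / W_dry``; the moisture ratio
normalises it by the initial (optionally equilibrium-corrected) value; the
drying rate is the moisture lost per hour between consecutive weighings.

Internal units: time in minutes, moisture as a fraction (kg water per kg
dry matter), thickness in metres.  Drying rate is reported per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt


def _as_float_array(x) -> npt.NDArray[np.float64]:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class DryingRun:
    """One convective drying experiment: conditions plus a time/weight series.

    Parameters
    ----------
    run_id : str
        Identifier for the run.
    temperature : float
        Drying-air temperature, degC (> 0).
    thickness : float
        Full slice thickness, m (> 0).
    air_velocity : float
        Drying-air velocity, m/s (> 0).
    initial_load : float
        Fresh sample weight loaded on the tray, kg.
    dry_mass : float
        Bone-dry matter mass of the load, kg.
    times : array-like
        Weighing times in minutes, strictly increasing, first element 0.
    weights : array-like
        Tray load weight at each time, kg; every weight must exceed dry_mass.
    initial_moisture_db : float
        Initial moisture content, kg water / kg dry matter.
    """

    run_id: str
    temperature: float
    thickness: float
    air_velocity: float
    initial_load: float
    dry_mass: float
    times: npt.NDArray[np.float64]
    weights: npt.NDArray[np.float64]
    initial_moisture_db: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "weights", _as_float_array(self.weights))
        t, w = self.times, self.weights
        if t.ndim != 1 or w.ndim != 1 or len(t) != len(w):
            raise ValueError("times and weights must be 1-D arrays of equal length")
        if len(t) == 0:
            raise ValueError("empty run")
        if t[0] != 0:
            raise ValueError(f"times must start at 0, got {t[0]}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.dry_mass <= 0:
            raise ValueError("dry_mass must be positive")
        bad = np.flatnonzero(w <= self.dry_mass)
        if bad.size:
            raise ValueError(
                f"weight at index {bad[0]} ({w[bad[0]]:.6g} kg) does not exceed "
                f"dry mass ({self.dry_mass:.6g} kg)"
            )
        if self.thickness <= 0 or self.air_velocity <= 0 or self.temperature <= 0:
            raise ValueError("thickness, air_velocity and temperature must be positive")

    @property
    def duration_minutes(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class MoistureSeries:
    """Dry-basis moisture content Mt over time, kg water / kg dry matter."""

    times: npt.NDArray[np.float64]
    moisture_db: npt.NDArray[np.float64]
    equilibrium_moisture_db: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "moisture_db", _as_float_array(self.moisture_db))
        if len(self.times) != len(self.moisture_db):
            raise ValueError("times and moisture_db must have equal length")
        if np.any(self.moisture_db < 0):
            raise ValueError("moisture content cannot be negative")


@dataclass(frozen=True)
class RatioSeries:
    """Dimensionless moisture ratio MR over time; MR[0] = 1 by construction."""

    times: npt.NDArray[np.float64]
    mr: npt.NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_float_array(self.times))
        object.__setattr__(self, "mr", _as_float_array(self.mr))


@dataclass(frozen=True)
class RateSeries:
    """Drying rate between consecutive weighings, kg water/(kg dry matter * h)."""

    mid_times: npt.NDArray[np.float64]
    dr: npt.NDArray[np.float64]
    dt_minutes: npt.NDArray[np.float64] = field(default=None)  # type: ignore[assignment]


def moisture_from_weights(run: DryingRun) -> MoistureSeries:
    """Convert a run's weight series to dry-basis moisture content.

    Mt[i] = (W[i] - W_dry) / W_dry.  The run invariants guarantee every
    weight exceeds the dry mass, so moisture is strictly positive.
    """
    moisture = (run.weights - run.dry_mass) / run.dry_mass
    return MoistureSeries(times=run.times, moisture_db=moisture)


def weights_from_moisture(series: MoistureSeries, dry_mass: float) -> npt.NDArray[np.float64]:
    """Inverse of :func:`moisture_from_weights`: W = W_dry * (1 + Mt)."""
    return dry_mass * (1.0 + series.moisture_db)


def moisture_ratio(series: MoistureSeries) -> RatioSeries:
    """Normalise a moisture series to the dimensionless moisture ratio.

    With equilibrium moisture Me given, MR = (Mt - Me) / (M0 - Me); with the
    default Me = 0 this reduces to MR = Mt / M0 (the usual simplification
    when equilibrium moisture is negligible against the drying range).
    """
    m0 = float(series.moisture_db[0])
    me = float(series.equilibrium_moisture_db)
    if m0 == me:
        raise ZeroDivisionError("initial moisture equals equilibrium moisture; MR undefined")
    if m0 < me:
        raise ValueError("initial moisture must exceed equilibrium moisture")
    mr = (series.moisture_db - me) / (m0 - me)
    return RatioSeries(times=series.times, mr=mr)


def drying_rate(series: MoistureSeries) -> RateSeries:
    """Finite-difference drying rate per hour between consecutive weighings.

    DR[i] = (Mt[i] - Mt[i+1]) / dt[i] with dt in hours; positive while the
    sample loses moisture.  Midpoint times locate each interval.
    """
    if len(series.times) < 2:
        raise ValueError("drying rate needs at least two points")
    dt_min = np.diff(series.times)
    if np.any(dt_min == 0):
        raise ValueError("duplicated time points (zero interval)")
    dr = -np.diff(series.moisture_db) / (dt_min / 60.0)
    mid = (series.times[:-1] + series.times[1:]) / 2.0
    return RateSeries(mid_times=mid, dr=dr, dt_minutes=dt_min)
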