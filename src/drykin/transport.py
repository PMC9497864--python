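"""Moisture transport properties: effective diffusivity, activation energy,
and the Dincer-number route to the mass-transfer Biot number and convective
mass-transfer coefficient.

Slope method (slab geometry)
----------------------------
In the falling-rate period the Fick slab solution, truncated to its first
term, gives

    MR(t) = (8/pi^2) exp(-pi^2 Deff t / (4 L^2)),       L = half thickness,

so ln MR is linear in time and Deff follows from the regression slope:
Deff = -slope * 4 L^2 / pi^2 (slope converted to 1/s first).

Arrhenius law
-------------
Deff = D0 exp(-Ea / (R (T + 273.15))) with R = 8.314e-3 kJ/(mol K);
Ea comes from regressing ln Deff on 1/(T + 273.15).

Dincer chain
------------
Di = v / (k L) with the drying constant k in 1/min, air velocity v in m/s
and L the full slice thickness in m — the empirical unit convention of the
source correlation (dimensionally mixed; a strict-SI variant converts k to
1/s).  Then Bi = 24.848 * Di^(-0.375) and hm = Bi * Deff / L (valid for
Bi > 0.1).  Note the two length conventions: the slope method uses the half
thickness, the Dincer chain the full thickness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .curves import DryingRun
from .fitting import ThinLayerModel, ThinLayerResults

__all__ = [
    "GAS_CONSTANT_KJ_MOL_K",
    "SlopeRegression",
    "TransportResult",
    "ArrheniusResult",
    "fick_slab_mr",
    "estimate_deff",
    "arrhenius_fit",
    "dincer_number",
    "biot_number",
    "mass_transfer_coefficient",
    "transport_table",
]

GAS_CONSTANT_KJ_MOL_K = 8.314e-3

_DINCER_COEF = 24.848
_DINCER_EXP = -0.375


@dataclass(frozen=True)
class SlopeRegression:
    """ln(MR)-vs-time OLS diagnostics behind a Deff estimate."""

    slope_per_min: float
    intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class TransportResult:
    """Transport chain for one run: Deff, Di, Bi, hm and the lengths used."""

    run_id: str
    temperature: float
    thickness: float
    deff: float
    slope: SlopeRegression | None
    dincer: float
    biot: float
    hm: float
    characteristic_length_deff: float  # half thickness, m
    characteristic_length_bi: float  # full thickness, m
    drying_constant_per_min: float


@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius fit of Deff(T) for one thickness group."""

    ea: float  # kJ/mol
    d0: float  # m^2/s
    r2: float
    n_points: int
    gas_constant: float = GAS_CONSTANT_KJ_MOL_K

    def summary(self) -> str:
        return (
            f"Arrhenius fit (n={self.n_points}): Ea = {self.ea:.2f} kJ/mol, "
            f"D0 = {self.d0:.3e} m^2/s, R^2 = {self.r2:.4f}"
        )


def fick_slab_mr(times_min, deff: float, thickness: float, n_terms: int = 1):
    """Forward Fick slab series MR(t) for an infinite slab of given thickness.

    ``n_terms=1`` is the long-time single-term form used by the slope
    method; larger ``n_terms`` sums the series (terms below 1e-12 are
    dropped) for round-trip testing of the estimator.  Times in minutes,
    Deff in m^2/s, thickness the full slice thickness in m.
    """
    if deff <= 0 or thickness <= 0:
        raise ValueError("deff and thickness must be positive")
    t_s = np.asarray(times_min, dtype=float) * 60.0
    half = thickness / 2.0
    tau = math.pi**2 * deff * t_s / (4.0 * half**2)
    mr = np.zeros_like(t_s)
    for n in range(max(1, n_terms)):
        coef = 8.0 / (math.pi**2 * (2 * n + 1) ** 2)
        term = coef * np.exp(-((2 * n + 1) ** 2) * tau)
        mr += term
        if n > 0 and np.all(term < 1e-12):
            break
    return mr


def estimate_deff(
    times_min,
    mr,
    thickness: float,
    mr_floor: float = 0.02,
    mr_ceiling: float = 0.95,
) -> tuple[float, SlopeRegression]:
    """Effective moisture diffusivity from the ln(MR) slope.

    Regresses ln MR on time over points with mr_floor < MR <= mr_ceiling
    (excluding the pre-falling-rate start and the noise-dominated tail) and
    converts the slope with the half-thickness slab relation.  Raises if
    fewer than three usable points remain or if moisture is not decreasing.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(mr, dtype=float)
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if np.any(y <= 0):
        raise ValueError("moisture ratio must be positive for the log transform")
    mask = (y > mr_floor) & (y <= mr_ceiling)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points with MR in ({mr_floor}, {mr_ceiling}]; need >= 3"
        )
    slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
    if slope >= 0:
        raise ValueError("non-negative ln(MR) slope: moisture not decreasing")
    resid = np.log(y[mask]) - (slope * t[mask] + intercept)
    ss_tot = float(np.sum((np.log(y[mask]) - np.log(y[mask]).mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    half = thickness / 2.0
    slope_per_s = slope / 60.0
    deff = -slope_per_s * 4.0 * half**2 / math.pi**2
    reg = SlopeRegression(
        slope_per_min=float(slope), intercept=float(intercept), r2=r2, n_points=int(mask.sum())
    )
    return deff, reg


def arrhenius_fit(temperatures_C, deffs) -> ArrheniusResult:
    """Fit Deff = D0 exp(-Ea / (R (T+273.15))) by ln-linear least squares."""
    temps = np.asarray(temperatures_C, dtype=float)
    d = np.asarray(deffs, dtype=float)
    if temps.shape != d.shape or temps.ndim != 1:
        raise ValueError("temperatures and deffs must be 1-D arrays of equal length")
    if len(np.unique(temps)) < 2:
        raise ValueError("Arrhenius fit needs at least two distinct temperatures")
    if np.any(d <= 0):
        raise ValueError("diffusivities must be positive")
    x = 1.0 / (temps + 273.15)
    y = np.log(d)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ArrheniusResult(
        ea=float(-slope * GAS_CONSTANT_KJ_MOL_K),
        d0=float(np.exp(intercept)),
        r2=r2,
        n_points=len(temps),
    )


def dincer_number(
    air_velocity: float, k_per_min: float, thickness: float, strict_si: bool = False
) -> float:
    """Dincer number Di = v / (k L), L the full slice thickness.

    Default keeps the drying constant in 1/min alongside v in m/s — the
    mixed unit convention of the published correlation chain.  With
    ``strict_si=True`` the drying constant is converted to 1/s first.
    """
    if air_velocity <= 0 or k_per_min <= 0 or thickness <= 0:
        raise ValueError("air velocity, drying constant and thickness must be positive")
    k = k_per_min / 60.0 if strict_si else k_per_min
    return air_velocity / (k * thickness)


def biot_number(di: float) -> float:
    """Mass-transfer Biot number from the Dincer correlation, 24.848 Di^-0.375."""
    if di <= 0:
        raise ValueError("Dincer number must be positive")
    return _DINCER_COEF * di**_DINCER_EXP


def mass_transfer_coefficient(bi: float, deff: float, thickness: float) -> float:
    """Convective mass-transfer coefficient hm = Bi * Deff / L (m/s).

    L is the full slice thickness.  The Biot-number route is only
    considered valid for Bi > 0.1; smaller values trigger a warning.
    """
    if bi <= 0 or deff <= 0 or thickness <= 0:
        raise ValueError("Bi, Deff and thickness must be positive")
    if bi <= 0.1:
        warnings.warn(
            f"Bi = {bi:.3g} <= 0.1: the Dincer-correlation route to hm is "
            "outside its stated validity range",
            stacklevel=2,
        )
    return bi * deff / thickness


def transport_chain(
    k_per_min: float,
    deff: float,
    thickness: float,
    air_velocity: float,
    strict_si: bool = False,
) -> tuple[float, float, float]:
    """(Di, Bi, hm) from a drying constant, a diffusivity and geometry."""
    di = dincer_number(air_velocity, k_per_min, thickness, strict_si=strict_si)
    bi = biot_number(di)
    hm = mass_transfer_coefficient(bi, deff, thickness)
    return di, bi, hm


def transport_table(
    runs: list[DryingRun],
    fits: dict[str, ThinLayerResults] | None = None,
    mr_floor: float = 0.02,
    mr_ceiling: float = 0.95,
) -> tuple[list[TransportResult], dict[float, ArrheniusResult], dict[str, str]]:
    """Per-run transport chain plus per-thickness Arrhenius fits.

    ``fits`` maps run_id to a fitted diffusion-approach results object
    (fitted on the spot when absent).  Returns (rows, arrhenius-by-thickness,
    failures-by-run_id); a run that fails is flagged without aborting the
    rest, and thickness groups with fewer than two temperatures simply have
    no Arrhenius entry.
    """
    rows: list[TransportResult] = []
    failures: dict[str, str] = {}
    for run in runs:
        try:
            fit = (fits or {}).get(run.run_id)
            if fit is None:
                fit = ThinLayerModel.from_run(run, model="diffusion_approach").fit()
            if not fit.converged:
                raise RuntimeError("diffusion-approach fit did not converge")
            k = fit.params.as_dict()["k"]
            from .curves import moisture_from_weights, moisture_ratio

            ratio = moisture_ratio(moisture_from_weights(run))
            deff, reg = estimate_deff(
                ratio.times, ratio.mr, run.thickness, mr_floor=mr_floor, mr_ceiling=mr_ceiling
            )
            di, bi, hm = transport_chain(k, deff, run.thickness, run.air_velocity)
            rows.append(
                TransportResult(
                    run_id=run.run_id,
                    temperature=run.temperature,
                    thickness=run.thickness,
                    deff=deff,
                    slope=reg,
                    dincer=di,
                    biot=bi,
                    hm=hm,
                    characteristic_length_deff=run.thickness / 2.0,
                    characteristic_length_bi=run.thickness,
                    drying_constant_per_min=k,
                )
            )
        except Exception as exc:
            failures[run.run_id] = str(exc)

    arrhenius: dict[float, ArrheniusResult] = {}
    by_thickness: dict[float, list[TransportResult]] = {}
    for row in rows:
        by_thickness.setdefault(row.thickness, []).append(row)
    for thickness, group in by_thickness.items():
        temps = [g.temperature for g in group]
        if len(set(temps)) >= 2:
            arrhenius[thickness] = arrhenius_fit(temps, [g.deff for g in group])
    return rows, arrhenius, failures
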