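"""Quantitative ink physics for thermally gelling hydrogel inks.

Covers the characterization models the planner consumes:

* Ostwald (power-law) shear-thinning viscosity, ``eta = K * gamma_dot**(n - 1)``,
  fitted by ordinary least squares in log-log space.
* Gel-point detection as the G'-G'' crossover temperature on a cooling sweep.
* Small-strain Hookean modulus (``sigma = E * eps``) from compression data.
* Series-circuit effective conductivity of multimaterial filaments
  (length-weighted harmonic mean of segment conductivities).
* A printability temperature window from gel points, and a lumped Newtonian
  cooling estimate of the temperature drop during ink switching.

All temperatures are degrees Celsius, lengths mm unless noted, moduli kPa,
viscosities Pa*s, conductivities S/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PowerLawFit",
    "RheologyCurve",
    "StressStrain",
    "InkSpec",
    "ConductivitySegmentSpec",
    "fit_power_law",
    "find_crossover",
    "fit_modulus",
    "series_conductivity",
    "specific_conductivity_from_resistance",
    "printability_window",
    "switching_temperature_drop",
    "gelation_risk",
    "read_shear_sweep",
    "read_rheology_curve",
    "read_stress_strain",
    "read_filament_resistances",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Ostwald power-law parameters: eta = K * gamma_dot**(n-1)."""

    K: float  # consistency index, Pa*s^n
    n: float  # flow index, dimensionless; n < 1 is shear thinning
    residual: float = 0.0  # RMS residual of the log-log fit

    def viscosity(self, shear_rate):
        """Model viscosity (Pa*s) at the given shear rate(s) (1/s)."""
        return self.K * np.asarray(shear_rate, dtype=float) ** (self.n - 1.0)

    @property
    def shear_thinning(self) -> bool:
        return self.n < 1.0


@dataclass(frozen=True)
class RheologyCurve:
    """Oscillatory temperature sweep: G', G'' and complex viscosity vs T."""

    temperature: tuple  # degC, strictly monotone
    G_storage: tuple  # Pa
    G_loss: tuple  # Pa
    complex_viscosity: tuple = ()  # Pa*s, optional

    def __post_init__(self):
        T = np.asarray(self.temperature, dtype=float)
        if len(T) != len(self.G_storage) or len(T) != len(self.G_loss):
            raise ValueError("temperature, G_storage and G_loss must have equal length")
        if self.complex_viscosity and len(self.complex_viscosity) != len(T):
            raise ValueError("complex_viscosity length mismatch")
        dT = np.diff(T)
        if len(T) > 1 and not (np.all(dT > 0) or np.all(dT < 0)):
            raise ValueError("temperatures must be strictly monotone")


@dataclass(frozen=True)
class StressStrain:
    """Uniaxial compression curve; strain dimensionless, stress kPa."""

    strain: tuple
    stress: tuple

    def __post_init__(self):
        eps = np.asarray(self.strain, dtype=float)
        if len(eps) != len(self.stress):
            raise ValueError("strain and stress must have equal length")
        if len(eps) and eps[0] < 0:
            raise ValueError("strain must start at >= 0")
        if np.any(np.diff(eps) <= 0):
            raise ValueError("strain must be strictly increasing")


@dataclass
class InkSpec:
    """Physical description of one hydrogel ink formulation.

    Concentrations are w/v%; ``cell_density`` is cells/mL. Model parameters
    are optional: an ink only needs the ones the planned object exercises.
    """

    ink_id: str
    agarose_concentration: float = 0.0
    swcnt_concentration: float = 0.0
    cell_density: float = 0.0
    power_law: PowerLawFit | None = None
    crossover_T: float | None = None  # gel point, degC
    youngs_modulus_E: float | None = None  # kPa
    specific_conductivity: float | None = None  # S/m

    def __post_init__(self):
        if self.agarose_concentration < 0 or self.swcnt_concentration < 0:
            raise ValueError("concentrations must be >= 0")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")


@dataclass(frozen=True)
class ConductivitySegmentSpec:
    """One resistor in the series-circuit view of a multimaterial filament."""

    ink_id: str
    length: float  # mm
    sigma: float  # specific conductivity, S/m

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("segment length must be > 0")
        if self.sigma <= 0:
            raise ValueError(f"segment {self.ink_id!r}: sigma must be > 0")


def fit_power_law(shear_rates, viscosities) -> PowerLawFit:
    """Fit the Ostwald model eta = K * gamma_dot**(n-1) by log-log OLS.

    The model linearizes to ``log eta = log K + (n-1) log gamma_dot``; the
    fit is ordinary least squares on the logs, which is deterministic and
    weights the decades of a shear sweep evenly.

    Parameters
    ----------
    shear_rates, viscosities
        Paired positive samples; at least 3 points.
    """
    g = np.asarray(shear_rates, dtype=float)
    eta = np.asarray(viscosities, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 points to fit the power law")
    if g.size != eta.size:
        raise ValueError("shear_rates and viscosities must have equal length")
    if np.any(g <= 0) or np.any(eta <= 0):
        raise ValueError("shear rates and viscosities must be positive")
    x, y = np.log(g), np.log(eta)
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return PowerLawFit(K=float(np.exp(intercept)), n=float(slope + 1.0), residual=resid)


def find_crossover(curve: RheologyCurve) -> float | None:
    """Gel point: the temperature where G' = G'' on the sweep.

    The crossing is located by linear interpolation of ``log G' - log G''``
    against temperature between the bracketing samples. If the curves cross
    more than once the highest-temperature crossing is returned (on cooling
    from the liquid side that is the first gelation event). Returns ``None``
    when the moduli never cross.
    """
    T = np.asarray(curve.temperature, dtype=float)
    d = np.log(np.asarray(curve.G_storage, dtype=float)) - np.log(
        np.asarray(curve.G_loss, dtype=float)
    )
    crossings = []
    for i in range(len(T) - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            crossings.append(float(T[i]))
        elif d0 * d1 < 0:
            crossings.append(float(T[i] + (T[i + 1] - T[i]) * d0 / (d0 - d1)))
    if len(T) and d[-1] == 0.0:
        crossings.append(float(T[-1]))
    if not crossings:
        return None
    return max(crossings)


def fit_modulus(curve: StressStrain, strain_window=(0.0, 0.04), *, intercept: bool = False):
    """Young's modulus E (kPa) from the small-strain window of a compression curve.

    By default fits ``sigma = E * eps`` (zero intercept) restricted to strains
    inside ``strain_window`` (inclusive), matching Hooke's law with prestrain
    already removed. ``intercept=True`` adds a free intercept and returns the
    slope only.
    """
    lo, hi = strain_window
    eps = np.asarray(curve.strain, dtype=float)
    sig = np.asarray(curve.stress, dtype=float)
    mask = (eps >= lo) & (eps <= hi)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 points inside the strain window")
    e, s = eps[mask], sig[mask]
    if intercept:
        slope, _ = np.polyfit(e, s, 1)
        return float(slope)
    denom = float(np.dot(e, e))
    if denom == 0.0:
        raise ValueError("strain window contains only zero strain")
    return float(np.dot(e, s) / denom)


def series_conductivity(segments, *, interface_equiv_length: float = 0.0) -> float:
    """Effective specific conductivity of segments treated as series resistors.

    With the shared cross-section cancelling, the series rule reduces to the
    length-weighted harmonic mean::

        sigma_eff = sum(L_i) / sum(L_i / sigma_i)

    ``interface_equiv_length`` (mm per S/m; default 0) adds a per-interface
    resistance term ``(k-1) * interface_equiv_length`` to the denominator —
    a hook for interfacial effects, off by default.
    """
    segs = list(segments)
    if not segs:
        raise ValueError("need at least one segment")
    total = sum(s.length for s in segs)
    denom = sum(s.length / s.sigma for s in segs)
    denom += (len(segs) - 1) * interface_equiv_length
    return total / denom


def specific_conductivity_from_resistance(R: float, length: float, diameter: float) -> float:
    """Specific conductivity sigma = L / (R * A) in S/m.

    Parameters: resistance ``R`` in ohm, filament ``length`` and ``diameter``
    in mm (converted to SI internally); A = pi d^2 / 4.
    """
    if R <= 0 or length <= 0 or diameter <= 0:
        raise ValueError("R, length and diameter must be positive")
    L_m = length * 1e-3
    A_m2 = math.pi * (diameter * 1e-3) ** 2 / 4.0
    return L_m / (R * A_m2)


def resistance_from_conductivity(sigma: float, length: float, diameter: float) -> float:
    """Inverse of :func:`specific_conductivity_from_resistance` (ohm)."""
    if sigma <= 0 or length <= 0 or diameter <= 0:
        raise ValueError("sigma, length and diameter must be positive")
    L_m = length * 1e-3
    A_m2 = math.pi * (diameter * 1e-3) ** 2 / 4.0
    return L_m / (sigma * A_m2)


def printability_window(inks, margin: float, ceiling: float):
    """Reservoir temperature window [T_low, T_high] keeping every ink liquid.

    T_low is the highest gel point among the inks plus a safety ``margin``;
    T_high is the supplied ``ceiling`` (e.g. a cell-viability or degradation
    limit). Raises if the window is empty or an ink lacks a gel point.
    """
    inks = list(inks)
    if not inks:
        raise ValueError("need at least one ink")
    for ink in inks:
        if ink.crossover_T is None:
            raise ValueError(f"ink {ink.ink_id!r} has no crossover_T")
    t_low = max(ink.crossover_T for ink in inks) + margin
    if t_low > ceiling:
        raise ValueError(
            f"empty printability window: need >= {t_low:g} degC but ceiling is {ceiling:g} degC"
        )
    return (t_low, ceiling)


def switching_temperature_drop(T0: float, T_env: float, elapsed: float, tau: float) -> float:
    """Lumped-capacitance (Newtonian) cooling of the aspirated column.

    ``T(t) = T_env + (T0 - T_env) * exp(-t / tau)`` with time constant ``tau``
    in seconds. Used to sanity-check that the capillary's excursion between
    reservoirs does not cool an already-aspirated ink below its gel point.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    return T_env + (T0 - T_env) * math.exp(-elapsed / tau)


def gelation_risk(temperature: float, inks) -> list:
    """Inks whose gel point lies above ``temperature`` (i.e. at risk of gelling)."""
    return [
        ink
        for ink in inks
        if ink.crossover_T is not None and temperature < ink.crossover_T
    ]


# ---------------------------------------------------------------------------
# CSV readers (column layouts documented per reader)

def read_shear_sweep(path):
    """Read (shear_rate, viscosity) CSV -> (shear_rates, viscosities) arrays."""
    df = pd.read_csv(path)
    return df["shear_rate"].to_numpy(float), df["viscosity"].to_numpy(float)


def read_rheology_curve(path) -> RheologyCurve:
    """Read (temperature, G_storage, G_loss[, viscosity]) CSV."""
    df = pd.read_csv(path)
    visc = tuple(df["viscosity"]) if "viscosity" in df.columns else ()
    return RheologyCurve(
        temperature=tuple(df["temperature"]),
        G_storage=tuple(df["G_storage"]),
        G_loss=tuple(df["G_loss"]),
        complex_viscosity=visc,
    )


def read_stress_strain(path) -> StressStrain:
    """Read (strain, stress) CSV; stress in kPa."""
    df = pd.read_csv(path)
    return StressStrain(strain=tuple(df["strain"]), stress=tuple(df["stress"]))


def read_filament_resistances(path) -> pd.DataFrame:
    """Read (filament_id, R_ohm, length_mm) CSV as a DataFrame."""
    df = pd.read_csv(path)
    missing = {"filament_id", "R_ohm", "length_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return df
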