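"""Free-air-chamber correction factors.

A parallel-plate free-air chamber (FAC) realizes air kerma from the
charge collected in a geometrically defined air volume.  The raw
charge-per-mass must be corrected for a set of small multiplicative
effects — ion recombination, humidity, in-chamber air attenuation,
electron loss, photon scatter, fluorescence and bremsstrahlung
reabsorption, initial-ion production, and diaphragm scatter.  This
module computes the spectrum-dependent factors from a photon spectrum,
chamber geometry and environmental conditions, and manages the adopted
constants and their uncertainties for the two NIST chambers used with
50 kV electronic brachytherapy sources (the Lamperti and Ritz FACs).

Conventions: factors are dimensionless multipliers applied in the
measurement equation; relative standard uncertainties are in percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .physics_tables import CoefficientTable, mix_coefficients
from .spectrometry import Spectrum

__all__ = [
    "FACGeometry",
    "EnvironmentalConditions",
    "WRatioModel",
    "BasisFunctionSet",
    "CorrectionSet",
    "chamber_preset",
    "k_ion_parametric",
    "k_ion_two_voltage",
    "humid_air_density",
    "water_vapor_mole_fraction",
    "k_humidity",
    "k_att",
    "mu_rho_eff",
    "interpolate_mu_eff_vs_L",
    "transport_correction",
    "load_basis_functions",
    "adopted_corrections",
]

# -- geometry and environment ---------------------------------------------


@dataclass(frozen=True)
class FACGeometry:
    """Critical dimensions of a parallel-plate free-air chamber (cm).

    ``attenuation_length`` L is the air path from the aperture plane to
    the mid-point of the collecting volume, so the aperture-to-collector
    offset is ``d_offset = L - collector_length/2``.
    """

    name: str
    diaphragm_diameter: float
    collector_length: float
    collector_width: float
    electrode_separation: float
    attenuation_length: float

    def __post_init__(self) -> None:
        for f in ("diaphragm_diameter", "collector_length",
                  "collector_width", "electrode_separation",
                  "attenuation_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.d_offset <= 0:
            raise ValueError("attenuation length shorter than half the "
                             "collector length")

    @property
    def d_offset(self) -> float:
        return self.attenuation_length - self.collector_length / 2.0

    @property
    def aperture_area(self) -> float:
        """Defining aperture area, cm²."""
        return math.pi * (self.diaphragm_diameter / 2.0) ** 2

    @property
    def v_eff(self) -> float:
        """Effective collecting volume: aperture area × collector length, cm³."""
        return self.aperture_area * self.collector_length


@dataclass(frozen=True)
class EnvironmentalConditions:
    """Laboratory air state: temperature (°C), pressure (kPa), RH (0–1)."""

    temperature: float = 22.0
    pressure: float = 101.325
    relative_humidity: float = 0.0
    co2_fraction: float = 0.0004

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")
        if self.temperature <= -273.15:
            raise ValueError("temperature below absolute zero")
        if not (0.0 <= self.relative_humidity <= 1.0):
            raise ValueError("relative humidity must be in [0, 1]")


def chamber_preset(name: str) -> FACGeometry:
    """Named chamber preset (``lamperti``, ``ritz``, ``wyckoff_attix``)."""
    cfg = _constants()["chambers"]
    key = name.lower()
    if key not in cfg:
        raise ValueError(f"unknown chamber {name!r}; "
                         f"have {sorted(cfg)}")
    c = cfg[key]
    return FACGeometry(
        name=key,
        diaphragm_diameter=c["diaphragm_diameter_cm"],
        collector_length=c["collector_length_cm"],
        collector_width=c["collector_width_cm"],
        electrode_separation=c["electrode_separation_cm"],
        attenuation_length=c["attenuation_length_cm"],
    )


# -- ion recombination -----------------------------------------------------

def k_ion_parametric(kerma_rate: float, chamber: str = "lamperti",
                     adopted: bool = False) -> float:
    """Ion-recombination correction from the NIST rate parameterizations.

    ``k_ion = 0.9996 + 0.004573·√K̇`` (Lamperti) or
    ``k_ion = 1 + 0.087136·K̇`` (Ritz), with K̇ in Gy/s.  For the low
    rates of the electronic brachytherapy sources the adopted policy is
    ``k_ion = 1``; pass ``adopted=True`` to apply it.
    """
    if kerma_rate < 0:
        raise ValueError("kerma rate must be non-negative")
    if adopted:
        return 1.0
    key = chamber.lower()
    if key == "lamperti":
        return 0.9996 + 0.004573 * math.sqrt(kerma_rate)
    if key == "ritz":
        return 1.0 + 0.087136 * kerma_rate
    raise ValueError(f"unknown chamber {chamber!r}")


def k_ion_two_voltage(i_full: float, i_half: float,
                      voltage_ratio: float = 2.0) -> float:
    """Two-voltage (Boag) recombination estimate for continuous beams.

    ``k_ion = (n² − 1) / (n² − i₁/i₂)`` with ``n = V₁/V₂`` (default 2)
    and currents ``i₁`` at full voltage, ``i₂`` at the reduced voltage.
    """
    if i_full <= 0 or i_half <= 0:
        raise ValueError("currents must be positive")
    n2 = voltage_ratio ** 2
    r = i_full / i_half
    if r >= n2:
        raise ValueError("current ratio incompatible with near-saturation "
                         "two-voltage model")
    return (n2 - 1.0) / (n2 - r)


# -- humidity --------------------------------------------------------------

# CIPM-2007 formulation constants (SI units; t in °C, T in K, p in Pa)
_R = 8.314472            # J mol^-1 K^-1
_M_V = 18.01528e-3       # kg/mol, water vapor
_SVP = (1.2378847e-5, -1.9121316e-2, 33.93711047, -6.3431645e3)
_ENH = (1.00062, 3.14e-8, 5.6e-7)
_Z_A = (1.58123e-6, -2.9331e-8, 1.1043e-10)
_Z_B = (5.707e-6, -2.051e-8)
_Z_C = (1.9898e-4, -2.376e-6)
_Z_D = 1.83e-11
_Z_E = -0.765e-8


def _molar_mass_dry_air(x_co2: float) -> float:
    return (28.96546 + 12.011 * (x_co2 - 0.0004)) * 1e-3


def water_vapor_mole_fraction(env: EnvironmentalConditions) -> float:
    """Mole fraction of water vapor from RH via the CIPM formulation."""
    t = env.temperature
    T = t + 273.15
    p = env.pressure * 1000.0
    A, B, C, D = _SVP
    p_sv = math.exp(A * T * T + B * T + C + D / T)
    alpha, beta, gamma = _ENH
    f = alpha + beta * p + gamma * t * t
    return f * env.relative_humidity * p_sv / p


def humid_air_density(env: EnvironmentalConditions) -> float:
    """Humid-air density (kg/m³) by the CIPM moist-air equation.

    Includes the CO₂ content, the enhancement factor, and the
    compressibility of the air–water-vapor mixture.  Conditions far
    outside the formulation's stated envelope (15–27 °C, 60–110 kPa)
    trigger a warning but are still evaluated.
    """
    t = env.temperature
    T = t + 273.15
    p = env.pressure * 1000.0
    if not (15.0 <= t <= 27.0) or not (60.0 <= env.pressure <= 110.0):
        warnings.warn("conditions outside the CIPM formulation envelope "
                      "(15–27 °C, 60–110 kPa)", stacklevel=2)
    x_v = water_vapor_mole_fraction(env)
    M_a = _molar_mass_dry_air(env.co2_fraction)
    a0, a1, a2 = _Z_A
    b0, b1 = _Z_B
    c0, c1 = _Z_C
    Z = (1.0
         - (p / T) * (a0 + a1 * t + a2 * t * t
                      + (b0 + b1 * t) * x_v
                      + (c0 + c1 * t) * x_v * x_v)
         + (p / T) ** 2 * (_Z_D + _Z_E * x_v * x_v))
    return p * M_a / (Z * _R * T) * (1.0 - x_v * (1.0 - _M_V / M_a))


@dataclass(frozen=True)
class WRatioModel:
    """W_humid/W_dry versus water-vapor partial pressure (kPa).

    Piecewise-smooth parameterization of the Niatel-type curve: a fast
    initial drop to the mid-humidity plateau (W ratio ≈ 0.9945 around
    1 kPa of vapor) followed by a gentle linear decline, so that the
    humidity correction is nearly flat across ordinary laboratory
    humidities.  ``ratio(0) = 1`` exactly.
    """

    depth: float = 0.00199
    knee_kpa: float = 0.15
    slope_per_kpa: float = 0.0037
    max_pv_kpa: float = 3.5

    def ratio(self, p_v_kpa: float) -> float:
        if p_v_kpa < 0 or p_v_kpa > self.max_pv_kpa:
            raise ValueError(
                f"vapor partial pressure {p_v_kpa:.3f} kPa outside the "
                f"model domain [0, {self.max_pv_kpa}] kPa")
        return (1.0
                - self.depth * (1.0 - math.exp(-p_v_kpa / self.knee_kpa))
                - self.slope_per_kpa * p_v_kpa)


DEFAULT_W_RATIO = WRatioModel()


def k_humidity(spec: Spectrum,
               env: EnvironmentalConditions,
               dry_air: CoefficientTable,
               water_vapor: CoefficientTable,
               w_ratio_model: WRatioModel = DEFAULT_W_RATIO) -> float:
    """Humidity correction factor.

    Product of three ratios evaluated for the given spectrum and air
    state: dry/humid air density (CIPM equation), dry/humid W value
    (Niatel-type curve vs vapor partial pressure), and the dry/humid
    kerma-integral ratio with humid-air coefficients from the
    mass-fraction mixing rule.  Exactly 1 at zero relative humidity.
    """
    if env.relative_humidity == 0.0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho_humid = humid_air_density(env)
        dry_env = EnvironmentalConditions(env.temperature, env.pressure,
                                          0.0, env.co2_fraction)
        rho_dry = humid_air_density(dry_env)

    x_v = water_vapor_mole_fraction(env)
    p_v = x_v * env.pressure
    w_ratio = w_ratio_model.ratio(p_v)

    M_a = _molar_mass_dry_air(env.co2_fraction)
    w_mass = x_v * _M_V / ((1.0 - x_v) * M_a + x_v * _M_V)
    humid = mix_coefficients([(dry_air, 1.0 - w_mass),
                              (water_vapor, w_mass)])

    e, s = _spectrum_support(spec, dry_air)
    num = np.sum(s * e * dry_air.mu_tr_rho_at(e))
    den = np.sum(s * e * humid.mu_tr_rho_at(e))
    return (rho_dry / rho_humid) * w_ratio * (num / den)


# -- air attenuation -------------------------------------------------------

def _spectrum_support(spec: Spectrum, table: CoefficientTable):
    """Bin centers and fluence restricted to nonzero fluence within the
    coefficient-table range."""
    e = spec.grid.centers
    s = spec.fluence
    mask = (s > 0) & (e >= table.energies[0]) & (e <= table.energies[-1])
    if not np.any(mask):
        raise ValueError("spectrum has no support inside the table range")
    return e[mask], s[mask]


def k_att(spec: Spectrum, geom: FACGeometry, air_table: CoefficientTable,
          rho_air: float) -> float:
    """In-chamber air-attenuation correction.

    Ratio of the unattenuated kerma integral to the kerma integral with
    the beam attenuated from the aperture plane over the collecting
    volume (transmission averaged along the collector length).
    ``rho_air`` in g/cm³.  Midpoint rule on the spectrum grid; invariant
    to spectrum rescaling; > 1 for any attenuating medium.
    """
    if rho_air <= 0:
        raise ValueError("air density must be positive")
    e, s = _spectrum_support(spec, air_table)
    mu = air_table.mu_rho_at(e) * rho_air           # cm^-1
    mutr = air_table.mu_tr_rho_at(e)
    x = mu * geom.collector_length
    transmission = np.exp(-mu * geom.d_offset) * (-np.expm1(-x)) / x
    num = np.sum(s * e * mutr)
    den = np.sum(s * transmission * e * mutr)
    return float(num / den)


def mu_rho_eff(k_att_value: float, geom: FACGeometry,
               rho_air: float) -> float:
    """Effective mass attenuation coefficient from the attenuation
    correction: ``ln(k_att)`` divided by the attenuation length expressed
    as a mass thickness ``ρ_air·L``, cm²/g."""
    if k_att_value <= 1.0:
        raise ValueError("k_att must exceed 1")
    if rho_air <= 0:
        raise ValueError("air density must be positive")
    return math.log(k_att_value) / (geom.attenuation_length * rho_air)


def interpolate_mu_eff_vs_L(results: Sequence[tuple[float, float]],
                            l_query: float) -> float:
    """Interpolate effective attenuation coefficient versus attenuation
    length across chambers (beam-hardening trend).

    Quadratic through three points, linear through two; extrapolation
    outside the supplied lengths raises ``ValueError``.
    """
    if len(results) < 2:
        raise ValueError("need at least two (L, mu_eff) points")
    pts = sorted(results)
    ls = np.array([p[0] for p in pts], dtype=float)
    vals = np.array([p[1] for p in pts], dtype=float)
    if not (ls[0] <= l_query <= ls[-1]):
        raise ValueError(f"L = {l_query} cm outside the supplied range "
                         f"[{ls[0]}, {ls[-1]}] cm")
    deg = 2 if len(pts) >= 3 else 1
    coeffs = np.polyfit(ls, vals, deg)
    return float(np.polyval(coeffs, l_query))


# -- Monte Carlo basis-function corrections (k_el, k_sc, k_fl, k_br) -------

_BASIS_FACTORS = ("k_el", "k_sc", "k_fl", "k_br")


@dataclass
class BasisFunctionSet:
    """Numerator/denominator basis functions of photon energy for one
    in-chamber transport correction of one chamber.

    The factors are defined as ratios of spectrum-weighted integrals of
    functions derived from Monte Carlo photon-transport runs; the
    packaged sets are schematic fixtures calibrated to the adopted
    values, and genuine Monte Carlo tables with the same CSV layout can
    be dropped in.
    """

    factor: str
    chamber: str
    energies: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.numerator = np.asarray(self.numerator, dtype=float)
        self.denominator = np.asarray(self.denominator, dtype=float)
        if not np.all(np.diff(self.energies) > 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.denominator <= 0):
            raise ValueError("denominator must be strictly positive")


def load_basis_functions(chamber: str,
                         factor: str) -> BasisFunctionSet:
    """Load the packaged basis-function fixture for one chamber/factor."""
    if factor not in _BASIS_FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    path = resources.files("kermalab") / "data" / "basis" / \
        f"{chamber.lower()}_{factor}.csv"
    try:
        df = pd.read_csv(path.open("r"))
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"no basis functions for {chamber}/{factor}") from exc
    return BasisFunctionSet(
        factor=factor, chamber=chamber.lower(),
        energies=df["energy_keV"].to_numpy(),
        numerator=df["numerator"].to_numpy(),
        denominator=df["denominator"].to_numpy(),
    )


def transport_correction(spec: Spectrum, basis: BasisFunctionSet) -> float:
    """Spectrum-weighted ratio of basis-function integrals.

    ``∫S(E)·num(E) dE / ∫S(E)·den(E) dE`` with linear interpolation of
    the basis functions onto the spectrum grid.  Invariant to common
    rescaling of numerator and denominator and to spectrum rescaling.
    """
    e = spec.grid.centers
    s = spec.fluence
    mask = s > 0
    e, s = e[mask], s[mask]
    if e.size == 0:
        raise ValueError("empty spectrum")
    if e.min() < basis.energies[0] or e.max() > basis.energies[-1]:
        raise ValueError(
            "basis-function support narrower than the spectrum: "
            f"spectrum [{e.min():.2f}, {e.max():.2f}] keV vs basis "
            f"[{basis.energies[0]:.2f}, {basis.energies[-1]:.2f}] keV")
    num = np.interp(e, basis.energies, basis.numerator)
    den = np.interp(e, basis.energies, basis.denominator)
    return float(np.sum(s * num) / np.sum(s * den))


# -- adopted constants -----------------------------------------------------

_FACTOR_ORDER = ("k_ion", "k_humidity", "k_att", "k_el", "k_sc", "k_fl",
                 "k_br_over_1mg", "k_ii", "k_dia")


@dataclass
class CorrectionSet:
    """The nine FAC correction factors with relative standard
    uncertainties (%).  ``k_br_over_1mg`` is k_br/(1−ḡ) with the mean
    radiative loss fraction ḡ taken identically zero."""

    values: dict[str, float]
    uncertainties_pct: dict[str, float]
    chamber: str = ""
    alternatives: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in _FACTOR_ORDER if f not in self.values]
        if missing:
            raise ValueError(f"missing correction factors: {missing}")
        for name, v in self.values.items():
            if not (0.95 <= v <= 1.05):
                raise ValueError(f"{name} = {v} outside [0.95, 1.05]")
        for name, u in self.uncertainties_pct.items():
            if u < 0:
                raise ValueError(f"negative uncertainty for {name}")

    def product(self) -> float:
        """Product of the nine correction factors."""
        out = 1.0
        for f in _FACTOR_ORDER:
            out *= self.values[f]
        return out

    def replace(self, **updates: float) -> "CorrectionSet":
        vals = dict(self.values)
        for k, v in updates.items():
            if k not in vals:
                raise ValueError(f"unknown factor {k!r}")
            vals[k] = v
        return CorrectionSet(vals, dict(self.uncertainties_pct),
                             self.chamber, dict(self.alternatives))


_CONSTANTS_CACHE: dict | None = None


def _constants() -> dict:
    global _CONSTANTS_CACHE
    if _CONSTANTS_CACHE is None:
        path = resources.files("kermalab") / "data" / "constants.yaml"
        _CONSTANTS_CACHE = yaml.safe_load(path.read_text())
    return _CONSTANTS_CACHE


def adopted_corrections(chamber: str,
                        initial_ion_alternative: bool = False) -> CorrectionSet:
    """Adopted correction-factor set for a NIST chamber.

    Returns the adopted constants with their relative standard
    uncertainties.  ``initial_ion_alternative=True`` substitutes the
    computed initial-ion value (0.9980) that is stored alongside the
    adopted unity value.
    """
    cfg = _constants()["adopted_corrections"]
    key = chamber.lower()
    if key not in cfg:
        raise ValueError(f"unknown chamber {chamber!r}")
    entries = cfg[key]
    values = {f: entries[f]["value"] for f in _FACTOR_ORDER}
    unc = {f: entries[f]["u_pct"] for f in _FACTOR_ORDER}
    alts = {f: entries[f]["alternative"] for f in _FACTOR_ORDER
            if "alternative" in entries[f]}
    cs = CorrectionSet(values, unc, chamber=key, alternatives=alts)
    if initial_ion_alternative:
        cs = cs.replace(k_ii=alts["k_ii"])
    return cs
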