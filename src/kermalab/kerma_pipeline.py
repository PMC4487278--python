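"""Air-kerma realization, air-kerma strength, and uncertainty budgets.

The measurement equation of a free-air chamber converts the net
ionization current into an air-kerma rate:

    K̇_air = (W/e) · I_net / (ρ_air · V_eff · (1 − ḡ)) · Π k_i ,

with W/e the mean energy expended per ion pair divided by the
elementary charge (33.97 J/C for dry air), ρ_air the dry-air density
from the ideal-gas relation, V_eff the aperture-area × collector-length
volume, ḡ the radiative-loss fraction (taken identically zero at these
energies), and k_i the nine chamber correction factors.  Results are
stated for reference conditions of 22 °C and 101.325 kPa; the
reference-condition factor (101.325 kPa/P)·((273.15 + T)/295.15 K)
equals ρ_ref/ρ(T, P), so the reported reference rate is independent of
the ambient temperature and pressure for a fixed charge per unit mass.

Air-kerma strength S_K is the in-vacuo air-kerma rate at distance d
times d²; the in-vacuo/in-air ratio over the 50 cm measurement path is
evaluated from the photon spectrum by removing the exponential air
attenuation inside the kerma integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fac_corrections import (CorrectionSet, EnvironmentalConditions,
                              FACGeometry, _constants, _spectrum_support)
from .physics_tables import CoefficientTable
from .spectrometry import Spectrum

__all__ = [
    "PhysicsConstants",
    "MeasurementRecord",
    "KermaResult",
    "UncertaintyBudget",
    "air_density_ideal",
    "reference_condition_factor",
    "realize_air_kerma",
    "kerma_from_spectrum",
    "vacuum_ratio",
    "air_kerma_strength",
    "combine_uncertainty",
    "table_budget",
    "well_chamber_coefficient",
]


@dataclass(frozen=True)
class PhysicsConstants:
    """Fixed constants of the realization (versioned via the packaged
    registry)."""

    W_over_e: float = 33.97          # J/C
    rho_0: float = 1.2929            # kg/m^3 at 0 degC, 101.325 kPa
    delta_cutoff: float = 5.0        # keV, kerma-integral low-energy cut
    reference_temperature: float = 22.0   # degC
    reference_pressure: float = 101.325   # kPa

    @classmethod
    def from_registry(cls) -> "PhysicsConstants":
        p = _constants()["physics"]
        return cls(W_over_e=p["W_over_e_J_per_C"],
                   rho_0=p["rho0_kg_m3"],
                   delta_cutoff=p["low_energy_cutoff_keV"],
                   reference_temperature=p["reference_temperature_C"],
                   reference_pressure=p["reference_pressure_kPa"])


DEFAULT_CONSTANTS = PhysicsConstants()


@dataclass
class MeasurementRecord:
    """One free-air-chamber current measurement."""

    i_net: float                     # A, net current of one sign
    env: EnvironmentalConditions
    chamber: FACGeometry
    distance: float = 50.0           # cm, source-to-aperture
    polarity: int = +1

    def __post_init__(self) -> None:
        if self.i_net <= 0:
            raise ValueError("net current must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.polarity not in (-1, +1):
            raise ValueError("polarity must be ±1")


@dataclass
class KermaResult:
    """Realized air-kerma rates and derived quantities."""

    kerma_rate: float                # Gy/s at measurement conditions
    kerma_rate_ref: float            # Gy/s at 22 degC, 101.325 kPa
    air_kerma_strength_si: float | None = None   # Gy·m^2/s
    air_kerma_strength_u: float | None = None    # U = µGy·m^2/h
    u_type_a_pct: float | None = None
    u_type_b_pct: float | None = None
    u_combined_pct: float | None = None


@dataclass
class UncertaintyBudget:
    """Named Type A / Type B relative standard uncertainty components (%)."""

    components: list[tuple[str, str, float]]  # (name, "A"|"B", u_pct)

    def __post_init__(self) -> None:
        for name, typ, u in self.components:
            if typ not in ("A", "B"):
                raise ValueError(f"component {name!r}: type must be A or B")
            if u < 0:
                raise ValueError(f"component {name!r}: negative uncertainty")

    def of_type(self, typ: str) -> list[float]:
        return [u for _, t, u in self.components if t == typ]


def air_density_ideal(env: EnvironmentalConditions,
                      constants: PhysicsConstants = DEFAULT_CONSTANTS,
                      ) -> float:
    """Ideal-gas dry-air density (kg/m³) from temperature and pressure."""
    return (constants.rho_0 * (env.pressure / 101.325)
            * 273.15 / (273.15 + env.temperature))


def reference_condition_factor(env: EnvironmentalConditions,
                               constants: PhysicsConstants =
                               DEFAULT_CONSTANTS) -> float:
    """Multiplier normalizing a measurement to 22 °C and 101.325 kPa;
    exactly 1 at reference conditions."""
    t_ref = constants.reference_temperature + 273.15
    return ((constants.reference_pressure / env.pressure)
            * (273.15 + env.temperature) / t_ref)


def realize_air_kerma(rec: MeasurementRecord,
                      corrections: CorrectionSet,
                      constants: PhysicsConstants = DEFAULT_CONSTANTS,
                      budget: UncertaintyBudget | None = None,
                      ) -> KermaResult:
    """Evaluate the measurement equation for one current measurement.

    Returns the kerma rate at the measurement conditions and the
    reference-condition rate (these coincide numerically: the ambient
    density in the measurement equation and the reference-condition
    factor cancel by construction).  If a budget is supplied, combined
    uncertainties are attached.
    """
    rho = air_density_ideal(rec.env, constants)          # kg/m^3
    v_eff_m3 = rec.chamber.v_eff * 1e-6                  # cm^3 -> m^3
    prod = corrections.product()
    rate = constants.W_over_e * rec.i_net / (rho * v_eff_m3) * prod
    rho_ref = air_density_ideal(
        EnvironmentalConditions(constants.reference_temperature,
                                constants.reference_pressure), constants)
    rate_ref = (constants.W_over_e * rec.i_net / (rho_ref * v_eff_m3)
                * prod * reference_condition_factor(rec.env, constants))
    result = KermaResult(kerma_rate=rate, kerma_rate_ref=rate_ref)
    if budget is not None:
        a, b, c = combine_uncertainty(budget)
        result.u_type_a_pct, result.u_type_b_pct, result.u_combined_pct = \
            a, b, c
    return result


def kerma_from_spectrum(spec: Spectrum, air_table: CoefficientTable,
                        delta: float = 5.0) -> float:
    """Relative air kerma from the fluence spectrum:
    ``Σ Φ(E)·E·(μ_tr/ρ)(E)`` above the low-energy cut-off ``delta``."""
    e, s = _spectrum_support(spec, air_table)
    mask = e >= delta
    e, s = e[mask], s[mask]
    return float(np.sum(s * e * air_table.mu_tr_rho_at(e)))


def vacuum_ratio(spec_in_air: Spectrum, air_table: CoefficientTable,
                 path: float = 50.0, rho_air: float = 1.19654e-3,
                 delta: float = 5.0) -> float:
    """In-vacuo to in-air kerma ratio over ``path`` cm of air.

    The in-vacuo spectrum is the measured one with the exponential air
    attenuation over the source-to-aperture path removed; the ratio of
    the two kerma integrals is returned.  ``rho_air`` in g/cm³.
    Always ≥ 1 and strictly increasing in the path length.
    """
    if path < 0:
        raise ValueError("path length must be non-negative")
    if path == 0:
        return 1.0
    e, s = _spectrum_support(spec_in_air, air_table)
    mask = e >= delta
    e, s = e[mask], s[mask]
    mutr = air_table.mu_tr_rho_at(e)
    mu = air_table.mu_rho_at(e) * rho_air
    num = np.sum(s * np.exp(mu * path) * e * mutr)
    den = np.sum(s * e * mutr)
    return float(num / den)


def air_kerma_strength(kerma_rate_vac: float,
                       distance: float) -> tuple[float, float]:
    """Air-kerma strength from the in-vacuo rate at ``distance`` (cm).

    Returns ``(S_K in Gy·m²/s, S_K in U)`` with 1 U = 1 µGy·m²/h.
    """
    if kerma_rate_vac <= 0 or distance <= 0:
        raise ValueError("rate and distance must be positive")
    d_m = distance / 100.0
    sk_si = kerma_rate_vac * d_m * d_m
    sk_u = sk_si * 1e6 * 3600.0
    return sk_si, sk_u


def combine_uncertainty(budget: UncertaintyBudget,
                        ) -> tuple[float, float, float]:
    """Root-sum-square combination: (Type A %, Type B %, combined %)."""
    a = math.sqrt(sum(u * u for u in budget.of_type("A")))
    b = math.sqrt(sum(u * u for u in budget.of_type("B")))
    return a, b, math.hypot(a, b)


def table_budget(chamber: str,
                 s_q_pct: float = 0.0) -> UncertaintyBudget:
    """The adopted air-kerma uncertainty budget for a chamber.

    ``s_q_pct`` adds the measurement-specific net-charge repeatability
    (standard deviation of the mean) as a Type A component.
    """
    cfg = _constants()["uncertainty_budget"]
    key = chamber.lower()
    if key not in cfg["type_B"]:
        raise ValueError(f"unknown chamber {chamber!r}")
    comps: list[tuple[str, str, float]] = []
    if s_q_pct > 0:
        comps.append(("Q_net repeatability", "A", s_q_pct))
    comps += [(c["name"], "A", c["u_pct"]) for c in cfg["type_A"]]
    comps += [(c["name"], "B", c["u_pct"]) for c in cfg["type_B"][key]]
    return UncertaintyBudget(comps)


def well_chamber_coefficient(kerma_rate_ref: float, well_current: float,
                             ) -> tuple[float, float, float]:
    """Well-chamber calibration coefficient and its uncertainty.

    The transfer-standard coefficient is the reference air-kerma rate
    divided by the well-chamber current, Gy/(A·s).  Returns
    ``(coefficient, expanded k=2 uncertainty %, standard uncertainty %)``
    with the air-kerma-rate component dominating the combination.
    """
    if kerma_rate_ref <= 0 or well_current <= 0:
        raise ValueError("rate and current must be positive")
    wc = _constants()["well_chamber"]
    u_exp = math.hypot(wc["u_kerma_rate_expanded_pct"],
                       wc["u_transfer_expanded_pct"])
    return kerma_rate_ref / well_current, u_exp, u_exp / 2.0
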