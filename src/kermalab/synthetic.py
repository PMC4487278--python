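"""Synthetic 50 kV source spectra, pulse-height forward model, and
simulated chamber measurements.

No miniature-x-ray-tube spectrum is published numerically, so every
pipeline stage is exercised against synthetic data with the statistical
structure of the measured ensemble: a filtered bremsstrahlung continuum
with a 50 keV endpoint and an effective low-energy cut-off near 7 keV,
prominent yttrium K x-ray lines near 15 and 17 keV with weaker tungsten
L lines near 8–11 keV, a fluence-weighted mean energy of ≈25.3 keV with
a source-to-source spread of ≈1.1 keV, ~0.5 keV FWHM detector
resolution, and dead times up to ~35 %.

The continuum is a Kramers spectrum times an air-equivalent filtration
transmission; the filtration thickness and the characteristic-line
fluence share are fixed once against the two printed summary statistics
of the measured ensemble (mean energy and kerma-effective attenuation
coefficient), and per-source variability enters as lognormal jitter on
the filtration and line intensities (see docs/methods.md).  All
generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .fac_corrections import CorrectionSet, EnvironmentalConditions, \
    FACGeometry
from .grids import DEFAULT_GRID, EnergyGrid
from .kerma_pipeline import DEFAULT_CONSTANTS, PhysicsConstants, \
    air_density_ideal
from .physics_tables import CoefficientTable, load_coefficient_table
from .spectrometry import (PulseHeightDistribution, ResponseMatrix,
                           Spectrum, forward_convolve)

__all__ = [
    "SourceModel",
    "AcquisitionModel",
    "generate_spectrum",
    "default_spectrum",
    "forward_pulse_height",
    "simulate_measurement",
]

# Characteristic lines (keV, relative intensity): yttrium K series from
# the anode target material, tungsten L series from the tube structure.
DEFAULT_LINES: tuple[tuple[float, float], ...] = (
    (14.958, 1.00),   # Y Kalpha
    (16.738, 0.20),   # Y Kbeta
    (8.398, 0.10),    # W Lalpha
    (9.672, 0.18),    # W Lbeta
    (11.286, 0.12),   # W Lgamma
)

# Continuum filtration (g/cm^2 air-equivalent) and total line fluence as
# a fraction of the continuum fluence; fixed once against the measured
# ensemble's printed mean energy (25.3 keV) and kerma-effective
# attenuation coefficient (~1.85 cm^2/g).
DEFAULT_FILTRATION = 1.44205
DEFAULT_LINE_FRACTION = 0.153264

# Lognormal jitter scales reproducing the ~1.1 keV source-to-source
# spread of mean energies and the per-source spread of the attenuation
# correction.
DEFAULT_FILTRATION_JITTER = 0.33
DEFAULT_LINE_JITTER = 0.30


@dataclass(frozen=True)
class SourceModel:
    """Parametric model of a miniature 50 kV x-ray source spectrum."""

    tube_potential: float = 50.0          # kV
    filtration: float = DEFAULT_FILTRATION        # g/cm^2 air-equivalent
    line_fraction: float = DEFAULT_LINE_FRACTION  # line / continuum fluence
    lines: tuple[tuple[float, float], ...] = DEFAULT_LINES
    e_cutoff: float = 7.0                 # keV
    line_fwhm: float = 0.5                # keV (intrinsic resolution)
    filtration_jitter: float = DEFAULT_FILTRATION_JITTER
    line_jitter: float = DEFAULT_LINE_JITTER

    def __post_init__(self) -> None:
        if any(e >= self.tube_potential for e, _ in self.lines):
            raise ValueError("characteristic lines must lie below the "
                             "tube potential")
        if not (0 < self.e_cutoff < self.tube_potential):
            raise ValueError("cut-off must lie below the endpoint")


@dataclass(frozen=True)
class AcquisitionModel:
    """Spectrometer acquisition model for the forward simulation."""

    resolution_fwhm: float = 0.5     # keV
    dead_time_fraction: float = 0.02
    pileup_slope: float = 1.0        # dimensionless pile-up amplitude
    total_counts: float | None = 2e6
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.resolution_fwhm < 0:
            raise ValueError("FWHM must be non-negative")
        if not (0.0 <= self.dead_time_fraction < 1.0):
            raise ValueError("dead-time fraction must be in [0, 1)")


def generate_spectrum(model: SourceModel = SourceModel(),
                      seed: int | None = None,
                      grid: EnergyGrid = DEFAULT_GRID,
                      air_table: CoefficientTable | None = None,
                      ) -> Spectrum:
    """Generate a synthetic source spectrum on ``grid``.

    With ``seed=None`` the deterministic default-parameter spectrum is
    returned; an integer seed draws one jittered source realization
    (bit-identical on rerun with the same seed).
    """
    if air_table is None:
        air_table = load_coefficient_table("dry_air", "renormalized")
    rng = np.random.default_rng(seed) if seed is not None else None

    filtration = model.filtration
    line_scale = np.ones(len(model.lines))
    if rng is not None:
        filtration *= np.exp(model.filtration_jitter * rng.standard_normal())
        line_scale = np.exp(model.line_jitter
                            * rng.standard_normal(len(model.lines)))

    e = grid.centers
    e0 = model.tube_potential
    inside = (e >= model.e_cutoff) & (e <= e0)
    cont = np.zeros_like(e)
    ein = e[inside]
    mu = air_table.mu_rho_at(np.clip(ein, air_table.energies[0],
                                     air_table.energies[-1]))
    cont[inside] = (e0 - ein) / ein * np.exp(-mu * filtration)
    cont_total = cont.sum()

    rel = np.array([r for _, r in model.lines]) * line_scale
    intensities = model.line_fraction * cont_total * rel / rel.sum()
    sigma = model.line_fwhm / 2.354820045
    fluence = cont.copy()
    for (e_line, _), inten in zip(model.lines, intensities):
        prof = np.exp(-0.5 * ((e - e_line) / sigma) ** 2)
        prof[~inside] = 0.0
        s = prof.sum()
        if s > 0:
            fluence += inten * prof / s

    total = fluence.sum()
    if total > 0:
        fluence /= total
    return Spectrum(grid, fluence, e_cutoff=model.e_cutoff, e_endpoint=e0,
                    meta={"seed": seed, "filtration_g_cm2": filtration})


def default_spectrum(grid: EnergyGrid = DEFAULT_GRID,
                     air_table: CoefficientTable | None = None) -> Spectrum:
    """The deterministic default-parameter spectrum (no jitter)."""
    return generate_spectrum(SourceModel(), seed=None, grid=grid,
                             air_table=air_table)


def forward_pulse_height(spec: Spectrum, response: ResponseMatrix,
                         acq: AcquisitionModel = AcquisitionModel(),
                         seed: int | None = None,
                         ) -> PulseHeightDistribution:
    """Forward-model a spectrum into a pulse-height distribution.

    Response convolution, then Gaussian resolution smearing, then a
    linear pile-up background scaled by the dead-time fraction (it
    extends above the 50 keV endpoint, as real pile-up does), then
    optional Poisson counting noise.
    """
    if not spec.grid.compatible(response.grid):
        raise ValueError("spectrum and response grids differ")
    grid = spec.grid
    counts = forward_convolve(spec, response)

    if acq.resolution_fwhm > 0:
        sigma_bins = acq.resolution_fwhm / 2.354820045 / grid.bin_width
        counts = gaussian_filter1d(counts, sigma_bins, mode="constant")

    if acq.pileup_slope > 0 and acq.dead_time_fraction > 0:
        e = grid.centers
        e_top = min(grid.e_max, spec.e_endpoint + 7.0)
        ramp = np.clip(1.0 - e / e_top, 0.0, None)
        amp = (acq.pileup_slope * acq.dead_time_fraction
               * counts.sum() / grid.n_bins)
        counts = counts + amp * ramp

    if acq.total_counts is not None and counts.sum() > 0:
        counts = counts * (acq.total_counts / counts.sum())

    if acq.poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(counts).astype(float)

    return PulseHeightDistribution(
        grid, counts, dead_time_fraction=acq.dead_time_fraction,
        source_id=str(spec.meta.get("seed", "")),
        meta={"truth_seed": spec.meta.get("seed")})


def simulate_measurement(truth_kerma_rate: float,
                         chamber: FACGeometry,
                         env: EnvironmentalConditions,
                         corrections: CorrectionSet,
                         noise_rel: float = 0.0,
                         seed: int | None = None,
                         constants: PhysicsConstants = DEFAULT_CONSTANTS,
                         ):
    """Invert the measurement equation to fabricate a current
    measurement for a known kerma rate (Gy/s).

    With zero noise the realization recovers the truth exactly; with
    noise the current carries multiplicative Gaussian error of relative
    scale ``noise_rel``.
    """
    from .kerma_pipeline import MeasurementRecord  # local to avoid cycle

    if truth_kerma_rate <= 0:
        raise ValueError("truth kerma rate must be positive")
    rho = air_density_ideal(env, constants)
    v_eff_m3 = chamber.v_eff * 1e-6
    i_net = (truth_kerma_rate * rho * v_eff_m3
             / (constants.W_over_e * corrections.product()))
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        i_net *= 1.0 + noise_rel * rng.standard_normal()
    return MeasurementRecord(i_net=i_net, env=env, chamber=chamber)
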