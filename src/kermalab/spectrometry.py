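"""HPGe pulse-height spectrometry: response model and backward stripping.

A pulse-height distribution measured with an HPGe detector is the true
incident photon spectrum convolved with the detector response: each
incident photon either deposits its full energy (the photopeak), loses a
germanium K x-ray (escape peaks 9.886 / 10.982 keV below the incident
energy), deposits only the Compton-electron energy when the scattered
photon escapes (a low-energy continuum), or leaves no signal at all.

Because the intrinsic resolution is so narrow (~0.5 keV FWHM) relative
to the ~0.08 keV bins, full matrix inversion of the smeared response is
impractical; instead the classical *backward stripping* is used: from
the highest bin downward, the photopeak is normalized to the remaining
counts in that bin and the bin's whole energy-deposition spectrum is
subtracted from the lower bins.  On noise-free input this is the exact
algebraic inverse of forward convolution (triangular back-substitution).
The intrinsic resolution is deliberately not deconvolved; stripped
spectra remain convolved with it, which does not measurably perturb the
spectrum integrals used downstream.

Pulse pile-up at high dead time adds a slowly varying background that
extends above the 50 keV endpoint; it is removed by subtracting a
straight line anchored at the stripped spectrum's values at (about)
7 keV and 50 keV.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grids import EnergyGrid
from .physics_tables import CoefficientTable

logger = logging.getLogger(__name__)

__all__ = [
    "PulseHeightDistribution",
    "ResponseMatrix",
    "Spectrum",
    "DetectorModel",
    "build_response_matrix",
    "strip",
    "subtract_pileup_background",
    "mean_energy",
    "read_spectrum",
    "write_spectrum",
    "read_phd",
    "write_phd",
]

# Germanium atomic data for the K-escape model
GE_K_EDGE = 11.103      # keV
GE_KALPHA = 9.886       # keV
GE_KBETA = 10.982       # keV
GE_DENSITY = 5.323      # g/cm^3
GE_K_FLUOR_YIELD = 0.535
GE_KALPHA_FRACTION = 0.885
GE_K_SHELL_FRACTION = 0.87   # K-shell share of photoabsorption above edge

# Approximate partition of the germanium cross section into photoelectric,
# incoherent and coherent parts (cm^2/g), used to weight the response
# channels.  Doubled point at the K edge.
_GE_PART_E = np.array([5.0, 6.0, 8.0, 10.0, 11.102, 11.104,
                       15.0, 20.0, 30.0, 40.0, 50.0, 60.0])
_GE_INCOH = np.array([0.095, 0.105, 0.118, 0.127, 0.130, 0.130,
                      0.140, 0.147, 0.153, 0.155, 0.155, 0.154])
_GE_COH = np.array([1.85, 1.55, 1.18, 0.95, 0.88, 0.88,
                    0.60, 0.43, 0.25, 0.17, 0.13, 0.105])

_ELECTRON_REST = 511.0  # keV


def _loglog(e, xs, ys):
    return np.exp(np.interp(np.log(e), np.log(xs), np.log(ys)))


# -- containers ------------------------------------------------------------


@dataclass
class Spectrum:
    """Binned relative photon fluence vs energy (unnormalized S(E)).

    ``fluence`` holds photons per bin in arbitrary relative units; it is
    zero below ``e_cutoff`` and above ``e_endpoint``.
    """

    grid: EnergyGrid
    fluence: np.ndarray
    e_cutoff: float = 0.0
    e_endpoint: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.fluence.shape != (self.grid.n_bins,):
            raise ValueError("fluence length must match the grid")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if self.e_endpoint is None:
            self.e_endpoint = self.grid.e_max
        e = self.grid.centers
        half = self.grid.bin_width / 2.0
        outside = (e < self.e_cutoff - half) | (e > self.e_endpoint + half)
        if np.any(self.fluence[outside] > 0):
            raise ValueError("fluence nonzero outside "
                             "[e_cutoff, e_endpoint]")

    @property
    def total(self) -> float:
        return float(self.fluence.sum())


@dataclass
class PulseHeightDistribution:
    """Detector counts per pulse-height bin with acquisition metadata."""

    grid: EnergyGrid
    counts: np.ndarray
    dead_time_fraction: float = 0.0
    live_time: float | None = None
    source_id: str = ""
    tube_potential: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError("counts length must match the grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.dead_time_fraction < 1.0):
            raise ValueError("dead-time fraction must be in [0, 1)")


@dataclass
class ResponseMatrix:
    """Per-bin energy-deposition model for the HPGe crystal.

    ``photopeak_prob[i]`` is the probability that a photon incident in
    bin *i* deposits its full energy.  ``downscatter[i, j]`` (strictly
    lower triangular, a density per keV) is the probability density of
    depositing energy in bin *j* < *i* via K x-ray escape or Compton
    escape.  ``undetected[i]`` is the probability of no deposit at all
    (transmission and coherent redirection); per column,
    ``photopeak + Σ downscatter·Δ + undetected = 1``.
    """

    grid: EnergyGrid
    photopeak_prob: np.ndarray
    downscatter: np.ndarray
    undetected: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        if self.photopeak_prob.shape != (n,):
            raise ValueError("photopeak_prob length mismatch")
        if self.downscatter.shape != (n, n):
            raise ValueError("downscatter must be n×n")
        if np.any(self.downscatter < 0) or np.any(self.photopeak_prob < 0):
            raise ValueError("response entries must be non-negative")
        if np.any(np.triu(self.downscatter) != 0):
            raise ValueError("downscatter must be strictly lower triangular")

    @classmethod
    def identity(cls, grid: EnergyGrid) -> "ResponseMatrix":
        n = grid.n_bins
        return cls(grid, np.ones(n), np.zeros((n, n)), np.zeros(n))


@dataclass(frozen=True)
class DetectorModel:
    """Planar HPGe crystal seen through a centered pinhole at normal
    incidence."""

    crystal_diameter: float = 1.13   # cm
    crystal_thickness: float = 1.0   # cm
    n_depth: int = 80                # depth quadrature points
    n_angles: int = 720              # Compton angular quadrature points


# -- response construction -------------------------------------------------

def build_response_matrix(grid: EnergyGrid,
                          ge_table: CoefficientTable,
                          detector: DetectorModel = DetectorModel(),
                          ) -> ResponseMatrix:
    """Construct the lower-triangular energy-deposition model.

    For each incident bin-center energy: total-interaction probability
    along the crystal thickness; photoelectric events deposit the full
    energy except when a germanium K x-ray escapes (two escape lines,
    with escape probability integrated over the photoabsorption depth
    distribution along the crystal axis); incoherent events deposit the
    Compton-electron energy with the Klein-Nishina angular distribution,
    the scattered photon escaping along its straight path or being
    reabsorbed (then the full energy is deposited); coherent events and
    transmission leave no deposit.  Incident energies below the table
    range are treated as fully absorbed (photopeak probability 1).
    """
    if grid.bin_width > (GE_KBETA - GE_KALPHA):
        warnings.warn("grid coarser than the Ge Kα–Kβ separation; escape "
                      "peaks merge", stacklevel=2)
    n = grid.n_bins
    centers = grid.centers
    dE = grid.bin_width
    t = detector.crystal_thickness

    photopeak = np.ones(n)
    down = np.zeros((n, n))
    undet = np.zeros(n)

    e_lo, e_hi = ge_table.energies[0], ge_table.energies[-1]
    mu_ka = float(ge_table.mu_rho_at(GE_KALPHA)) * GE_DENSITY
    mu_kb = float(ge_table.mu_rho_at(GE_KBETA)) * GE_DENSITY

    # depth quadrature (midpoint)
    z = (np.arange(detector.n_depth) + 0.5) * (t / detector.n_depth)
    dz = t / detector.n_depth

    # Compton angular quadrature over cos(theta)
    c = np.linspace(1.0, -1.0, detector.n_angles + 1)
    c = 0.5 * (c[:-1] + c[1:])
    dc = 2.0 / detector.n_angles

    for i, E in enumerate(centers):
        if E < e_lo:
            continue  # fully absorbed: photopeak 1, nothing else
        if E > e_hi:
            raise ValueError("grid extends above the germanium table")
        mu = float(ge_table.mu_rho_at(E)) * GE_DENSITY
        p_int = -np.expm1(-mu * t)
        undet[i] = 1.0 - p_int

        part_e = np.clip(E, _GE_PART_E[0], _GE_PART_E[-1])
        incoh = _loglog(part_e, _GE_PART_E, _GE_INCOH)
        coh = _loglog(part_e, _GE_PART_E, _GE_COH)
        total = float(ge_table.mu_rho_at(E))
        f_incoh = min(incoh / total, 1.0)
        f_coh = min(coh / total, 1.0)
        f_pe = max(1.0 - f_incoh - f_coh, 0.0)

        undet[i] += p_int * f_coh  # coherent: no energy deposit
        p_pe = p_int * f_pe
        p_inc = p_int * f_incoh
        peak = p_pe

        # photoabsorption depth distribution (normalized over [0, t])
        w_z = mu * np.exp(-mu * z) * dz / p_int

        if E > GE_K_EDGE:
            # K x-ray escape through either plane face (axial paths)
            for e_line, branch, mu_line in (
                    (GE_KALPHA, GE_KALPHA_FRACTION, mu_ka),
                    (GE_KBETA, 1.0 - GE_KALPHA_FRACTION, mu_kb)):
                esc = np.sum(w_z * 0.5 * (np.exp(-mu_line * z)
                                          + np.exp(-mu_line * (t - z))))
                p_esc = (p_pe * GE_K_SHELL_FRACTION * GE_K_FLUOR_YIELD
                         * branch * esc)
                e_dep = E - e_line
                j = grid.index_of(e_dep)
                if j < i and p_esc > 0:
                    down[i, j] += p_esc / dE
                    peak -= p_esc

        if p_inc > 0:
            k = E / _ELECTRON_REST
            e_sc = E / (1.0 + k * (1.0 - c))       # scattered photon, keV
            T = E - e_sc                            # electron deposit
            r = e_sc / E
            kn = r * r * (r + 1.0 / r - (1.0 - c * c))
            w_ang = kn * dc
            w_ang /= w_ang.sum()

            mu_sc = np.where(e_sc >= e_lo,
                             _loglog(np.clip(e_sc, e_lo, e_hi),
                                     ge_table.energies,
                                     ge_table.mu_rho) * GE_DENSITY,
                             np.inf)
            # escape probability of the scattered photon along its path,
            # averaged over interaction depth
            path = np.where(c[None, :] > 1e-9,
                            (t - z[:, None]) / np.maximum(c[None, :], 1e-9),
                            np.where(c[None, :] < -1e-9,
                                     z[:, None] / np.maximum(-c[None, :],
                                                             1e-9),
                                     np.inf))
            esc_sc = np.sum(w_z[:, None] * np.exp(-mu_sc[None, :] * path),
                            axis=0)

            p_tail = p_inc * w_ang * esc_sc           # per angle node
            peak += p_inc - p_tail.sum()              # reabsorbed -> full E
            j_idx = np.clip(((T - grid.e_min) / dE).astype(int), 0, n - 1)
            j_idx = np.minimum(j_idx, i - 1)
            np.add.at(down[i], j_idx, p_tail / dE)

        photopeak[i] = peak

    return ResponseMatrix(grid, photopeak, down, undet)


def forward_convolve(spec: Spectrum, response: ResponseMatrix) -> np.ndarray:
    """Expected deposit counts per bin for a fluence spectrum (no
    resolution smearing, no noise)."""
    if not spec.grid.compatible(response.grid):
        raise ValueError("spectrum and response grids differ")
    f = spec.fluence
    counts = response.photopeak_prob * f
    counts = counts + (f[:, None] * response.downscatter
                       * response.grid.bin_width).sum(axis=0)
    return counts


# -- stripping -------------------------------------------------------------

def strip(phd: PulseHeightDistribution, response: ResponseMatrix,
          strip_start: float = 60.0) -> Spectrum:
    """Backward-strip a pulse-height distribution into the incident
    photon spectrum.

    From the highest nonzero bin at or below ``strip_start`` downward:
    the photopeak is normalized to the remaining counts in that bin and
    the bin's scaled energy-deposition spectrum is subtracted from all
    lower bins.  Negative remainders are clipped to zero; the total
    clipped mass is logged and reported in ``meta['clipped_counts']``.
    The result is still convolved with the intrinsic resolution.
    """
    if not phd.grid.compatible(response.grid):
        raise ValueError("pulse-height and response grids differ")
    grid = phd.grid
    dE = grid.bin_width
    rem = phd.counts.astype(float).copy()
    fluence = np.zeros_like(rem)
    clipped = 0.0

    nonzero = np.nonzero(rem)[0]
    if nonzero.size == 0:
        return Spectrum(grid, fluence, meta={"clipped_counts": 0.0})
    top = min(int(nonzero[-1]),
              grid.index_of(min(strip_start, grid.e_max)))

    for i in range(top, -1, -1):
        if rem[i] <= 0:
            continue
        pp = response.photopeak_prob[i]
        if pp <= 0:
            raise ValueError(
                f"zero photopeak probability at bin {i} "
                f"({grid.centers[i]:.2f} keV) with nonzero counts")
        fluence[i] = rem[i] / pp
        if i > 0:
            rem[:i] -= fluence[i] * response.downscatter[i, :i] * dE
            neg = rem[:i] < 0
            if np.any(neg):
                clipped += float(-rem[:i][neg].sum())
                rem[:i][neg] = 0.0
        rem[i] = 0.0

    if clipped > 0:
        logger.info("stripping clipped %.4g counts to zero", clipped)
    meta = {"clipped_counts": clipped, "source_id": phd.source_id,
            "dead_time_fraction": phd.dead_time_fraction}
    return Spectrum(grid, fluence, e_cutoff=grid.e_min,
                    e_endpoint=grid.centers[top], meta=meta)


def subtract_pileup_background(spec: Spectrum, e_low: float = 7.0,
                               e_high: float = 50.0) -> Spectrum:
    """Remove the straight-line pile-up background.

    Subtracts the line through the spectrum's values at ``e_low`` and
    ``e_high`` on that interval, clips negatives to zero, and zeroes the
    spectrum outside the interval, yielding a spectrum cleanly extending
    from about ``e_low`` up to ``e_high``.
    """
    grid = spec.grid
    if not (grid.e_min <= e_low < e_high <= grid.e_max):
        raise ValueError("anchors must satisfy e_min <= e_low < e_high "
                         "<= e_max")
    e = grid.centers
    i_lo, i_hi = grid.index_of(e_low), grid.index_of(e_high)
    s_lo, s_hi = spec.fluence[i_lo], spec.fluence[i_hi]
    scale = max(spec.fluence.max(), 1e-300)
    if s_hi > s_lo and s_hi > 0.01 * scale:
        warnings.warn("background rises toward the endpoint; pathological "
                      "pile-up shape", stacklevel=2)
    line = s_lo + (s_hi - s_lo) * (e - e[i_lo]) / (e[i_hi] - e[i_lo])
    out = spec.fluence.copy()
    sl = slice(i_lo, i_hi + 1)
    out[sl] = np.clip(out[sl] - line[sl], 0.0, None)
    out[:i_lo] = 0.0
    out[i_hi + 1:] = 0.0
    meta = dict(spec.meta)
    meta["pileup_anchors_keV"] = (e_low, e_high)
    return Spectrum(grid, out, e_cutoff=e_low, e_endpoint=e_high, meta=meta)


def mean_energy(spec: Spectrum) -> float:
    """Fluence-weighted mean energy, keV."""
    total = spec.fluence.sum()
    if total <= 0:
        raise ValueError("empty spectrum")
    return float(np.sum(spec.grid.centers * spec.fluence) / total)


# -- plain-text I/O --------------------------------------------------------

def _write_two_column(path, energies, values, header):
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for e, v in zip(energies, values):
            fh.write(f"{e:.5f},{v:.8g}\n")


def _read_two_column(path):
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1]


def _grid_from_energies(e: np.ndarray) -> EnergyGrid:
    d = np.diff(e)
    if not np.allclose(d, d[0], rtol=1e-6):
        raise ValueError("non-uniform energy column")
    w = float(d[0])
    return EnergyGrid(float(e[0]) - w / 2, float(e[-1]) + w / 2, w)


def write_spectrum(spec: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV plus a JSON metadata sidecar."""
    path = Path(path)
    _write_two_column(path, spec.grid.centers, spec.fluence,
                      "energy_keV,fluence")
    meta = {"e_cutoff_keV": spec.e_cutoff, "e_endpoint_keV": spec.e_endpoint,
            **{k: v for k, v in spec.meta.items()
               if isinstance(v, (int, float, str, list, tuple))}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    e, v = _read_two_column(path)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Spectrum(_grid_from_energies(e), v,
                    e_cutoff=meta.get("e_cutoff_keV", 0.0),
                    e_endpoint=meta.get("e_endpoint_keV"), meta=meta)


def write_phd(phd: PulseHeightDistribution, path) -> None:
    """Write a pulse-height distribution as CSV plus JSON sidecar."""
    path = Path(path)
    _write_two_column(path, phd.grid.centers, phd.counts,
                      "energy_keV,counts")
    meta = {"dead_time_fraction": phd.dead_time_fraction,
            "live_time_s": phd.live_time, "source_id": phd.source_id,
            "tube_potential_kV": phd.tube_potential}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_phd(path) -> PulseHeightDistribution:
    path = Path(path)
    e, v = _read_two_column(path)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return PulseHeightDistribution(
        _grid_from_energies(e), v,
        dead_time_fraction=meta.get("dead_time_fraction", 0.0),
        live_time=meta.get("live_time_s"),
        source_id=meta.get("source_id", ""),
        tube_potential=meta.get("tube_potential_kV", 50.0))
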