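# Methods

This note documents the models, numerical choices and calibrations
behind kermalab, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Interaction-coefficient tables

All spectrum integrals use packaged CSV tables of the photon mass
attenuation coefficient μ/ρ and mass energy-transfer coefficient
μ_tr/ρ for dry air, water vapor and germanium on a 0.5 keV grid from
5 to 60 keV, generated once by `scripts/generate_reference_tables.py`
from standard compilation values and interpolated log-log at run time
(log-log linear interpolation is exact at nodes and appropriate for
smooth photoelectric-dominated coefficients with no absorption edges in
this range for air; the germanium K edge at 11.103 keV is represented
by a doubled grid point so interpolation never crosses it). μ_tr/ρ is
taken equal to μ_en/ρ: the radiative fraction is below 0.1 % under
60 keV. Queries outside the table range raise rather than extrapolate.

Two photoelectric treatments are provided. The *unrenormalized* tables
carry the compilation values; the *renormalized* variant rescales the
photoelectric component by 0.975, the magnitude of the
Hartree-Fock/Hartree-Slater renormalization for the low-Z constituents
of air. The variants differ by ~2 % at 10 keV and ~0.2 % at 50 keV,
and change the attenuation correction by less than the source-to-source
spread. The renormalized variant is the default throughout, matching
the treatment favored by recent synchrotron measurements on air. The
germanium values are accurate to a few percent — sufficient for the
detector-response model, whose correctness is established by exact
round-trip algebra rather than absolute efficiency.

Humid air is a mass-fraction mixture of the dry-air and water-vapor
tables (simple additivity); the air composition itself is fixed inside
the packaged dry-air table.

## Detector response and stripping

The HPGe response is schematized per incident bin-center energy with a
single-scattering model for a planar crystal (default 1 cm thick)
illuminated normally through a centered pinhole:

- interaction probability `1 − exp(−μ_Ge t)` along the thickness, with
  the photoabsorption depth distribution retained for escape
  calculations;
- photoelectric events deposit the full energy unless a germanium
  K x-ray (Kα 9.886 keV, branching 0.885; Kβ 10.982 keV) escapes
  through either plane face — K-shell fraction 0.87, fluorescence
  yield 0.535, escape integrated over the depth distribution along the
  crystal axis;
- incoherent events deposit the Compton-electron energy with the
  Klein-Nishina angular distribution; the scattered photon escapes
  along its straight path (depth-averaged) or is reabsorbed, in which
  case the full energy is deposited;
- coherent scattering and transmission leave no deposit.

Escape paths are evaluated along the crystal thickness only (no lateral
escape); this is a declared simplification of the full Monte Carlo
schematization and is validated by construction properties (per-column
probability balance to 1e-9, strict triangularity) and by the
qualitative behavior of the stripped/raw ratio, not by absolute
efficiency claims. Escape peaks merge into a single line, with a
warning, if the grid is coarser than the Kα–Kβ separation.

Backward stripping walks from the highest nonzero bin (or 60 keV,
whichever is lower) downward, normalizing the photopeak to the
remaining counts and subtracting the scaled deposition spectrum from
all lower bins. On noise-free input this is the exact algebraic
inverse of forward convolution (verified to 1e-6 relative and better).
Negative remainders — which arise from counting noise or model
mismatch — are clipped to zero and the clipped mass is reported in the
result metadata as a quality metric. The intrinsic resolution
(~0.5 keV FWHM) is deliberately not deconvolved: it appears only in
the forward simulator, and stripped spectra remain convolved with it,
which does not measurably perturb the downstream spectrum integrals.

Pile-up background is removed by subtracting the straight line through
the stripped spectrum's values at 7 and 50 keV (both anchors
overridable), clipping negatives and zeroing outside the interval.
The anchor at 7 keV works because the source spectra are effectively
zero there, so the anchor samples the background alone.

## Correction factors

- **k_ion** — the printed rate parameterizations for both chambers are
  evaluated exactly; the adopted policy for the low rates of these
  sources is unity, selectable by flag. A continuous-beam two-voltage
  (Boag) estimator `k = (n²−1)/(n²−i₁/i₂)` is provided for direct
  determinations.
- **k_humidity** — the product of (i) the dry/humid density ratio from
  the CIPM moist-air equation (enhancement factor, compressibility,
  CO₂ term; validated against the 1.2929 kg/m³ dry-air anchor to
  0.02 %), (ii) the dry/humid W-value ratio, and (iii) the dry/humid
  kerma-integral ratio with mixed coefficients. The W-ratio curve vs
  vapor partial pressure is a fixture: a fast exponential drop
  (knee 0.15 kPa) to a plateau near 0.9945 plus a gentle linear
  decline (0.0037/kPa). The plateau level matches the published
  mid-humidity W-ratio plateau; the knee depth was set once so the
  correction averaged over the laboratory envelope (RH 15–55 %,
  21–24 °C, 98.66–102.66 kPa) equals 0.9979. The slope makes the
  correction nearly flat — slowly decreasing — in RH, reproducing the
  known near-cancellation of the density and W effects. At zero RH
  every term is exactly 1.
- **k_att** — ratio of kerma integrals with the collecting-volume
  transmission `exp(−μ d_off)(1−exp(−μ d_col))/(μ d_col)` in the
  denominator, evaluated by the midpoint rule on the 80 eV spectrum
  grid (quadrature error far below the quoted precision). The
  effective coefficient uses `ln(k_att)/(ρ_air L)`: the attenuation
  length is converted to a mass thickness with the reference-condition
  air density, which is the interpretation that reproduces the
  published 1.85/1.83 cm²/g values from 1.0087/1.0283.
- **k_el, k_sc, k_fl, k_br/(1−ḡ)** — ratios of spectrum-weighted
  integrals of per-chamber numerator/denominator basis functions. The
  genuine Monte Carlo basis tables are not published; the packaged
  fixtures use the kerma kernel E·(μ_tr/ρ) as denominator and a gentle
  linear energy trend in the numerator, with the level calibrated once
  so the default synthetic spectrum reproduces the adopted values
  (electron loss grows with energy; scatter and fluorescence
  reabsorption are relatively larger at low energy). Factors adopted
  as exactly unity use identical numerator and denominator. The
  integrator is generic: real Monte Carlo tables in the same CSV
  layout drop in unchanged.
- **k_ii, k_dia** — adopted as unity with 0.2 % and 0.1 % standard
  uncertainties; the computed initial-ion alternative 0.9980 is stored
  and selectable by flag. (The budget table carries the initial-ion
  entry at its printed 0.04 % value, which reflects the spread of the
  computed alternative rather than the adopted-unity uncertainty.)

Pipeline policy mirrors laboratory practice: the attenuation and
humidity corrections are computed per run and checked against the
adopted constants, while the transport corrections enter through the
adopted values.

## Measurement equation and reference conditions

ḡ is fixed at zero; k_br/(1−ḡ) enters as 1.0 with its tabulated
uncertainty. The reference-condition factor
`(101.325/P)·((273.15+T)/295.15)` equals ρ_ref/ρ(T,P) for an ideal
gas. The reference rate is therefore evaluated as
`(W/e)·I/(ρ_ref·V_eff)·Πk · factor`, which is algebraically identical
to the ambient realization — the ambient-density division and the
normalization cancel, so the reported reference rate is independent of
laboratory temperature and pressure for a fixed charge per unit mass.
This cancellation is tested end to end.

Reference air kerma at 50 cm is the primary reported quantity;
air-kerma strength `S_K = K̇·vacuum_ratio·d²` is derived output, since
the vacuum-ratio conversion adds the dominant extra uncertainty.

Uncertainty budgets combine named Type A and Type B components by plain
root-sum-square with no effective-degrees-of-freedom machinery,
matching the adopted budget arithmetic; the measurement-specific
charge repeatability enters as an additional Type A component. The
well-chamber transfer coefficient is the reference rate divided by the
well current, with the expanded (k=2) uncertainty formed from the
0.7 % air-kerma-rate component and the transfer residual; the coverage
factor of the 0.7 % component is not further decomposed.

## Synthetic source model

The generator emulates the *measured, stripped* spectra of miniature
50 kV sources, not the bare tube physics: a Kramers continuum
`(E₀−E)/E` times an air-equivalent filtration transmission
`exp(−(μ/ρ)_air(E)·x)`, plus Gaussian characteristic lines at the
standard Y K (14.958, 16.738 keV) and W L (8.398, 9.672, 11.286 keV)
energies with 0.5 keV FWHM (the intrinsic resolution retained in
stripped spectra), a hard cut-off at 7 keV and the 50 keV endpoint.
Cooling-catheter and source-wall transmission are absorbed into the
single effective filtration parameter.

The two continuum/line degrees of freedom — filtration thickness
x = 1.44205 g/cm² and line fluence fraction 0.153264 of the
continuum — were fixed by a single two-parameter solve against the two
printed summary statistics of the measured ensemble: fluence-weighted
mean energy 25.3 keV and kerma-effective attenuation coefficient
1.85 cm²/g (Lamperti geometry). A smooth filtered continuum alone that
hits the mean energy has an effective coefficient near 1.2 cm²/g; the
prominent characteristic lines must carry a substantial fluence share,
consistent with their visual dominance in measured spectra. Per-source
variability is lognormal jitter on the filtration (σ = 0.33) and on
each line intensity (σ = 0.30), set once so the ensemble spread of
mean energies is ≈1.1 keV; this jointly reproduces the per-source
spread of the attenuation correction (≈0.1 %) and the in-vacuo ratio
(≈0.7 % relative SD) without further adjustment.

What the synthetic ensemble does *not* model: pulse-processing
electronics, energy-calibration drift, true pile-up spectral
distortion below the endpoint (represented only by the linear
background term), angular source anisotropy, and real cross-section
uncertainties. Passing tests therefore demonstrate the correctness and
internal consistency of the analysis chain under the stated spectral
conditions, not the absolute accuracy of a laboratory realization.

The acquisition model applies the response convolution, Gaussian
resolution smearing, a linear pile-up ramp extending ~7 keV above the
endpoint scaled by the dead-time fraction, and Poisson counting noise;
all generators are pure functions of (parameters, seed).

## Problem sizes

The default grid is 80 eV bins over 0–60 keV (750 bins). Test and
acceptance ensembles use 30 spectra for attenuation/vacuum-ratio
statistics, 100 for the mean-energy calibration, and 26×10 simulated
measurements for repeatability; these sizes give Monte Carlo errors
comfortably below the tolerances they are compared against, and the
full suite runs in seconds.

## Known limitations

- The detector response is a 1-D-escape schematization; stripped
  absolute efficiencies are not metrological.
- The W-ratio curve and transport-correction basis functions are
  calibrated fixtures, not published datasets; they are constrained
  only by the aggregate values they reproduce.
- Coefficient tables carry compilation-vintage uncertainty at the
  percent level; quantities formed as ratios (k_att, vacuum ratio,
  k_humidity) largely cancel it, absolute kerma integrals do not.
- The Wyckoff-Attix chamber preset is complete only in its attenuation
  length; the other dimensions are placeholders for the μ_eff-vs-L
  interpolation.
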