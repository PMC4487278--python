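# kermalab

Air-kerma realization for miniature 50 kV electronic brachytherapy
x-ray sources with parallel-plate free-air chambers (FACs), implemented
as a tested, reusable pipeline: HPGe pulse-height-spectrum stripping,
the nine FAC correction factors, the air-kerma measurement equation,
air-kerma-strength conversion, and GUM-style uncertainty budgets —
exercised end to end on synthetic spectra with the statistical
structure of measured miniature-source spectra.

## Who this is for

Radiation-dosimetry and medical-physics developers working on
primary-standard air-kerma metrology for low-energy x-ray sources: the
package lets every stage of the realization chain be driven, tested and
audited without access to laboratory data.

## The physics

A free-air chamber realizes the air-kerma rate from the net ionization
current through the measurement equation

    K̇_air = (W/e) · I_net / (ρ_air · V_eff · (1 − ḡ)) · Π k_i

with `W/e = 33.97 J/C` the mean energy expended in dry air per ion pair
divided by the elementary charge, `ρ_air` the dry-air density from the
ideal-gas relation `ρ_air = ρ₀ (P/101.325 kPa)(273.15/(273.15+T))`
(`ρ₀ = 1.2929 kg/m³`), `V_eff` the aperture-area × collector-length
volume, `ḡ ≡ 0` at these energies, and nine correction factors `k_i`
(ion recombination, humidity, in-chamber air attenuation, electron
loss, photon scatter, fluorescence and bremsstrahlung reabsorption,
initial ion, diaphragm scatter). Results are stated for reference
conditions of 22 °C and 101.325 kPa.

The spectrum-dependent corrections are integrals over the true photon
spectrum `S(E)`, which is obtained from a measured HPGe pulse-height
distribution by backward stripping of a precomputed triangular
energy-deposition response (photopeak, Ge K x-ray escape peaks, Compton
escape continuum), followed by a straight-line pile-up background
subtraction anchored at 7 and 50 keV. For example the attenuation
correction is

    k_att = ∫S(E)·E·(μ_tr/ρ) dE /
            ∫S(E)·exp[−μ d_off]·(1−exp[−μ d_col])/(μ d_col)·E·(μ_tr/ρ) dE

and the effective attenuation coefficient `(μ/ρ)_eff =
ln(k_att)/(ρ_air·L)` with `L = d_off + d_col/2` the attenuation length.
Air-kerma strength is `S_K = K̇_air^vac(d)·d²` (1 U = 1 µGy·m²/h), with
the in-vacuo/in-air ratio evaluated from the spectrum by removing the
exponential attenuation of the 50 cm air path inside the kerma
integral `K_air = ∫Φ(E)·E·(μ_tr/ρ) dE`.

## Worked example

Simulate two synthetic sources, strip one pulse-height distribution
back to a spectrum, and compute the Lamperti-chamber corrections:

```
$ kerma-lab simulate --sources 2 --seed 5 --outdir sim
wrote 2 sources to sim

$ kerma-lab strip sim/source_0005_phd.csv --out stripped.csv
mean energy: 24.29 keV; clipped counts: 0

$ kerma-lab corrections stripped.csv --chamber lamperti
{
 "chamber": "lamperti",
 "k_att": 1.010358663475826,
 "k_humidity": 0.9978485848306173,
 "mean_energy_keV": 24.28936070707788,
 "vacuum_ratio_50cm": 1.154026811108397,
 "k_el": 1.0006568195199945,
 "k_sc": 0.9987477242517296,
 "k_fl": 0.997995451815775,
 "k_br": 1.0
}
```

This source realization is slightly softer than the ensemble average
(mean energy 24.3 keV versus 25.3 keV), so its attenuation correction
(1.0104) sits in the upper half of the per-source range 1.0064–1.0110
and its 50 cm vacuum ratio (1.154) is above the ensemble mean of 1.12.
The humidity correction at the default laboratory state (35 % RH) is
0.9978, and the in-chamber transport corrections are within a few parts
in 10⁴ of their adopted values — they are deliberately insensitive to
source-to-source spectral differences.

Realizing air kerma from a measured current:

```
$ kerma-lab realize --config run.yaml     # current, chamber, T, P
{
 "kerma_rate_Gy_per_s": 0.00023490328131576879,
 "kerma_rate_ref_Gy_per_s": 0.00023490328131576876,
 "air_kerma_strength_Gy_m2_per_s": 6.577291876841526e-05,
 "air_kerma_strength_U": 236782.50756629495,
 "u_type_A_pct": 0.07348469228349534,
 "u_type_B_pct": 0.31480152477394385,
 "u_combined_pct": 0.3232645975048922
}
```

The measurement-condition and reference-condition rates coincide
because the ambient-density term and the reference-condition factor
cancel for a fixed charge per unit mass (see `docs/methods.md`).

## Layout

- `kermalab.physics_tables` — coefficient tables, log-log
  interpolation, humid-air mixing.
- `kermalab.spectrometry` — HPGe response model, backward stripping,
  pile-up subtraction, spectrum I/O.
- `kermalab.fac_corrections` — the nine correction factors, chamber
  presets, adopted constants.
- `kermalab.kerma_pipeline` — measurement equation, air-kerma
  strength, uncertainty budgets, well-chamber transfer coefficients.
- `kermalab.synthetic` — source-spectrum generator, pulse-height
  forward model, simulated measurements.
- `kerma-lab` — CLI over the above (`simulate`, `strip`,
  `corrections`, `realize`, `budget`).
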