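{
 "material": "germanium",
 "variant": "renormalized",
 "units": {
  "energy": "keV",
  "mu_rho": "cm^2/g",
  "mu_tr_rho": "cm^2/g"
 },
 "provenance": "Log-log interpolation of standard compilation values for photon mass attenuation and mass energy-transfer coefficients; mu_tr/rho taken equal to mu_en/rho (radiative fraction negligible below 60 keV). The renormalized variant rescales the photoelectric component by 0.975.",
 "generated_by": "scripts/generate_reference_tables.py"
}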