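# Synthetic stand-in for one system of the composition matrix.
# Enrichment parameters are emulation choices, not measured values.
name: systemB
temperature_K: 310
spec:
  box:
  - 80.0
  - 80.0
  - 120.0
  leaflet_z:
  - 42.5
  - 77.5
  lipid_grid: 24
  sigma_xy: 0.5
  p_fraction: 0.25
  n_fraction: 0.25
  n_frames: 100
  ion_counts:
    O2-: 80
    K+: 134
  charged_lipids: 54
  enrichment:
    O2-:
      w_surf: 0.33
      lam: 1.5
      r_max_exp: 8.0
      r_max: 40.0
    K+:
      w_surf: 0.2
      lam: 1.8
      r_max_exp: 8.0
      r_max: 40.0
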