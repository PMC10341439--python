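# memprox

Membrane-proximity statistics for ions and charged radicals near lipid
bilayers.

Biological membranes are usually negatively charged, and reactive oxygen
species such as the superoxide anion radical (·O₂⁻) are themselves
charged. How strongly a membrane's charge — or a protective glycosyl
layer on glycolipid headgroups — rarefies the radical population right at
the bilayer surface is a question about *distributions*: how often does a
mobile species sit within a few ångströms of the lipid atoms? `memprox`
provides the statistical toolkit for answering it from multi-frame
coordinate data (MD-style trajectories or synthetic ensembles), aimed at
people analysing bilayer/electrolyte simulations.

## What it computes

Given per-frame coordinates, per-atom species labels, charges and role
tags, the package computes:

- **Distance-to-surface slice density.** For a target species, the
  distance *r* of each particle to the membrane surface (minimum distance
  to any non-excluded lipid atom of either leaflet, minimum-image in
  *x,y*), histogrammed into

  D(r) = N(r) / (Dx · Dy · δr · f),

  with N(r) the count in [r, r+δr) summed over all f frames and Dx·Dy the
  lateral box area (defaults δr = 0.2 Å, r ∈ [0, 40] Å).

- **Near-surface occurrence fraction.** R = 100 · A_r / A %, where A_r is
  the area under D(r) up to the cutoff r_c — the first local minimum of
  D after its first peak (species defaults 3.2 Å for ·O₂⁻ and K⁺, 2.8 Å
  for Na⁺, 3.8 Å for Cl⁻ when no interior minimum exists) — and A the
  total area. Between-system comparisons are reported as relative
  reductions 100·(R_ref − R_test)/R_ref.

- **Axial profiles.** Per-species number densities along the membrane
  normal *z*; P–P peak separation (a bilayer-thickness proxy), N–N
  separation, and the peak-height-to-bulk ratio R_ph.

- **Electrostatic potential.** Laterally averaged charge density ρ(z) and
  the slab Poisson double integral
  ψ(z) = −(1/ε₀ε_r) ∫₀ᶻ dz′ ∫₀^{z′} ρ(z″) dz″, with signed extrema and
  peak separations.

- **Equilibration.** Kabsch least-squares superposition, per-frame RMSD
  against the first frame or the iterative mean structure, and a plateau
  criterion on the trailing ordinary-least-squares slope (default
  tolerance 0.05 Å/ns).

- **Speciation.** The Henderson–Hasselbalch protonated fraction of the
  superoxide/hydroperoxyl pair (pKa 4.7): at pH 7.4 only ≈ 0.2% is in the
  neutral HO₂· form, which is why the anionic form and its electrostatics
  dominate.

A synthetic bilayer-slab generator (`memprox.synthetic`) produces
ensembles whose ion-to-surface distances follow a known mixture of a
surface-enriched exponential layer and a uniform bulk, with a closed-form
expected R — the recovery oracle used throughout the test suite.

## Worked example

Generate a neutral-membrane-like synthetic system and measure how often
the radical sits within 3.2 Å of the surface:

```sh
$ cat specA.yaml
box: [80.0, 80.0, 120.0]
leaflet_z: [42.5, 77.5]
lipid_grid: 24
ion_counts: {O2-: 80, K+: 80}
charged_lipids: 0
enrichment:
  O2-: {w_surf: 0.6, lam: 1.5, r_max_exp: 8.0, r_max: 40.0}
  K+:  {w_surf: 0.18, lam: 1.8, r_max_exp: 8.0, r_max: 40.0}
n_frames: 200
seed: 1

$ memprox synth --spec specA.yaml --out A.mxf
wrote 200 frames, 1312 atoms -> A.mxf

$ memprox proximity --traj A.mxf --target "species:O2-" \
      --membrane "tag:lipid" --exclude-tags glycosyl --out proxA.csv
{"R_percent": 56.27, "r_c": 3.2, "r_peak": 0.1, "rc_defaulted": true, "species": "O2-"}
```

56.27% of the radical's distribution lies within r_c = 3.2 Å of the
surface — within Monte-Carlo error of the generator's closed-form
expectation (56.35% for w_surf = 0.6, λ = 1.5 Å). `rc_defaulted` is true
because the synthetic distance law decays monotonically from the surface
(no interior first peak), so the species default cutoff was used.

Comparing a neutral and a negatively charged system end to end
(`memprox run --config run.yaml`, two systems with emulation weights
0.60/0.33 and the charged system carrying 54 lipid charges balanced by
134 K⁺) prints:

```json
[
  {"system": "charged", "R_percent": 34.92,
   "reduction_vs_ref_percent": 38.41, "ratio_of_ref_percent": 61.6},
  {"system": "neutral", "R_percent": 56.7,
   "reduction_vs_ref_percent": 0.0, "ratio_of_ref_percent": 100.0}
]
```

i.e. membrane charge reduces the radical's near-surface occurrence by
38.41% in this synthetic pairing. The speciation helper:

```sh
$ memprox speciation --ph 7.4
{"pH": 7.4, "pKa": 4.7, "protonated_fraction": 0.0019912891707283, "protonated_percent": 0.1991}
```

Presets `systemA` … `systemH` (see `memprox.pipeline.load_preset`) encode
the full composition matrix — neutral vs charged membranes, K⁺ vs Na⁺
counterions, added KCl, and a glycosyl-covered membrane — over synthetic
geometry so the comparative workflow runs without any MD engine.

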