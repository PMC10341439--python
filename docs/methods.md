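# Methods

This note records the statistical model behind `memprox`, the defaults
and their rationale, what the synthetic generator does and does not
emulate, and the numerical choices that were genuinely open.

## The proximity statistic

The quantity at the centre of the package is the distance-to-surface
slice density

D(r) = N(r) / (Dx · Dy · δr · f),

where N(r) counts target particles whose distance to the membrane
surface falls in the half-open slab [r, r+δr), summed over all f frames,
and Dx·Dy is the lateral box area. Defaults are δr = 0.2 Å and
r ∈ [0, 40] Å, the conventions used when this statistic is applied to
multi-nanosecond bilayer trajectories (typically 1000 frames over 5 ns,
hence the 5 ps default frame spacing in the RMSD module). Particles
beyond r_max drop out of the histogram; their count is reported.

**Definition of "surface".** The distance of a particle to the membrane
is the minimum Euclidean distance to any non-excluded lipid atom of
*both* leaflets, with minimum-image wrapping in x and y only (slab
geometry — z is the bilayer normal and must never be wrapped). A
min-atom definition, rather than distance to a fitted plane, is what
makes sub-3 Å first-peak positions possible and is the only definition
consistent with cutoffs like 2.8–3.8 Å. All atoms of the membrane
selection participate; no heavy-atom filter is applied (callers can
restrict the selection expression instead). Glycosyl-tagged atoms can be
excluded so the distance refers to the phospholipid (hydrocarbon-bearing)
surface even in glycolipid membranes — the chemically relevant surface
for lipid peroxidation.

**Occurrence fraction.** R = 100·A_r/A %, with A_r the area under D up
to the cutoff r_c and A the total area. Because the normaliser
Dx·Dy·δr·f is constant across bins, the area ratio is computed in the
exactly proportional count-sum form; this sidesteps any integration-rule
ambiguity and makes R manifestly invariant under rescaling of area, bin
width or frame count. A bin belongs to the near-surface region iff its
right edge is ≤ r_c; a particle exactly at r_c therefore counts to the
far side. Both leaflets are pooled into one histogram with a single
Dx·Dy normaliser; the absolute scale of D is thus conventional, but
every comparison the package reports (R, relative reductions, ratios) is
a ratio and unaffected.

**Cutoff detection.** r_c is the first local minimum of D(r) after its
first peak. The curve is smoothed with a centred moving average (default
3 bins) and the first peak must have prominence above 5% of the global
maximum — real D(r) curves are noisy and these two knobs are exposed in
the API with those defaults. When no interior minimum exists (monotone
profiles; the synthetic generator's exponential law), the species
defaults 3.2 Å (·O₂⁻), 3.2 Å (K⁺), 2.8 Å (Na⁺) and 3.8 Å (Cl⁻) are used
and the result is flagged `defaulted`.

## Synthetic generator and its oracle

The generator emulates the *geometry* of a bilayer patch (two leaflets
of pseudo-atoms on jittered xy lattices in an 80 × 80 × 120 Å box, leaflet
planes 35 Å apart — a typical phosphate peak-to-peak spacing — leaving
≥ 40 Å of aqueous half-space per side) and the *distribution* of mobile
ions, not their dynamics. Each ion's distance to its leaflet plane is an
i.i.d. draw from

p(r) = w_surf · TruncExp(r; λ, r_max_exp) + (1 − w_surf) · U(0, r_max),

a surface-enriched layer (the electric double layer next to a charged
interface) plus a uniform bulk. The expected occurrence fraction is the
closed form

E[R](r_c) = 100·[w_surf·(1−e^{−r_c/λ})/(1−e^{−r_max_exp/λ})
            + (1−w_surf)·r_c/r_max],

which the analysis pipeline must recover within binomial Monte-Carlo
error; this is the package's main internal validation loop.

Two deliberate choices keep the oracle *exact* rather than approximate:

- lattice jitter is applied in xy only (z jitter would smear p(r));
- each ion is placed directly above a uniformly chosen lattice site of
  its leaflet, so the minimum ion-to-atom distance equals the drawn
  plane distance exactly. Fully uniform ion xy positions would inflate
  small distances by ≈ E[d²]/2r (d the offset to the nearest lattice
  site), a bias comparable to the 3-s.e. recovery band at the default
  sample sizes. The ion xy marginal is lattice-discretised as a result;
  none of the computed statistics depend on it.

What the generator does **not** emulate, and hence what passing recovery
tests do not show: real D(r) shapes (the synthetic law is monotone from
the surface — no first peak/minimum structure, no bimodal cation
layering), correlated frames, ion–ion interactions, membrane
undulations, or water. Bimodal distributions can be composed from two
mixtures if needed, but no mechanistic claim is attached. Water is
implicit: no statistic in the package counts water atoms. Generated
systems verify electroneutrality (ion charges plus the configured count
of −1 e lipid charges must sum to zero).

Per-purpose RNG streams are derived from the root seed with fixed
`SeedSequence` spawn keys (0 = lattice, 1 = glycosyl, 2+i = ion species
in sorted order), so adding a species does not perturb the others.

## Axial profiles and R_ph

Number densities along z are frame-averaged histograms normalised by
Dx·Dy·Δz (default Δz = 0.2 Å). The P–P separation takes the global
maximum on each side of the bilayer centre (estimated as the midpoint of
the phosphate peaks, with a config override) and reports the distance
between bin centres rounded to 0.1 Å. Leaflets are not symmetrised. The
peak-to-bulk ratio R_ph divides the maximum density within 10 Å of
either surface by the mean density over aqueous bins farther than 10 Å
from both surfaces; the 10 Å margin clears the first and second
enrichment peaks, and at least 10 bulk bins are required for the mean to
be meaningful.

## Electrostatic potential

The laterally averaged slab Poisson solution is computed by two
cumulative trapezoid integrations of ρ(z) (e/Å³, converted to SI), with
the boundary conditions E(0) = 0 and gauge ψ(0) = 0 at the lower box
edge. ε_r defaults to 1 — the raw-charge convention appropriate for
explicit-solvent charge densities. Reported summaries (signed extrema,
per-side peak separations) are gauge-invariant up to the reference
level; when a bulk window is supplied (the pipeline uses the aqueous
region beyond the upper surface plus the R_ph margin) the profile is
re-zeroed on the bulk mean, which is the natural reference for signed
maxima. Non-neutral total charge makes ψ grow quadratically; the profile
is still returned but flagged, with a warning. No dipole or slab-PME
correction schemes are attempted.

A note on discrete neutrality: the double integral is
trapezoid-consistent, so fixtures must be neutral in the trapezoid sense
(not merely zero-sum) to avoid a linear drift of ψ; the capacitor and
symmetry tests do exactly this.

## Superposition and equilibration

Superposition is the standard Kabsch SVD solution with the determinant
correction enforcing a proper rotation; collinear references are
rejected. RMSD series can use the first frame as reference (the default,
matching the usual from-start convention for judging equilibration) or
the time-mean structure ⟨r_α⟩, computed by two rounds of superposition
to the evolving mean — iterating further changes the result below
numerical noise for well-behaved ensembles. The plateau criterion fits
an ordinary-least-squares slope to the trailing window of the series and
declares equilibration when |slope| ≤ 0.05 Å/ns; the tolerance is a
package choice (no standard numeric criterion exists for "the RMSD curve
looks flat") and is exposed in the API.

## Speciation

The superoxide/hydroperoxyl equilibrium ·O₂⁻ + H⁺ = HO₂· has pKa 4.7;
the protonated fraction 1/(1 + 10^{pH−pKa}) evaluates to 0.199% at
pH 7.4, the value used throughout to justify treating the radical as an
anion. pH 7.4 is the documented default for "physiological".

## Problem sizes and determinism

The validation suites run on deliberately modest sizes chosen for tight
Monte-Carlo control: recovery uses 200 ions × 100 independent frames
(2×10⁴ particle-frames) per seed over 20 seeds, with 3-s.e. binomial
bands and a ≥ 95% coverage requirement; oracle-equivalence checks use 50
random instances of ≤ 10³ atoms and demand bit-exact agreement with the
brute-force double loop (the vectorised kernel performs the same IEEE
operations in the same order, and min/sqrt commute). All randomness
flows from explicit seeds; pipeline reports are byte-identical across
reruns with the same seed, which is asserted in the tests.

## Known limitations

- Whether the two leaflets' counts should be halved rather than pooled
  in the D(r) normaliser is a convention; ratios are unaffected.
- The preset enrichment weights (`systemA`…`systemH`) are emulation
  choices tuned to the qualitative ordering neutral > charged >
  glycosyl-covered; they are not measured quantities, and absolute R
  values from presets should not be compared against real trajectories.
- The potential module assumes an orthorhombic box and a z-normal slab;
  no 3D maps.
- GRO inputs are read as concatenated fixed-column frames; binary
  trajectory formats (XTC/DCD) are out of scope.
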