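# Methods

`lipocurv` implements two computational pipelines for studying how
rod-shaped proteins (CETP-like) bind the curved lipid surfaces of HDL-sized
particles and liposomes: (A) projection-visibility-corrected counting of
surface protrusions measured on negative-stain EM-style 2D projections, and
(B) coarse-grained POPC vesicle construction, relaxation and
surface-hydrophobicity analysis as a function of curvature.

## Track A — protrusion counting under projection occlusion

### Visibility model

A rod of length *l* attached radially to a sphere of diameter *D* has its
tip at radial distance *D*/2 + *l*.  Under parallel projection along a
random viewing axis, the tip lands outside the particle silhouette — and
the rod is countable — only when the attachment direction is close enough
to the projection plane.  For attachment directions uniform on the sphere
the visibility probability is

    P(D, l) = sqrt(1 − (D / (D + 2 l))²)

P is 1 for vanishing spheres, 0 for vanishing rods, increasing in *l* and
decreasing in *D*.  For a 8.5-nm rod, P ≈ 0.88 on a 15-nm particle and
≈ 0.71 on a 40-nm particle: raw projected counts understate true surface
occupancy by 12–29% over the relevant size range, and by more for larger
vesicles.  An optional minimum resolvable protrusion length *m* generalises
the closed form (tip must project at least *m* beyond the silhouette); the
default is 0.

The closed form is verified in the test suite against an independent
Monte-Carlo orientation-sampling oracle (10⁶ uniform directions per (D, l)
point, agreement within 3 binomial standard errors), and the projection
routine of the synthetic generator is verified against the closed form the
same way — the two implementations share no geometry code.

### Occlusion correction

Binned series (per-diameter-bin mean visible counts, or count histograms)
are corrected by dividing each bin by P evaluated at the bin center with
the class protrusion length.  Bins where P falls below a configurable floor
(default 0.05) are flagged and passed through undivided rather than
amplified; flagged bins are excluded from downstream fits.  In expectation
the correction exactly inverts visibility thinning: visible counts are a
thinned Poisson process with rate λ(D)·P(D, l), so corrected bin means
recover λ.  The end-to-end recovery test generates 10⁴ particles with
λ(D) = max(0, 8.4 − 0.2 D), projects, bins (2.17-nm steps), corrects, and
requires every bin holding ≥ 200 particles to match λ within 5%.  For that
bound to sit at ≥ 3σ of the binomial/Poisson sampling noise, the recovery
population is drawn near-uniformly on [13.02, 23.87] nm (6–11 bin edges of
the 2.17-nm grid), giving ~2000 particles per bin with λ between 3.6 and
5.8; the comparison uses λ at the per-bin mean diameter, which removes the
O(2%) systematic from the sloping diameter density within a bin.

### Synthetic particle fields

Ground truth particles carry a class diameter law (normal for the HDL
classes: 12.7 ± 1.6, 11.4 ± 1.7 and 10.2 ± 1.2 nm for HDL₂, HDL₃ and
reconstituted HDL; truncated lognormal for liposomes, default mode 30 nm on
[7.7, 116.2] nm with an alternative 50-nm-mode preset for the
pre-staining nominal peak), a protrusion count drawn Poisson with mean
λ(D) = max(0, β₀ − β₁·D), attachment directions uniform on the sphere, and
rod lengths normal (8.5 ± 0.6 nm, truncated at 0).  The default binding law
(β₀ = 8.4, β₁ = 0.2 nm⁻¹) is calibrated so that ~5.4 rods decorate a 15-nm
liposome while a 40-nm liposome carries ~0.4 — the qualitative regime of
CETP on POPC liposomes; only the trend, not a generative law, is available
to calibrate against, so both parameters are configuration.

Measurement noise: both projected diameters receive multiplicative
Gaussian noise (CV 5% by default) and the long axis an elongation factor
drawn truncated-normal(1.1, 0.08) ≥ 1, emulating stain-flattening
anisotropy; with noise disabled the geometric mean of the two measured
diameters equals D exactly.  The generator emulates measurement records,
not micrograph pixels: real-data effects it does not model include
overlapping particles, stain-depth variation, picking bias against faint
protrusions, and spatial correlations within micrographs.  Passing
recovery tests therefore demonstrate correctness of the estimator under
the stated measurement model, not robustness to those artifacts.

Overlapping protrusions in projection are counted independently (two rods
whose tips project to nearby points count as two); real measurements would
sometimes merge them.

## Track B — coarse-grained vesicles and surface hydrophobicity

### Lipid model and vesicle construction

One POPC lipid is 13 beads (residue-based coarse-graining, ~10 heavy atoms
per bead): choline, phosphate, two glycerol beads (hydrophilic) and nine
tail beads split 4 + 5 between the palmitoyl and oleoyl chains
(hydrophobic).  The per-chain split is a package choice; only the 1+1+2+9
assignment is fixed by the model.  Beads sit on eight depth levels spanning
18.4 Å — one leaflet of the 36.8 Å bilayer — so the radial chain spacing
(≈ 2.6 Å) is compressed relative to a free chain (~3.3 Å).  Glycerol beads
are classed hydrophilic for surface accounting; `SASAConfig.glycerol_class`
exposes the alternative convention.

A vesicle of nominal outer diameter *d* nm places outer-leaflet head beads
on a Fibonacci sphere lattice of radius R = 5·d Å with
round(4πR²/65 Å²) lipids, and inner-leaflet heads on R − 36.8 Å tiled at
the same area per lipid (tiling at head-bead radii is a convention choice;
the reference 12-nm build gives 696 outer + 104 inner lipids = 10,400
beads).  Tails point to the bilayer midplane.  The Fibonacci lattice is
deterministic up to a seed-controlled global rotation and per-lipid
azimuths.  An open pore removes all lipids inside a spherical cap of the
requested area fraction (13% → 42.3° half-angle); the pore is the
escape valve that lets the initially strained bilayer redistribute during
relaxation.

### Stand-in force field

The published residue-based CG interaction tables are not reproduced here;
the relaxation engine uses a deliberately simple implicit-solvent stand-in
whose parameters are package defaults (energy in arbitrary thermal-scale
units):

* harmonic bonds (k = 10 /Ų) and angles (k = 5 /rad²) with rest geometry
  from the template — lipids are semi-rigid;
* 12-6 Lennard-Jones between beads of different lipids, truncated and
  shifted at 12 Å, with class-pair parameters: ε = 0.5/0.5/1.5 and
  σ = 9.1/6.9/4.7 Å for head–head/head–tail/tail–tail.  Tail–tail cohesion
  is strongest (3× head–head) and drives tail burial and pore closure.
  The large head–head diameter represents the hydrated head group; it is
  the lateral pressure element that pins the head lattice near the 65 Ų
  per-lipid density.  Without it, zero-temperature minimisation of an LJ
  membrane collapses toward crystalline tail packing (~48 Ų/lipid) — a
  well-known artifact of minimising thermal force fields — and the vesicle
  shrinks far below its nominal size.  σ_hh was calibrated once against
  the relaxed diameter of the pore-free 12-nm build and then frozen;
* an implicit-solvent exposure penalty: every hydrophobic bead pays
  w·A₀·exp(−ρ/ρ₀), where ρ is a smooth local bead density (quartic kernel,
  7 Å range), ρ₀ = 4, A₀ = 4π(2.35+1.4)² Å² a reference exposed-bead area
  and w = 0.03 energy/Ų.  This term supplies the edge tension at the pore
  rim and a burial preference for exposed tails, standing in for the
  hydrophobic effect of the missing explicit water.  A repulsion cap below
  0.8 σ keeps overlapping beads finite (with a warning).

Forces are the exact analytic gradient (finite-difference-verified in the
tests to 1e-4 relative).  Energy is invariant under rigid rotation and
translation, and internal forces sum to zero.

### Relaxation and pore healing

Relaxation is damped gradient descent with backtracking: each step moves
beads along the net force (largest per-bead displacement capped at 0.5 Å)
and is accepted only if the energy does not increase; neighbor lists
(KD-tree, 2 Å skin) are refreshed on drift.  Termination: force inf-norm
below tolerance, step budget (default 2500), or a stalled line search.

Zero-temperature descent cannot reproduce the lateral lipid diffusion by
which a thermal simulation closes a 40°-wide pore — the lattice jams with
the hole intact.  Pore healing therefore applies collective moves: locate
the largest empty spherical cap on the outer head shell, then remap every
lipid's polar angle about the pore axis so the cap shrinks by 3° while the
covered region stretches uniformly in solid angle (each lipid rotates
rigidly about the center of mass), and descend again.  A healing block is
accepted only if it ends below the pre-move energy, so the recorded energy
trace of accepted states is non-increasing and the force field — not the
move generator — decides whether closure is favorable; if a block fails to
recover the pre-move energy it is reverted and healing stops.  Healing
rounds repeat until the residual empty cap stays below 8° through a full
descent phase (relaxed pore-free vesicles show 6–7° of bare lattice
vacancy; the pore-closed diagnostic flags empty caps above 2% of shell
area, i.e. 16.3°).

Stabilisation diagnostics follow the usual criteria for a relaxed vesicle:
pore closed (grid search for empty caps on a ~1° direction mesh), spherical
shell (radial distribution of head beads about the center of mass;
sphericity = outer-peak FWHM / peak radius), and a stabilised hydrophobic
fraction.  The equilibrated diameter is twice the mean radial distance of
outer-leaflet choline beads from the center of mass.

### Thermal snapshots

The production analysis of a thermal trajectory averages surface properties
over late frames.  Here the post-minimisation state is dressed with
isotropic Gaussian jitter (default amplitude 1.7 Å per coordinate, 30
snapshots) and the hydrophobic fraction is averaged over the ensemble.
The amplitude plays the role of the thermal bead RMSF: minimised
zero-temperature surfaces are unphysically smooth, and surface packing
defects at body temperature are wider than their T = 0 counterparts.  The
1.7 Å default is of the order of CG lipid bead fluctuations at 300 K and
was fixed together with the force-field calibration; like every parameter
here it is configuration, and the snapshot-to-snapshot standard deviation
is reported alongside the mean.

### SASA and the curvature trend

Shrake–Rupley SASA uses per-bead test points on a Fibonacci lattice
(default 960; converges to <0.5% between 960 and 3840 points), bead radius
2.35 Å (half the 4.7 Å CG bead diameter) and probe radius 2.35 Å — the
probe represents a coarse-grained water bead, matching the solvent
resolution of the bead model.  An atomistic 1.4 Å probe resolves sub-bead
crevices that CG solvent cannot enter and, on these bead models, saturates
the measurement with lattice-crevice area to the point of erasing the
curvature dependence; the CG-consistent probe preserves it.  Neighbor
search uses a KD-tree; the kernel is numba-compiled.  The hydrophobic
fraction is tail-bead SASA over total SASA in percent.  The total includes
the lumen-facing surface (solvent fills the vesicle interior); a
`surface="outer"` option restricts the accounting to beads outside the
bilayer midplane for sensitivity analysis, since which denominator the
reference analysis used is ambiguous.

`curvature_trend` reports regressions of the fraction against both D and
1/D, plus a strict-monotonicity flag.  For the reference five-point series
the 1/D regression gives r ≈ 0.99 while the direct-D regression gives
|r| ≈ 0.87 — hydrophobicity from curvature-induced packing defects is
linear in curvature, not diameter.  Both are always reported because the
conventional presentation ("fraction against diameter") is ambiguous about
the abscissa actually regressed.

## Statistics

Geometric-mean diameter sqrt(d_long·d_perp); aspect ratio ≥ 1 with inputs
sorted; half-open histogram bins [k·step, (k+1)·step) with origin 0 and the
2.17-nm step used for diameter histograms; least-squares polynomial fits
(degree configurable; 6 by default, 9 supported — both conventions appear
in practice) restricted to their fitted domain; OLS regression with Pearson
r and the two-sided t-test p-value (t = r·sqrt(n−2)/sqrt(1−r²), df = n−2;
delegated to `scipy.stats.linregress` and cross-checked against a
permutation test).  Binding-fraction summaries report the {0, 1, 2, >2}
visible-count categories, pooled, or as mean ± sd across micrograph groups
when group labels exist.

## Problem sizes used by the test suite

The default test run keeps simulations at sizes that make the full suite
complete in well under half an hour on one CPU: the 12-nm vesicle
(10,400 beads) is relaxed with the full protocol; the 42-nm vesicle
(162,019 beads pored) is relaxed with a reduced step budget and analysed
with 240 SASA points; the five-diameter monotonicity series uses pore-free
builds with a short descent, a small snapshot ensemble and 240-point SASA
over 5 seeds.  The acceptance script runs the full 12-nm protocol.
Monte-Carlo checks use 10⁶ orientations; recovery fields 10⁴ particles.

## Known limitations

* The force field is a calibrated stand-in: absolute energies are not
  physical, kinetics are meaningless, and no thermodynamic-ensemble claims
  are made.  Absolute hydrophobic fractions inherit the calibration;
  the curvature trend is the robust, mechanism-level output.
* Zero-temperature relaxation plus jitter is not an MD trajectory; lipid
  flip-flop between leaflets, lateral diffusion kinetics and the 90-ns
  closure pathway are out of scope.
* Leaflet lipid numbers come from head-radius tiling, which over-crowds
  the outer-leaflet tails at the midplane on small vesicles; relaxation
  resolves the strain by interdigitation and a slight inward shift of the
  inner leaflet, so the relaxed bilayer is thinner than 36.8 Å at high
  curvature.
* The synthetic EM fields are measurement-record emulations; printed
  per-micrograph binding percentages and size histograms of real samples
  are not reproducible from them, only the estimator properties are
  testable.
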