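# lipocurv

Curvature-driven surface analysis of HDL-like particles and liposomes:

* **Binding track** — synthetic populations of spherical particles
  (HDL subclasses, POPC liposomes) decorated with rod-shaped surface
  protrusions (CETP-like, ~8.5 nm), projected into noisy 2D measurement
  records the way negative-stain EM measures them, and the stereological
  **occlusion correction** that recovers true per-particle protrusion
  counts from projected counts: a radial rod of length *l* on a sphere of
  diameter *D* is visible in projection with probability

  ```
  P(D, l) = sqrt(1 − (D / (D + 2l))²)
  ```

  so observed count histograms are corrected by dividing each diameter bin
  by P.

* **Vesicle track** — coarse-grained POPC bilayer vesicles (13 beads per
  lipid: choline, phosphate, 2× glycerol, 9 tail beads; 65 Å² per lipid;
  36.8 Å bilayer; optional open pore covering 13% of the surface), an
  implicit-solvent relaxation engine that closes the pore and equilibrates
  the shell, and **Shrake–Rupley SASA** analysis of the hydrophobic surface
  fraction — the curvature-induced packing-defect signal that makes small,
  highly curved vesicles better binders of hydrophobic protein tips.
  Across relaxed vesicles of 12–42 nm the hydrophobic fraction falls from
  ~13% to ~7% and is linear in curvature (1/D, Pearson r ≈ 0.99).

## Worked example

```bash
python examples/visibility_model.py
```

```
D =  15.0 nm:  P closed form = 0.8833,  Monte Carlo = 0.8834 ± 0.0003
D =  40.0 nm:  P closed form = 0.7124,  Monte Carlo = 0.7120 ± 0.0005

observed mean count 2.00 at D = 15 nm  ->  corrected 2.264
(the correction divides by P, undoing the orientation-averaged masking)
```

On a 15-nm particle ~12% of surface rods point too close to the viewing
axis to be counted; dividing the observed mean by P(15, 8.5) = 0.883
recovers the true surface occupancy.  `examples/binding_recovery.py` runs
the full loop — generate 10⁴ particles with a diameter-dependent binding
law λ(D) = max(0, 8.4 − 0.2·D), project, bin at 2.17 nm, correct — and
prints corrected bin means that match λ to a few percent.

The vesicle track (`examples/vesicle_hydrophobicity.py`, a few minutes):

```
built: 694 lipids, 9022 beads (604 outer / 90 inner)
relaxed in 2500 steps: energy 923748 -> -85506
pore closed: True, RDF sphericity: 0.074
equilibrated diameter: 11.81 nm
hydrophobic surface fraction: 12.9 ± 0.3 %
```

The 13%-area pore of the initial model closes during relaxation while the
shell stays spherical at ~12 nm, and roughly an eighth of the
solvent-accessible surface is exposed hydrophobic tail area — packing
defects between head groups at this high curvature.
`examples/curvature_trend.py` regresses a relaxed five-vesicle series and
shows the fraction is linear in 1/D (r ≈ 0.99), not in D (|r| ≈ 0.87).

A thin CLI mirrors the library (`lipocurv simulate / measure / correct /
build / relax / sasa / trend / run`); `lipocurv run -c config.yaml`
executes a whole track from a YAML config with full seed provenance.

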