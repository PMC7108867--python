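# tissuemech

Coarse-grained 2D mechanics of a four-tissue embryonic trunk cross-section
(neural tube, left/right presomitic mesoderm, notochord over a rigid yolk
wall), plus the image-quantification toolkit used to analyze the matching
microscopy-style data.

## What it does

* **`tissuemech.model`** — pressurized mass-spring loops with piecewise
  inter-tissue forces (stiff repulsion below `R_rep`, linear adhesion up to
  `R_adh`), integrated with overdamped explicit Euler to steady state.
  The inner loop is JIT-compiled (numba) with a neighbor list; the force
  math is mirrored in plain numpy (`tissue_forces`, `interaction_force`)
  and cross-checked in tests.
* **`tissuemech.morphometrics`** — interfacial length and angle, bounding
  extents, areas and left/right asymmetry, circle-fit radii of curvature,
  detachment gaps, medial-lateral tension profiles.
* **`tissuemech.experiments`** — parameter sweeps (surface stiffness K_S,
  adhesion stiffness K_adh), the genotype panel (WT, cdh2, itga5, double
  mutant), and unilateral perturbations probing contralateral tension
  gradients.
* **`tissuemech.synth`** — seeded generators of microscopy-style inputs
  with ground truth: fibrous matrix images, photolabeled-spot time series
  with programmed anisotropic shrinkage and photobleaching, noisy circle
  arcs, dual-channel ratio pairs.
* **`tissuemech.imquant`** — Phansalkar local thresholding, min-fraction
  global thresholding, Feret-based size sorting (4/40 µm classes),
  medial-lateral distribution histograms, AP density profiles, spot
  width/height metrics, multi-pass block-matching displacement fields with
  rose histograms, the Newton-Pratt algebraic circle fit, ratiometric ML
  gradients, polygonal region means.
* **`tissuemech.cli` / `tissuemech.manifest`** — CLI subcommands and an
  end-to-end pipeline with a checksum manifest.

## CLI

```bash
tissuemech simulate --ks 100 --kadh 10 --out out/wt
tissuemech measure --state out/wt/state.csv --out out/wt_metrics.csv
tissuemech sweep --swept ks --grid 35,50,75,100,150,200 --out out/sweep.csv
tissuemech genotypes --out out/genotypes.csv
tissuemech perturb --mode left_adhesion --factor 0.5 --out out/perturb.csv
tissuemech synth matrix --seed 1 --out out/synth
tissuemech quantify matrix --image out/synth/matrix.tif --out out/matrix.csv
tissuemech run-all --seed 1 --out out/pipeline
```

Configuration files (YAML or JSON) can override model constants and the
canonical layout: `{"model": {"K_S": 55}, "layout": {"psm_center_x": 1.1}}`.

## Model units

All simulation quantities are dimensionless model units (rest length
l0 = 0.1, pressure P = 5, drag c = 10, time step dt = 0.001). Image
quantification uses the 8-bit intensity convention and a default pixel
scale of 17.4 px/µm.
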