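# Methods

## Scope and model

`gliamorph` quantifies microglial morphology from single-channel confocal
z-stacks and compares per-cell summaries across experimental groups. The
analysis assumes: one fluorescence channel in which both somata and
processes are labeled; somata distinctly brighter than processes; voxel
spacing known in μm (anisotropy is expected and handled); cells sparse
enough that a marker-controlled watershed can separate neighbors. All
physical quantities use the voxel-center convention: the coordinate of voxel
`i` along an axis is `(i + 0.5) · spacing`.

## Segmentation

The chain is: (optional) slice-wise CLAHE → global Li threshold →
open/close simplification → slice-wise Phansalkar soma detection → 3D
watershed → individual-cell filter.

* **Denoising.** An in-plane Gaussian (σ = 0.8 px) is applied before
  thresholding, but only when noise is detected (robust MAD estimate of the
  successive-difference sd); a clean synthetic stack therefore binarizes
  exactly. In-plane-only smoothing avoids destroying structures that are a
  single z-slice thick.
* **Li threshold with background floor.** Li's minimum-cross-entropy
  threshold is computed once per stack (a per-slice variant is
  config-switchable). When foreground occupies a tiny fraction of the stack
  (sparse single-cell fields), the global cross-entropy minimum lies
  *inside* the background mode — this is a property of the objective, not an
  implementation artifact (verified against a brute-force scan). The
  threshold is therefore floored at `median + 4·MAD·1.4826` of the stack.
  On well-populated images the Li value exceeds the floor and is used
  unchanged.
* **CLAHE default off.** Contrast-limited adaptive histogram equalization
  is implemented (slice-wise, kernel 127 px, clip 0.01) and tested, but
  disabled by default: on sparse fields with flat background it stretches
  background-only tiles to full range and destabilizes any global
  threshold. Enable it for real tissue with uneven illumination.
* **Mask simplification** uses slice-wise disk structuring elements, not 3D
  balls: with 0.3 × 0.3 × 1.0 μm voxels a 3D ball opening erodes every
  process that is one z-slice thick (i.e. most of them). Opening defaults
  to 0 px (the floored threshold leaves almost no speckle, and even a 1 px
  opening erases 2-px-wide distal processes); closing defaults to 1 px.
* **Phansalkar soma detection.** Slice-wise local threshold
  `t = m·(1 + p·e^(−q·m) + k·(s/R − 1))` with the published constants
  (k = 0.25, R = 0.5, p = 2, q = 10) and the radius as printed (20 px),
  computed with FFT box statistics over a disk. Intensities are normalized
  with the 1st percentile anchored to 0 (the formula assumes a dark
  background; an offset background otherwise lifts the whole field above
  its own local threshold). The threshold map is clamped at +1e-6 so FFT
  round-off (±1e-17) in empty regions cannot promote an exactly-zero
  background. The thresholded result is cleaned by a 2D opening (6 px) that
  removes thin processes, grouped into 3D components and gated by volume
  (55–1500 μm³).
* **Watershed** runs on the negated anisotropic Euclidean distance
  transform, seeded with the soma components, constrained to the mask.
  Somata outside the mask are rejected with a warning; unassigned mask
  components (fragments, spheroids) larger than 1 μm³ are attached to the
  nearest cell within 4 μm, which is what makes fragmentation measurable
  per cell.
* **Individual-cell filter.** Accepted cells have exactly one soma, volume
  in 150–20 000 μm³, and no contact with the x/y border (z faces are exempt
  by default — thin confocal stacks clip every cell in z).

## Skeletonization and graph building

Thinning uses 3D topology-preserving skeletonization on the voxel grid,
ignoring anisotropy (the classic plugins behave the same); lengths are
physical afterwards. Voxel classes follow the 26-neighborhood degree rule
(0 isolated / 1 endpoint / 2 slab / ≥3 junction). Graph construction:

* adjacent junction voxels merge into one junction node (centroid
  coordinate);
* all skeleton voxels inside the detected soma collapse into a single root
  node — a thinned soma blob otherwise degenerates into arbitrary short
  edges with no morphological meaning;
* edges are traced through slab runs; edge length is the sum of
  voxel-center steps under the anisotropic spacing (not endpoint-to-endpoint
  distance);
* cleanup removes thinning artifacts: terminal spurs shorter than 2 μm
  attached to junctions, junction–junction edges shorter than 1.5 μm
  (contracted), self-loops shorter than 3 μm, and pass-through degree-2
  junctions left behind by either step (their edges are spliced). Without
  this cleanup, noiseless-phantom segment recovery drops from ~93% to
  ~60–75% within ±1: μm-thick processes always thin with sub-resolution
  spurs and junction micro-loops. Pruning can be disabled in config.

The longest path is the weighted graph diameter (max over components),
computed by per-node Dijkstra; tests verify it against an independent
all-pairs networkx oracle. Watershed basins and tie-breaks are
deterministic, as is every other stage; two runs with the same seed produce
byte-identical CSVs.

## Sholl analysis

Spheres are true Euclidean spheres in μm about the soma centroid (radial
step 1 μm by default); intersections are transversal crossings of the
skeleton-edge polylines. Crossing counting drops vertices that lie exactly
on a sphere before counting sign changes, so passing through such a vertex
counts once and a tangential touch counts zero — without this rule an
axis-aligned polyline sampled at the step spacing yields zero crossings at
every integer radius. The per-cell AUC integrates the branch-count curve by
trapezoid from r = 0 (count defined 0) to one step past the last non-zero
radius. Per-class shell densities (slab/junction/endpoint counts divided by
shell volume) are secondary outputs; the branch-count curve carries the AUC
because that is the scale on which group differences are usually reported.

The phantom module provides an *independent* analytic oracle: exact
segment–sphere crossing counts from the ground-truth polylines, including
the chord-dip case (both piece endpoints outside the sphere, closest point
inside, two crossings). Pipeline profiles on ground-truth graphs match it
exactly (integer equality on 100 random trees in the acceptance suite).

## Classification

The visual activation/dystrophy criteria are operationalized as explicit
thresholds, all in config, calibrated to separate the phantom regimes and
to be re-tuned for real data:

| surrogate | rule | default |
|---|---|---|
| hypertrophy | soma volume > threshold | 200 μm³ |
| process shortening | longest path < threshold | 50 μm |
| activated | both of the above (strict inequalities) | — |
| fragmentation | > 1 mask component (≥ 3.5 μm³ each) | — |
| deramification | segment count < threshold | 8 |
| spheroids | ≥ 1 detached compact blob, 2.5–65 μm³, compactness ≥ 0.6 | — |
| dystrophic | at least one of the three | — |

Compactness is the ratio of the volume-equivalent sphere radius to the
component's maximal radial extent (1 for a sphere). Sub-threshold detached
slivers are ignored entirely: noise makes dim process tips flicker off the
mask, producing sub-4 μm³ fragments that are not dystrophy. Gnarling and
beading have no measurable surrogate here and are deliberately not
implemented. Field summaries report the percentage of activated cells per
field and per animal, warning when an animal has fewer than 4 fields.

## Group statistics

Cells are the statistical unit, pooled per condition (sample ids are
retained so animal-level aggregation remains possible). The omnibus test is
Kruskal–Wallis with mid-rank tie correction and χ² p-values regardless of n
(no small-sample exact tables). Pairwise comparisons are Dunn z statistics
on the pooled ranks with tie correction; two adjustments are provided
because practice varies: Holm–Šidák step-down (the default) and Dunn's
classical Bonferroni. Both are implemented in-package; Holm–Šidák is
cross-checked against statsmodels in the tests. The null calibration of the
omnibus test (type-I error 0.05 ± 0.01 at α = 0.05, 3 groups of 10, 10 000
simulations) is part of the acceptance suite.

## Phantom generator

Each phantom cell is a rooted tree grown by recursive bifurcation: a
segment of branch order *o* bifurcates with probability `p0·decay^(o−1)` up
to order 5; segment lengths are Gaussian with order-shrinking means; radii
taper per order from 1.1 μm; growth is damped out-of-plane (z factor 0.35)
to emulate thin tissue sections. Growth is *self-avoiding*: a branch that
cannot achieve ~3.5 μm of clearance is retried at another angle or dropped,
and the ground-truth tree splices out any degree-2 node this leaves behind.
Without self-avoidance, process–process contacts create mask cycles that
have no counterpart in the tree topology, making topology recovery
ill-posed rather than hard.

Regime constants were calibrated by tree-level Monte-Carlo (closed-form
expectation available in `expected_tip_count`) to per-cell magnitudes of
the kind reported for young/aged microglia before/after an inflammatory
challenge — realized mean tips 13.1 / 8.5 / 5.6 / 4.9 across
`young_naive / young_si / aged_naive / aged_si`, with SI regimes
hypertrophic (larger somata) and shortened, and aged regimes fragmented
(p = 0.3 per eligible distal segment, cutting a ~2.8 μm gap that leaves
both pieces resolvable) with cytoplasmic spheroids (0.6 per cell, radius
1.0–1.5 μm, placed clear of all processes). Mean analytic Sholl AUCs land
at ~160/83/44/40 branches·μm — same ordering and near-equal aged pair as
the published pattern, at ~75% of the printed scale: matching the absolute
values would need ~45 μm cells and roughly 4× larger stacks, and cell
extent (~35 μm) was chosen to keep per-field compute tractable.

Rasterization draws processes as capsules with per-point radii plus a
finely-resampled center line (guaranteeing 26-connectivity even where the
radius falls below the 1 μm z-spacing), somata and spheroids as flattened
ellipsoids (z factor 0.8). Default imaging model: voxels 0.3 × 0.3 × 1.0 μm
(typical confocal; the single-cell fields auto-fit the cell with a 4 μm
margin), Gaussian PSF σ = (0.5, 0.15, 0.15) μm, Poisson shot noise at 0.5
photons per intensity unit, Gaussian read noise with
SNR = (soma peak − background)/sd = 10, background 100, soma amplitude
250 above background, process amplitude 0.55 of soma. Ground-truth label
volumes are taken before blur and noise. Cohorts derive one child RNG per
(condition, cell) from the master seed via `numpy` `SeedSequence` spawn
keys, so any cell is reproducible in isolation.

What the phantoms do **not** emulate: structured tissue background and
autofluorescence, staining heterogeneity along processes, gnarling/beading
geometry, depth-dependent attenuation, overlapping cell territories, and
real PSF side lobes. Passing the recovery tests therefore shows the
algorithm chain is correct and well-calibrated on idealized but noisy
anisotropic data; it does not certify performance on real tissue, where
the classification thresholds in particular must be re-tuned.

## Problem sizes and runtimes

The test suite analyzes one shared 4-condition cohort of 20 cells per
condition at default SNR (~1–2 s per cell on one core), 100 noiseless
phantoms for topology recovery, 100 ground-truth trees for Sholl
equivalence, and 10 000 null simulations for the Kruskal–Wallis
calibration. `scripts/acceptance.py` re-runs the same study sizes from a
user seed. These sizes give stable pass/fail behavior for the ordering and
calibration properties while keeping a full run in minutes on one CPU.

## Known limitations

* Global thresholding of extremely sparse fields relies on the MAD floor;
  fields whose background is non-Gaussian (structured tissue) may need the
  CLAHE path and re-tuned gates.
* Recovered Sholl AUC underestimates the analytic ground truth by ~10% for
  ramified cells (blur and noise dim the thinnest distal branches), more
  for deramified cells whose AUC is small to begin with.
* The 20 px Phansalkar radius is kept in pixel units by design (its μm size
  depends on magnification); with very different pixel sizes it should be
  rescaled.
* Branch order, not diameter-based (Strahler) order, indexes taper and
  branching in the generator.
* SWC export represents multi-component (fragmented) cells as multiple
  roots in one file; cycle-closing edges, if a skeleton ever contains one,
  are broken at their far end because SWC cannot represent cycles.
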