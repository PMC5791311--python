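# gliamorph

Automated 3D morphometry of microglia from confocal z-stacks.

Microglia — the resident immune cells of the brain — signal their functional
state through shape: surveillant cells have small somata and long, highly
ramified processes; activated cells are hypertrophic with retracted
processes; senescent ("dystrophic") cells show deramification, cytoplasmic
fragmentation and spheroids. `gliamorph` turns a single-channel (Iba1-like)
fluorescence z-stack into per-cell numbers that capture these states, and
compares them across experimental groups.

## What the pipeline computes

For each field (a 3D grayscale TIFF with voxel spacing in μm):

1. **Segmentation** — optional slice-wise CLAHE contrast enhancement, a
   single Li minimum-cross-entropy threshold over the stack (guarded by a
   robust background floor for sparse fields), open/close mask
   simplification, slice-wise Phansalkar local thresholding (radius 20 px)
   to find bright compact cell bodies, and a marker-controlled 3D watershed
   over the negated Euclidean distance transform to split touching cells.
   Only *individual* cells — exactly one soma, not clipped by the field
   border, volume within bounds — are analyzed.
2. **Skeletonization** — 3D topology-preserving thinning of each cell;
   skeleton voxels are labeled by their 26-neighborhood degree as
   *endpoints* (1 neighbor), *slabs* (2) or *junctions* (≥3); junction
   clusters are merged and the soma is collapsed into a single root node,
   giving a spatial graph with physical edge lengths.
3. **Sholl analysis** — crossings of the skeleton with concentric Euclidean
   spheres at a 1 μm radial step about the soma centroid, plus
   slab/junction/endpoint densities per spherical shell. Each cell is
   summarized by the trapezoidal area under its branch-count curve
   (AUC, branches·μm), its maximal branch number, segment count and
   longest skeleton path (weighted graph diameter).
4. **Classification** — explicit numeric surrogates for the visual criteria:
   *activated* ⇔ soma volume above threshold **and** longest path below
   threshold; *dystrophic* ⇔ fragmentation (multiple mask components) or
   deramification (few segments) or cytoplasmic spheroids (detached compact
   blobs). Percentages of activated cells are reported per field and per
   animal.
5. **Group statistics** — cells pooled per condition, compared with a
   Kruskal–Wallis omnibus test
   `H = 12/(N(N+1)) · Σ nᵢ (R̄ᵢ − (N+1)/2)²` (mid-rank tie correction,
   χ² p-values), with Dunn z tests pairwise and Holm–Šidák step-down
   adjustment (Dunn/Bonferroni selectable). Summaries are mean ± SEM.

Because suitable public image sets with ground truth do not exist, the
package ships a first-class phantom generator: stochastic self-avoiding
branching trees (recursive bifurcation, order-dependent branching
probability, tapering radii) rasterized into anisotropic stacks with PSF
blur and mixed Poisson–Gaussian noise, in four calibrated regimes
(`young_naive`, `young_si`, `aged_naive`, `aged_si`) spanning ramified to
deramified/fragmented morphologies. Every phantom carries exact ground
truth: segment/tip counts, component counts, longest path and an analytic
Sholl profile computed by exact segment–sphere intersection.

## Worked example

```python
from gliamorph.phantoms import regime_spec
from gliamorph.pipeline import run_synthetic_cohort
from gliamorph.stats import compare_groups

specs = {c: regime_spec(c) for c in ["young_naive", "aged_naive"]}
pooled, truth = run_synthetic_cohort(specs, n_cells=6, master_seed=7)
print(pooled.groupby("condition")[["segment_count", "sholl_auc",
                                   "max_branches", "longest_path_um"]].mean())
comp = compare_groups(pooled, "sholl_auc")
print(f"Kruskal-Wallis H = {comp.h_statistic:.2f}, p = {comp.omnibus_p:.2g}")
```

prints

```
             segment_count  sholl_auc  max_branches  longest_path_um
condition
aged_naive             9.0       36.5           4.0             29.2
young_naive           19.5      122.2           7.0             77.0
Kruskal-Wallis H = 7.01, p = 0.0081
```

i.e. the pipeline recovers the planted contrast: ramified young-like cells
carry roughly twice the skeleton segments, three times the Sholl AUC and
much longer processes than deramified aged-like cells, and the pooled
nonparametric test separates the groups.

The same thing from the shell:

```bash
gliamorph simulate --out cohort --seed 7 --n-cells 6
gliamorph run cohort/manifest.csv --out results --posthoc holm_sidak
```

writes per-cell `morphometrics.csv`, the pooled table, `stats.csv` and a
JSON provenance record.

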