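# Methods

## Scope and model of the data

`amyquant` treats a stained brain section as a set of aligned single-channel
2D intensity rasters (X-34 amyloid, CD31 endothelium, GFAP astrocytes,
ICAM-1), each reducible to a boolean mask by thresholding. All biology is
then expressed as pixel-count ratios between masks inside a region-of-
interest polygon. This is deliberately faithful to the ImageJ-macro style of
analysis it re-implements: no intensity-weighted colocalization, no 3D
reasoning, no registration between sections. The assumptions that matter:

* masks of different channels are pixel-aligned (same acquisition grid);
* a pixel is "positive" for a marker iff its intensity reaches the channel
  threshold (inclusive `>=`: the chosen cutoff is the lowest positive level);
* overlap of structures in depth within a thick section projects into 2D
  overlap — association fractions are upper bounds in that sense.

## Segmentation

**Global thresholds** (X-34, GFAP, ICAM-1). One cutoff per channel, applied
to every section of that channel. When not supplied by the user it is
suggested from the pooled histogram of all sections. The default suggestion
method, `midpeak`, takes the midpoint between the background and foreground
histogram modes (the two-class split is seeded with the isodata threshold).
Rationale: on fluorescence histograms with a small foreground mass, Otsu's
criterion places the cutoff far below the half-height of the edge-intensity
profile (the foreground class mean is dragged down by partial-volume edge
pixels), which systematically widens thin structures such as astrocyte
processes; a mid-mode cutoff is unbiased for structures whose edge profile
is symmetric about half-height. `otsu`, `triangle` and `isodata` remain
available.

**Bernsen auto-local threshold** (CD31). For each pixel, the min/max over a
circular window (pixel-centre distance ≤ r, clipped at image borders) define
`mid = (lo + hi)/2`; pixels in windows with contrast `hi − lo < c` take a
configurable low-contrast assignment. Defaults r = 15 px and c = 15 grey
levels, the defaults of the ImageJ Auto Local Threshold plugin's Bernsen
implementation; low-contrast pixels default to background so empty
parenchyma cannot flood the vessel mask. The implementation uses ±∞-padded
min/max filters and is tested for exact equality against a per-pixel
brute-force oracle.

The pipeline pre-smooths CD31 with a Gaussian of σ = 1.2 px before Bernsen.
With the contrast floor at 15 grey levels, unsmoothed read noise (SD ≈ 8 on
8-bit data) spans more than 15 levels inside a radius-15 window, which would
defeat the low-contrast guard; σ = 1.2 brings the background noise range
inside a window below c while barely moving tube edges. Globally thresholded
channels are not pre-smoothed (their threshold margin is large, and
smoothing widens 3-px-wide processes).

## Mask algebra and metrics

Rasterization of ROI polygons uses pixel-centre containment (even-odd rule,
boundary centres inside), 0-based x-right/y-down coordinates. Metrics are
declarative numerator/denominator expressions over labelled masks,
intersected with the ROI; the built-in panel covers total %-area for all
four markers, vascular GFAP/ICAM-1, plaque-associated GFAP, parenchymal
ICAM-1 (exact pixel-count complement, so total = vascular + parenchymal
always), CAA area, and the two CAA↔vascular-GFAP association fractions.
"Associated with" is strict mask intersection; an optional reference
dilation (default 0 px) exists for sensitivity analyses only. Undefined
ratios (empty denominator) are recorded as NA, never 0, to avoid biasing
group means.

Per-animal aggregation defaults to the unweighted mean of per-section values
(NA dropped) — one point per mouse — with pooled pixel counts available via
config.

## CAA separation

Manually drawn vascular-amyloid masks are the faithful path: the manual mask
is intersected back onto the segmented X-34 mask (CAA ⊆ amyloid by
construction). The automated surrogate labels each 8-connected amyloid
component (≥ 20 px) vascular iff its overlap with the CD31 mask dilated by
2 px is ≥ 0.5, or its best-fit-ellipse axis ratio is ≥ 3 (elongated deposits
tracking a vessel). The two output masks partition the retained amyloid.
Components with a degenerate minor axis (1-px-wide lines) are treated as
infinitely elongated. CAA metrics are computed in the cortical ROI only by
default (vascular amyloid is a cortical phenomenon in this model); other
regions can be enabled. Automated masks are labelled as such in provenance.

## Vessel morphometry

The CD31 mask is thinned (Zhang topology-preserving skeletonization) and
converted to a graph: nodes are skeleton endpoints and junctions (mutually
adjacent junction pixels merged into one node), edges carry the ordered
pixel chain between nodes. Conventions, each chosen to make the analytic
phantoms exact and documented because a different tracing tool could choose
otherwise:

* spur branches with a free end shorter than `min_branch_px` (default 10 px)
  are pruned iteratively; a compact blob therefore contributes no edges;
* free chain ends are trimmed by the local distance-transform radius —
  thinning bends skeleton tips toward object corners, which would otherwise
  keep a straight tube from measuring tortuosity exactly 1;
* path length uses the chain metric (1 per axial step, √2 per diagonal);
* the local radius at a chain pixel is the 3×3 ridge maximum of the
  Euclidean distance transform minus 0.5 px (centre-to-edge correction); the
  ridge maximum compensates the skeleton sitting up to a pixel off the true
  centreline at oblique orientations. A solid bar of odd width w measures
  diameter w at 0°/90° exactly and within 1 px at 30°/45°;
* tortuosity = path length / chord length, floored at 1; closed loops are
  split at their farthest-point pair first so tortuosity stays finite;
* per-section summaries weight edges by path length by default (long
  segments dominate the biology); an unweighted option exists.

The chain metric overestimates the length of lines near 22.5°–30° by up to
~8–10%, which is visible in the 30° bar phantom (tortuosity ≈ 1.07–1.11);
circular arcs average this error away (semicircle within 0.2% of π/2).
Thinning is not exactly 90°-equivariant, so total skeleton length under a
90° rotation agrees to ~1%, not exactly; translation invariance is exact.

## Synthetic histology generator

The generator exists so every stage can be validated against known truth; it
emulates the *statistical structure* the analysis assumes, not photorealism.
Per 256×256 px section (1 µm/px) with default parameters:

* **vessels**: persistent-random-walk centrelines from the field borders
  (turn SD 0.10 rad/step, occasional branching), dilated by per-vessel radii
  of 2–3 px, added until the target area fraction (6%) is reached; an
  unreachable target raises an explicit error;
* **plaques**: 10 disks of radius 4–10 px whose centres are rejected within
  one radius of a vessel (parenchymal by construction);
* **CAA**: 3 annuli (inner radius r−2, outer r+2 around a vessel of radius
  r) along random vessel subchains of 15–40 px, placed in the cortical
  compartment; CAA ⊆ amyloid truth by construction;
* **astrocytes**: 60 soma-plus-radial-process stars; with probability 0.4 a
  soma is seeded on a vessel (±2 px), with probability 0.3 near a plaque;
  associated astrocytes are "reactive" (1.7× process length), giving the
  vascular/plaque-GFAP metrics tunable true effect sizes;
* **ICAM-1**: full endothelial signal on ~30% of vessels (at least one per
  section, so the vascular fraction is always defined) plus 8 small
  parenchymal blobs;
* **rendering**: each channel is `bias × (amplitude × blur(structure, 0.8) +
  background) + N(0, noise_sd)`, quantized to 8 bits; amplitude 180 over
  background 15 with noise SD 8 (SNR ≈ 20) and a unit-mean quadratic-
  polynomial bias field of ±8% — the regional staining variation that
  motivates local thresholding of CD31. A Poisson shot-noise component is
  optional and off by default.

Ground truth consists of the structure masks and the value of every built-in
metric evaluated on those masks (the stored true values are exactly
reproducible from the masks — a tested invariant). Cohorts derive all
per-animal/section seeds from one master seed; between-animal variability is
a lognormal multiplier (CV 0.15) on structure counts. For statistics-only
calibration at hundreds of replicates, `simulate_metric_table` draws
per-animal metric values directly from lognormal distributions with
configured group means (CV 0.35, a typical between-animal spread for
histological fractions) — group effects are then exactly the configured mean
ratios.

What the generator does **not** emulate: optics PSFs beyond Gaussian blur,
depth projection of a 40-µm section, staining artefacts (folds, edge
effects, autofluorescence), spatially correlated noise, and realistic
astrocyte/vessel morphological diversity. Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated image
model, not segmentation robustness on arbitrary real tissue — on real data
the global thresholds remain a per-channel scientific choice the user should
review (the pipeline logs them per run).

## Statistics

Two-way ANOVA with interaction on per-animal values: Type III sums of
squares under sum-to-zero contrasts, computed as the residual-SS increase
when one effect column is dropped from the full least-squares fit — the
behaviour of mainstream commercial packages on unbalanced designs (group
sizes in such studies routinely differ). F = MS_effect/MS_residual, 1 df per
effect in the 2×2 design; zero residual variance is flagged and p reported
as NaN rather than 0 or 1. The implementation is tested to 1e-10 against
statsmodels' Type III ANOVA as an independent reference.

Šidák pairwise comparisons use the pooled residual mean square and residual
df: `t = (m_i − m_j)/√(MS_res(1/n_i + 1/n_j))`, `p_adj = 1 − (1 − p)^m` with
m the family size, always reported. The default family is the four simple
effects (KO vs HEM within each amyloid-genotype level; transgenic vs WT
within each apoA-I level). Comparisons are emitted only when an omnibus
effect has p < 0.05 (configurable override), mirroring gated post-hoc
practice. All tests are two-sided at α = 0.05.

Mann-Whitney U counts `x > y` pairs plus half the ties. For n ≤ 16 the
two-sided p is exact by complete enumeration of all C(n, n_x) labelings
(valid with ties, where it is the exact permutation p); larger samples use
the normal approximation with tie and continuity corrections. The unpaired
t test is Student (pooled variance) by default with Welch-Satterthwaite
available. Test choice per metric is declared in config, as in practice
(amyloid endpoints: t or Mann-Whitney comparing the two transgenic groups).

Calibration of the whole chain is itself tested: on null cohorts the
omnibus type-I error at α = 0.05 falls within [0.03, 0.07] over 500
replicates and the p-values pass a Kolmogorov-Smirnov uniformity check; with
group means set to the reported cortical vascular-GFAP values
(0.21/0.30/1.80/3.86% of CD31 area) at n = 7 per group, the targeted Šidák
comparison is significant in well over half the replicates.

## Problem sizes and determinism

Validation runs use 256×256 px sections (20 sections for metric recovery, 20
seeds for classifier accuracy), 500 statistics-only replicates for null
calibration and 200 for power, and a 4-animal, 96×96 px cohort for the
end-to-end determinism check — sizes chosen so the full validation completes
in well under a minute on one CPU while keeping sampling error far below the
tolerances being checked. All randomness flows from explicit
`numpy.random.Generator` seeds (no global state); identical config + seed
reproduces every CSV byte for byte.

## Known limitations

* 2D only; association metrics inherit the depth-projection bias of the
  underlying workflow and cannot be corrected here.
* The automated CAA classifier is a formalized surrogate for a manual,
  morphology-based judgement; its thresholds (overlap ≥ 0.5 against CD31
  dilated 2 px, elongation ≥ 3, min component 20 px) are config-exposed and
  its output is flagged as automated. Manual masks remain the reference
  path.
* Vessel "diameter" and "tortuosity" follow the stated skeleton conventions;
  absolute agreement with proprietary tracing software is not a goal.
* Exact reproduction of any particular study's masks is impossible without
  its images and manually chosen thresholds; the package instead guarantees
  the measurement chain is correct under a known image model.
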