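# Methods

This note documents the models, parameters and numerical choices behind
`nengrade`, and what its synthetic-data experiments do and do not show.

## Problem setting

Neuroendocrine neoplasms are graded from proliferation: the mitotic count
(figures per 2 mm² of tumor at the hotspot, H&E stain) and the Ki-67 index
(percent positive nuclei at the hotspot, immunohistochemistry). Grades are
ordinal (G1/G2/G3) with the cut-offs <2 / 2–20 / >20 per 2 mm² and
<3% / 3–20% / >20%; boundary values 2, 20, 3% and 20% are read as G2
(the "2–20"/"3–20" ranges are inclusive). Discordant measures resolve to
the higher grade, and a patient with several slides receives the highest
slide grade. The package operates downstream of two deep components it
deliberately treats as pluggable inputs: a mitotic-figure object detector
(point detections with confidences) and tumor/tissue maskers.

## Ki-67 patch quantification

Patches are fixed, non-overlapping 1536×1536 px tiles at 0.2525 µm/px
(~0.39×0.39 mm). The chain is classical:

1. **Color deconvolution.** Optical density `OD = −log10(I/255)` per RGB
   channel is projected onto the inverse of a 3×3 unit-row stain matrix.
   The stain vectors are not measurable from a single patch, so the
   standard published Ruifrok–Johnston H-E-DAB values are the default,
   overridable in `Ki67Config`. Negative concentrations are clipped to 0.
2. **Otsu thresholding** of the hematoxylin and DAB concentration planes
   independently; foreground is the high-concentration side. Two
   degenerate-input rules: a constant plane yields an all-background mask,
   and the threshold is floored at `min_stain_od` (default 0.1 OD) so that
   a *stain-absent* plane — where Otsu would split pure sensor noise and
   mark ~half the pixels — also yields an empty mask. 0.1 OD is far below
   any real nuclear staining (~0.4–1.0 OD) and far above 8-bit quantization
   noise (~0.01 OD).
3. **Mask expansion** by morphological dilation with a Euclidean disk of
   radius 5 px, closing small holes and smoothing nucleus boundaries.
4. **Circle detection** with a circular Hough transform (scikit-image)
   applied to the mask boundary. Defaults: radii 8–24 px in steps of 2
   (nuclei of ~5–10 µm diameter, plus the 5 px dilation), minimum center
   distance 16 px, and an accumulator threshold of 0.3 on the normalized
   accumulator. These were calibrated once on synthetic fixtures of known
   geometry (planted disks are recovered exactly; full-chain counts on
   700-nucleus patches are within a few cells of truth) and frozen in
   `Ki67Config`; every parameter is exposed.
5. **Index.** `100 · |D circles| / |H circles|`, kept at full float
   precision; a patch qualifies only with ≥ 500 H-channel circles. The
   D-channel is counted independently of H (no cross-channel matching):
   positive nuclei carry hematoxylin too, so the H count is the
   all-cells denominator.

The Hough transform runs on the binary mask boundary rather than a Canny
edge map; on near-binary masks the two coincide, and the boundary is
cheaper and parameter-free.

## Density maps

Detections with confidence ≥ 0.5 (configurable; detector operating points
vary) are binned onto the 512-px patch grid with half-open cell intervals,
0-based, x = column. A square summing window of side
`round(sqrt(area)·1000 / (mpp·patch))` patches — 11 for 2 mm² at
0.2525 µm/px — slides at stride 1. The default border mode is centered
("same") with zero padding so maps keep the grid shape; "valid" is
available since border windows cover less than 2 mm² of tissue. Histogram
features are nearly invariant to this choice; the hotspot value is exactly
invariant. With a tumor mask, non-tumor cells contribute zero and are
reported missing (NaN); a grid cell counts as tumor when its pixel-mask
coverage is ≥ 50%. The hotspot is the maximum map value, ties broken
row-major (smallest row, then column) for determinism. Ki-67 density maps
hold the per-patch index of qualifying patches (window of 1), NaN
elsewhere.

## Histograms and classifiers

Slide features are normalized frequency histograms of the density-map
values: mitotic values are rounded half-up, clipped to 48 (well above the
G3 threshold of 20, so clipping never moves mass across a grade boundary)
into 49 unit bins; Ki-67 indices are rounded into 101 bins over 0–100.
Unit-width Ki-67 bins were chosen for symmetry with the mitotic histogram.
When a patient has several same-stain slides, their map values are pooled
*before* normalization (`pool_map_values`), so larger slides weigh more;
this is the package's reading of a slide-area-weighted patient summary.
Missing (non-tumor/unqualified) positions never enter a histogram, and an
all-missing slide is an error rather than a silent zero vector.

Classifiers over these features are a one-hidden-layer MLP (64 rectified
units, softmax output, Adam, learning rate 1e-3, ≤500 epochs, fixed seed)
or multinomial logistic regression. Class weighting is inverse class
frequency normalized to mean 1 — as explicit weights for the logistic
model, and as seeded oversampling to balanced class counts for the MLP
(whose scikit-learn implementation takes no class weights; oversampling is
the sampling-based equivalent in expectation). Evaluation uses
grade-stratified 3-fold cross-validation: per-grade seeded shuffle,
round-robin fold deal (per-fold grade counts within one patient of the
global mix), the held-out fold alternating test/val (~17% each), and the
reported metric is the mean over folds of balanced accuracy (unweighted
mean per-class recall) on the test halves.

Dual-stain combination strategies: *naïve 1* takes the max of the H&E
classifier grade and the WHO grade of the patient's Ki-67 hotspot
(maximum qualifying patch index — the clinical hotspot convention;
configurable to the mean); *naïve 2* the max of the two classifier
grades; the *concatenated* model trains one classifier on the 150-dim
[mitotic 49 | Ki-67 101] vector.

## Survival evaluation

Kaplan–Meier estimation, Greenwood/log-log 95% bands, log-rank tests and
Cox proportional-hazards fits are delegated to lifelines. Median survival
is the smallest time with S(t) ≤ 0.5 (NaN if never reached). Harrell's
c-index is implemented in-package: admissible pairs are those whose
shorter observed time is an event (for tied times, an event paired with a
censored observation counts as shorter; tied times with two events are
not orderable and are excluded); concordance means the shorter survivor
has the higher risk, risk ties credit 0.5. When a cohort is stratified by
grade, the grade itself (1 < 2 < 3) is the ordinal risk score. The test
suite checks this implementation against an O(n²) brute-force oracle and
against lifelines on tie-free data.

## Synthetic data

The generators are first-class, seeded (one `SeedSequence` fans out to
per-component streams; identical seeds give byte-identical artifacts) and
carry exact ground truth.

**IHC patches.** Nuclei are placed on a jittered grid guaranteeing a
minimum center separation (default 40 px — comfortably above the dilated
nucleus diameter, so masks never merge), radii uniform in 7–12 px, an
exact count `round(n·fraction)` positive. Rendering goes through
Beer–Lambert optics: per-nucleus stain concentrations (hematoxylin 0.9 OD
for negative nuclei; hematoxylin 0.5 + DAB 0.8 for positive, each with
±15% per-nucleus gain), a σ=1 px Gaussian blur as anti-aliasing, RGB =
background·10^(−OD), and additive Gaussian sensor noise (σ=1.5 of 255).
Defaults (700 nuclei per 1536-px patch, i.e. ≥ the 500-cell floor) match
the evaluation geometry. Not emulated: chromatin texture, overlapping or
non-circular nuclei, stromal DAB uptake, stain variability between
slides — so index-recovery results bound algorithmic error only, not
robustness to real-stain variation.

**Detection fields.** Per-patch Poisson counts at a background rate
(default 0.05/patch) raised to a hotspot rate (default 5/patch) within a
planted disk (radius 3 patches) on a 40×40 grid; points uniform within
their patch, confidences uniform in [0.5, 1]. The truth includes the
count grid and the exhaustive-scan maximum 11×11 window sum.

**Cohorts.** 300 patients by default with grade mix (0.59, 0.30, 0.11),
echoing the class imbalance of a resection cohort dominated by G1
disease. Grade-conditional models: mitotic hotspot-window means
(0.5, 8, 30) counts/2 mm² with background (0.002, 0.02, 0.08)/patch —
values placed centrally inside each WHO band; per-patch Ki-67 fractions
Beta-distributed with means (1.5%, 10%, 40%), concentration 60; survival
exponential with scales (8, 5, 1.5) years and 20% independent censoring,
reproducing the qualitative ordering of published NEN survival by grade.
An *overlapping* preset (means (1.5, 4, 10) with log-normal σ=0.6
patient-level rate heterogeneity, Ki-67 means (2%, 8%, 30%)) creates the
regime where single-stain grading is ambiguous and the Ki-67 channel adds
information. An optional degenerate regime draws hotspot counts from
disjoint per-grade integer ranges and implants them exactly, making WHO
hotspot grading correct by construction — the end-to-end identifiability
check.

## Problem sizes and tolerances

The shipped experiments use desk-scale sizes chosen to exercise every
code path at full default geometry: 50 patches × 600 nuclei for Ki-67
index recovery (mean absolute error ≤ 5 percentage points — the
recovery-suite bound; measured error is well under 1 pp), 100 seeded
fields for hotspot recovery, 50 random grids for the window-sum oracle,
300-patient cohorts and 10 seeds for classifier comparisons, 200 records
for the c-index oracle. Histogram normalization is checked to 1e-12;
survival values to pytest's default relative tolerance.

## Known limitations

- The Ki-67 chain counts circles, not segmented nuclei; heavily
  overlapping or elongated nuclei in real tissue will violate the
  circle model in ways the synthetic generator does not probe.
- Stain vectors are fixed per run; no per-slide stain estimation
  (e.g. Macenko) is performed.
- The detector operating point (score ≥ 0.5) is a configuration
  default, not a calibrated choice; density maps scale directly with it.
- Patch-level CNN predictions for the majority-voting baseline and MIL
  aggregation are out of scope; `majority_vote` consumes externally
  produced patch grades.
- WSI pyramid reading/tiling is out of scope; the package consumes
  patches, detection tables and masks.
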