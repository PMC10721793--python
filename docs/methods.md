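# Methods

This note documents the models and procedures fibroquant implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Trichrome fibrosis scoring

The fibrosis score of a Masson's-trichrome-stained lung section is the
fraction of the lung-tissue area occupied by collagen-positive (blue)
pixels. The pipeline assumes an 8-bit RGB image of a section on a bright,
achromatic slide background, with collagen stained blue, fibrin and vessel
walls red, and nuclei/tissue dark.

**Step 1 — background and walls.** Background pixels are those with
per-pixel coefficient of variation over (R, G, B) below `cov_threshold`
(default 0.05) and channel mean at or above `brightness_floor` (default
200): white is achromatic (CoV ≈ 0) and bright, whereas stained tissue is
chromatic or dark. A frame of `border_width` pixels (default 8) is filled
with the background mean to suppress scanner edge artifacts. The image is
then collapsed to grayscale by averaging the three channels, and
alveolar-wall tissue is segmented as pixels darker than a threshold
(Otsu's method by default, any fixed value via config), clamped strictly
below the background's grayscale mean so background can never be called
tissue.

**Step 2 — lung region.** The fragmented wall mask is dilated with a disk
of `lung_dilation_radius` (default 10 px, which must exceed half the
alveolar spacing to connect neighbouring septa), components smaller than
`min_contour_area` (default 0.1% of the image area) are discarded as
artifacts, the holes of the remaining components are filled, and the mask
is eroded with the same disk to cancel the dilation at the outline. On a
filled convex region the dilate/erode pair is an exact identity, which the
tests assert.

**Step 3 — fibrotic regions.** Fibrotic tissue has thickened, densely
packed walls where the sparse alveolar lattice is destroyed. Local wall
density is the mean of the wall mask over a `density_window` ×
`density_window` box (default 51, odd, zero padding at the image
boundary); pixels above `density_threshold` (default 0.35) are fibrotic.
The defaults assume a normal lattice density well below 0.35 and nearly
confluent walls inside lesions. The moving average is computed from an
integer summed-area table, so every value is exactly
(window sum) / window²; a naive double-loop computation reproduces it
bit for bit, which both the tests and the acceptance script verify.

**Step 4 — collagen vs fibrin unmixing.** Candidate pixels are the
intersection of the fibrotic mask with the wall mask. Their RGB triples
are mean-centred and decomposed by PCA (unscaled covariance). One
component carries the blue-vs-red stain transition; *which* one depends on
the image: on real slides the leading component is usually overall
brightness, pushing the stain contrast into the second or third component,
while on scenes whose variance is dominated by the stain itself it can be
the first. The package therefore selects, among the considered components
(`pca_components`, default {1, 2, 3}) whose eigenvalue is non-negligible
(relative tolerance 1e-10), the one whose loading w maximizes |w_B − w_R|,
breaking ties toward the lower index. Projections are multiplied by
sign(w_B − w_R) so that "more blue" always means "larger"; a zero sign is
treated as degenerate (empty mask, warning), as are fewer than 10
candidate pixels or a rank-0 covariance. The collagen mask is the
candidates whose signed projection exceeds a threshold (Otsu on the
projections by default; the threshold is applied to signed projections,
not absolute values). On noise-free two-colour scenes this procedure
reproduces the per-pixel B > R classification exactly, for any mixture
fraction and pixel order — the polarity-invariance tests exercise both.

**Step 5 — score.** |collagen ∩ lung| / |lung|, in [0, 1]. An empty lung
mask is an explicit error.

The module contains no randomness; identical inputs give bitwise
identical results. 16-bit inputs are linearly rescaled to [0, 255] with a
warning; alpha channels are dropped. Masks use row-major, 0-based pixel
indexing. Morphology uses disk structuring elements and 8-connectivity by
default (4 available); erosion treats out-of-frame pixels as foreground so
tissue touching the frame is not eaten.

## Immunofluorescence counting

Each channel is binarized (Otsu or fixed, per channel), closed with a disk
of `bridge_radius` (default 2 px) to reconnect intermittent fragments of
one cell, cleaned of components below `min_object_area` (default 30 px²),
and the surviving connected components are counted. Closing and removal
can only merge or delete components, so neither step ever increases the
count. Note that a true morphological closing bridges a narrow gap only
between *extended* fragments — a disk that fits through the gap past
isolated single pixels will not connect them; the dilate-then-erode pair
is exactly the closing, not a plain dilation. No DAPI gating or watershed
splitting is performed; ROI labels (normal vs disease area) are input
annotations, not computed.

## Single-cell computations

*QC*: a cell is kept when its detected-feature count lies in
[`min_features`, `max_features`] = [200, 5,000] **inclusive** and its
mitochondrial count fraction is at most `max_mito_fraction` = 0.05
(exactly 5% is kept; strictly above is removed as apoptotic). Zero-total
cells are removed with their own reason code, since the mito fraction is
undefined. Mitochondrial genes are identified by a configurable name
prefix (default `mt-`) or an explicit list. The filter is idempotent.

*Normalization*: value(g, c) = log1p(count(g, c) / total(c) × 10,000),
natural log. Scaling a cell's library leaves its values unchanged.

*Signature scores*: the per-cell arithmetic mean of the log-normalized
values over the genes of a marker set present in the matrix; absent genes
are reported, an entirely absent set is an error. Gene sets are inputs
(YAML); the package hard-codes none.

*Relative abundance*: within each compartment (e.g. Ptprc-positive,
Ptprc-negative, ILCs — an input column), frequencies of each cell type per
phase sum to one, and log2FC is taken against the intact phase. A type
absent from the reference phase has undefined log2FC (NaN) unless a
pseudocount is requested (off by default). Frequencies are computed over
the cells given, which after the usual workflow means QC-passing cells.

Clustering, embedding, label transfer and differential expression are out
of scope; cell-type, phase and compartment labels are inputs.

## Clinical formulas and the resampling test

`C_st = TV / (P_plateau − PEEP)` with PEEP defaulting to 2 cm H2O;
non-positive pressure gradients are rejected as non-physical. The ddCt
quantity is implemented exactly as
(Ct_ctrl(ref) − Ct_smp(ref)) − (Ct_ctrl(goi) − Ct_smp(goi)) with fold
change 2^ddCt; under this sign convention a sample expressing more target
than the control yields ddCt < 0 and a fold change below 1, which is the
mirror image of the common Livak 2^−ΔΔCt usage — `livak=True` provides the
latter. Collagen mass is normalized to lung wet weight (µg/mg).

The balanced resampling test compares a large group to a small one by
drawing, per repeat (default 3), a subset of the large group of the small
group's size without replacement (seeded) and running a two-tailed
unpaired t-test. "Student's" is read as the pooled-variance test; Welch is
available via config. All repeats are reported rather than a single
"representative" one. Under a simulated null the per-repeat rejection rate
at α = 0.05 is calibrated (checked over 1,000 runs at group sizes 27 and
10, the shape used in practice).

## Synthetic data: what it emulates, and what it does not

**Trichrome scenes** (default 512×512): an elliptical lung (semi-axes 0.70
and 0.72 of the half image) on a white background (245, 245, 245); a
sparse wall lattice (spacing 16 px, thickness 2 px, random phase) plus a
pleural boundary line, colour (150, 90, 130); a collagen patch rendered as
a twice-as-dense, thickened lattice (spacing 8, thickness 7, ≈ 98%
cover) in blue (70, 90, 185) — fibrotic walls are densely packed, not a
flat painted region, so the density logic of Step 3 is genuinely
exercised; up to two solid fibrin blobs (radius 12 px) in red
(200, 85, 95). Intra-lung air spaces are tinted pale lavender
(245, 210, 250): nearly as bright as the background but chromatic
(CoV ≈ 0.076), so they are not classified as slide background — emulating
the fact that alveolar air spaces sit above tissue, not bare glass. The
patch radius is solved by bisection so the collagen pixels hit the
requested lung fraction (within ±2% after rasterization; the reported
planted score is recomputed from the emitted masks and is exact by
construction). Gaussian pixel noise (sd 3) is added after all masks are
fixed. Fractions above 0.9 are rejected: a denser patch cannot fit inside
the lung. Not emulated: scanner optics, stain variability, tissue folds,
magnification/pixel size (the source slides' scale is unknown, so
geometry is parameterized), or anything photorealistic — passing tests
show the pipeline recovers planted fractions under the stated geometry
and noise, not that it handles every real-slide artifact.

**IF fields** (default 256×256, 4 channels): solid disks of radius 5 at
peak 200 on background 20 with noise sd 8, placed by dart throwing with
pairwise separation ≥ 30 px (bounded retries; infeasible packings raise).
Touching or overlapping cells are deliberately absent — the counting
pipeline does not split touching objects, and the generator's separation
constraint mirrors its operating assumption.

**Count matrices** (default 2,000 genes × 600 cells, 13 mito genes named
after the mouse mitochondrial protein genes): per-gene rates are
exponential draws scaled so a normal cell expects ≈ 3,000 counts and
≈ 1,250 detected features (inside the QC window); mito genes are rescaled
to a 1.5% expected share. Planted low-feature cells have the whole
library scaled by 0.05 (expected features ≈ 140 < 200); planted high-mito
cells have mito rates boosted to a 15% expected share; the generator
validates at construction that these expectations fall on the correct
side of the QC bounds. A signature-positive subpopulation (default 10% of
cells) has its signature genes (default the first 10 non-mito genes)
multiplied by `signature_fold` (default 4). The designated cluster is
planted at *exactly* round(freq × n) cells per phase in shuffled order —
the planted frequency is a study condition, not a random draw — so
abundance-recovery variability comes from whatever selection (e.g. QC)
happens downstream, not from the planting itself. Counts are Poisson;
over-dispersion, dropout beyond Poisson zeros, doublets and batch effects
are not modelled.

All generators derive every draw from a single integer seed through one
`numpy` Generator; identical parameters give bitwise-identical output.

## Problem sizes

The test suite and the acceptance script use 20 trichrome scenes at
512×512 for score recovery, 10 two-colour scenes for the unmixing oracle,
100 random masks up to 64×64 for the moving-average oracle, 100
four-channel IF stacks at 256×256, 50 random matrices for the QC oracle,
50 label replicates at 2,000 cells/phase for abundance recovery, and
1,000 runs for the t-test null calibration. These sizes give stable
estimates (binomial sd of the null rejection rate ≈ 0.004 at 3,000
repeat-level tests) while keeping a full run in the tens of seconds.

## Known limitations

* The spectral unmixing assumes exactly two stain classes among candidate
  pixels; mixed or intermediate hues are assigned to whichever side of
  the projection threshold they fall on.
* With no red-stained pixels among the candidates at all, Otsu's
  threshold will split the blue cluster itself; scenes with collagen
  present essentially always contain red/purple contamination at the
  patch boundary, which anchors the threshold, but a pure-blue candidate
  set is a degenerate input.
* The IF pipeline counts connected components, so touching cells merge
  into one object.
* The abundance table treats cells as independent; no uncertainty is
  attached to the log2FC point estimates.
* QC expectations in the count generator are validated in expectation;
  individual planted cells can fall on the wrong side of a bound with
  small probability (the tests allow 5% of planted cells to do so).
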