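# Methods

## Tissue representation

All geometry operates on a `ClassMap`: a 2-D uint8 raster with codes
0 = background, 1 = tumor, 2 = stroma, 255 = NODATA, plus isotropic
micrometers-per-pixel (`mpp`) metadata. "Background" covers everything a
pathologist would visually exclude when scoring TSR — necrosis, adipose
tissue, psammoma bodies, vessels — as well as glass; NODATA marks
unscanned or excluded area and never enters any tally. Coordinates are
0-based, row-major, pixel-centered; physical distances always convert
through `mpp` (typical full-resolution H&E scans are 0.25 µm/px at 40x;
patch classification is meant to run at the 20x level).

## Segmentation layer

Class maps may be supplied directly or produced by classifying overlapping
RGB patches. Patches default to 256 px with a 128 px stride (50% overlap);
origin grids are clamped so the last row/column abuts the image border,
guaranteeing full coverage with no out-of-bounds reads. Each patch maps to
a 3-vector of class probabilities through a pluggable callable; per-pixel
probabilities are the mean over all covering patches (probability
averaging, not hard-label voting, which yields smoother boundaries under
overlap), and the final label is the argmax with ties resolved to the
*lowest* class code. The tie rule is deliberate: ambiguous pixels fall to
background and are thereby excluded from the tumor/stroma ratio rather
than contaminating it.

No trained network ships with the package: the classifier slot accepts any
callable, and two references are provided — a deterministic palette
classifier for synthetic fixtures (nearest-palette-color pixel fractions,
so a pure-color tile gets a hard probability vector) and, implicitly, the
option to wrap any external model. The scientific content here is the
downstream geometry, not a particular set of CNN weights.

Majority-vote integer-factor downsampling (ties again to the lowest code)
provides the working resolution for region searches; the default working
resolution is 8 µm/px, configurable. Boundary error of block majority
voting scales with the perimeter-to-area ratio (verified on disk phantoms
in the tests).

## Most-invasive field of view

The MI region is the disk of radius 1.6 mm — the area of a 10x microscopy
field — maximizing tumor fraction n_tumor/(n_tumor+n_stroma) (background
excluded from the denominator). A field is admissible only if strictly
more than 2/3 of its in-bounds non-NODATA area is tumor-or-stroma tissue,
which rejects fields hanging off the tissue edge. Candidate centers lie on
a grid with spacing radius/16 (100 µm at default radius) — fine enough
that the discretization error is far below biological variability, and
configurable down to stride 1 for exhaustive search. Ties break toward
higher tissue fraction, then row-major order.

Disk tallies are computed by FFT convolution of 0/1 indicator rasters with
the rasterized disk and rounded back to integers; because the counts are
integers, rounding recovers them exactly and the optimized search is
bit-equivalent to brute-force per-center counting (asserted over 100
random maps in the tests). Border-clipped disks are normalized by their
in-bounds area, avoiding a zero-padding bias.

## Whole-tumor bed

Local tumor density at a pixel is the tumor fraction within a 500 µm disk;
the denominator counts all in-bounds non-NODATA pixels (background
included), so necrotic cores lower density smoothly and the bed stays
contiguous across them. A `tissue_only` switch restricts the denominator
to tumor+stroma for users who prefer it.

The bed is every pixel with density strictly above a size-dependent
threshold

    τ(A) = τ_base                                      A ≥ A_ref
    τ(A) = τ_base + (τ_max − τ_base)(1 − A/A_ref)      A < A_ref

with defaults τ_base = 0.15, τ_max = 0.50, A_ref = 50 mm². The piecewise
linear form is this package's choice: it is the simplest shape that is
monotone non-increasing in tumor area and pins both asymptotes, and it
reproduces the intended behavior that smaller tumors receive a higher
threshold and hence a smaller stroma margin. The constants are
configurable because the empirically tuned values used in pathology
practice are calibrated against reference annotations that differ between
labs. Eight-connected components smaller than 0.1 mm² are removed as
noise; an empty bed raises an explicit error rather than returning an
empty mask.

## TSR measurement and stratification

TSR = 100 · n_stroma/(n_stroma+n_tumor) inside a region of measurement;
background pixels inside the region are counted (reported as excluded) but
never enter the ratio. Stratification is stroma-rich at TSR ≥ 50% by
default. The optimal-cutoff search dichotomizes at every integer cutoff in
[5, 95], scores each split by the two-group log-rank chi-square on overall
survival, skips cutoffs leaving fewer than 5 patients on a side (a
degeneracy guard), and returns the argmax with the full grid attached —
deliberately without multiple-testing correction, mirroring its
exploratory use; callers can correct on the returned grid.

Manual scoring is modeled as tenfold percentages from two raters; on
discordance a third score is required and the median of the three is
returned. The median rule is a deterministic stand-in for a consensus
discussion and is labeled as such. Concordance between score series is
Pearson r plus ICC(2,1) — two-way random effects, absolute agreement,
single rater (computed via pingouin's ICC(A,1), the same estimand in
McGraw-Wong notation). Absolute agreement is the right flavor here because
a rater with a constant offset should not count as concordant; the result
object carries the flavor label so alternatives can be compared.

## Survival machinery

Times are months throughout; subjects without an event are right-censored,
and at tied times events precede censorings. Kaplan-Meier estimation,
the k-sample log-rank test and Cox proportional-hazards fits are backed by
lifelines; Cox uses the Efron tie approximation (the better default under
heavy ties at month resolution) and reports exp(coef) with Wald 95% CIs.
Model building follows the standard epidemiological recipe: univariable
screen at p < 0.10, then backward elimination dropping the largest-p
candidate while p ≥ 0.05 — with the exposure of interest forced into the
model at every step, so the adjusted exposure estimate is always reported.
The full selection trace is recorded. Ten-year overall-survival
probabilities are read off the KM curve at 120 months.

Categorical association testing computes expected counts and dispatches:
Pearson chi-square *without* continuity correction unless more than 20% of
expected counts fall below 5, in which case Fisher's exact test is used
(2×2 only; sparse r×c tables are refused with an explicit message rather
than silently approximated). The no-correction choice is required for
consistency with standard cohort-table practice on moderately sized 2×2
tables.

TIL counts arrive as ordinal bins 0..5 for {0, 1–5, 6–19, 20–49, 50–100,
>100} positive cells (highest count per tumor). Quartile categorization
computes the linear-interpolation 75th percentile of the codes and takes
its ceiling as the HIGH threshold, so a boundary falling inside a tied
value sends the whole tied mass up — reproducible and conservative for
group sizes. A 3-way scheme splits at the 25th/75th percentiles likewise.
All-equal input degenerates to all-LOW with a flag. The joint classifier
maps (stroma category, TIL level) to LOW (poor, high), HIGH (rich, low),
MEDIUM otherwise.

## Synthetic data

`generate_mask` paints organic tumor/stroma interdigitation by ranking a
Gaussian-smoothed noise field (plus Gaussian bumps at a chosen number of
tumor nests) and thresholding at exact pixel counts. The planted MI disk
at the raster center contains only tumor and stroma with the target stroma
count planted exactly; outside, background blobs cover their target
fraction and the tumor/stroma split is stratified over coarse tiles
(largest-remainder allocation) so local stroma fraction is homogeneous at
field-of-view scale — consequently the planted disk is the genuine
most-invasive hotspot whenever its tumor fraction exceeds the whole-tumor
one. The ground-truth record carries exact tallies, so TSR recovery can be
asserted to machine precision.

`generate_cohort` draws exponential overall survival with rate
ln(2)/median (default median 38 months, typical of advanced-stage disease)
multiplied by hr_stroma_rich^[rich] · hr_til_low^[TIL-low]; defaults are
340 patients, one-third stroma-rich, HR 1.6 and 1.5 — the magnitude of
crude TSR effects in published ovarian-cancer cohorts. The TIL-low
indicator derives from the CD8 bin against the theoretical top-quartile
threshold of the sampled bin distribution. Censoring selects exactly
round(f·n) patients and censors each at a uniform fraction of their event
time, hitting the target censoring fraction exactly; PFS is a Beta(2,2)
fraction of OS with its own event indicator (the real PFS/OS dependence is
unknown; the constant is documented here). A separate change-point
generator assigns uniform TSR on [5, 95] and doubles the hazard above a
known cutoff, for validating the cutoff search.

What the generators do *not* emulate: stain variability, scanner
artifacts, spatially realistic tumor architecture (papillary vs solid
growth), informative censoring, covariate-outcome confounding, or
correlated multi-marker TIL structure. Passing tests therefore demonstrate
algorithmic correctness — exact tallies, search optimality, estimator
calibration — not robustness to real histology.

## Problem sizes and numerical choices

Verification workloads use 128×128 working-resolution rasters (50 µm/px,
covering the full 1.6 mm field), 50-rep Cox recovery at n = 500, 20-seed
change-point recovery at n = 300, and 50-seed risk-group ordering at
n = 600 — sizes at which Monte-Carlo error is small relative to the
asserted tolerances while the full suite runs in well under a minute for
the imaging stages and a few tens of seconds for the statistics. Strict
inequalities follow the stated definitions ("more than 2/3", density
"higher than" τ); argmax ties everywhere resolve deterministically (lowest
code, first grid position). Degenerate inputs raise typed exceptions
rather than returning sentinel values, and batch drivers convert them into
recorded per-slide skip reasons.

## Known limitations

* No pyramidal WSI decoding (vendor formats), stain normalization, or GPU
  inference; inputs are plain rasters with JSON sidecars.
* One class map per patient: no multi-slide aggregation.
* The dynamic-threshold constants are package defaults, not a calibration
  against pathologist tumor-bed annotations; users with reference
  annotations should tune τ_base/τ_max/A_ref.
* Fisher's exact test is limited to 2×2 tables.
* The cutoff search reports an uncorrected maximum; treat its p-values as
  exploratory.
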