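# Methods

This note documents the models and procedures implemented in `ibexniche`,
the parameter defaults and why they were chosen, the assumptions of the
synthetic-data generator, and the numerical choices that matter for
reproducibility.

## Imaging preprocessing and segmentation

Each channel is restricted to its dynamic range by saturating the
brightest fraction of pixels (default 0.01%, `saturation_fraction=1e-4`):
the (1 − f) quantile maps to 255, the minimum to 0, and brighter pixels
clip; output is 8-bit. Autofluorescence and channel spillover that appears
as a shared additive background across channels is reduced by pairwise
channel arithmetic, `clamp(target − scale·reference, 0)`; the pairs and
scales are data-dependent and live entirely in the configuration, since no
universal setting exists.

Nuclei are segmented from the nuclear stain by thresholding (Otsu by
default, manual override available), a Euclidean distance transform
lightly smoothed (σ = 1 px) to stabilize plateau maxima, watershed seeded
from distance maxima with a minimum seed separation (default 8 px), and a
size filter (default 10 μm²) to drop debris. "Smoothing radius 4 px" for
membrane markers is interpreted as a Gaussian with σ = 4 px (configurable);
the filter exists to pull membrane staining over the nuclear mask, so MFIs
are measured over the nuclear label region only, for membrane markers after
smoothing and for nuclear markers (GFP-like) on the raw channel. Centroids
convert to micrometers via the pixel size (default 0.284 μm/px, written to
and read from OME-TIFF metadata). Stacks are assumed pre-aligned;
multi-cycle registration is out of scope.

## Phenotype classification

**Stage 1 — thresholds and profile matching.** For each marker, cells are
split into +/− at an automatic "elbow" of the sorted expression curve. The
elbow is located kneedle-style — the point of maximum perpendicular
distance from the chord joining the curve's endpoints — computed on the
log scale, because fluorescence intensities are right-skewed: on the raw
scale, whenever positives are common the log-normal upper tail (not the
negative/positive boundary) is the farthest point from the chord. The
chord picks the neighborhood of the boundary; within a window of ±10% of n
around it, the widest gap between consecutive log values centers the
threshold in the negative/positive valley. The construction is exactly
scale-equivariant (rescaling a marker rescales its threshold), and a
manual per-marker override is honored. Thresholds are pooled across
samples by default; per-sample thresholding is possible by calling
`compute_thresholds` per group, but pooling is the default because it uses
the full curve and the shipped generator has no per-sample intensity
shifts.

Cells whose binary profile agrees with exactly one panel profile on every
non-`any` marker are assigned; cells matching zero or ≥ 2 profiles stay
uncategorized (ties are not force-assigned). Per-type mean MFI vectors
over matched cells become the representative quantitative profiles; a type
needs ≥ 20 matched cells (configurable) to enter the regression
dictionary, which prevents degenerate means.

**Stage 2 — regression mixture.** Each uncategorized cell's MFI vector
(one observation per marker) is regressed on the matrix of representative
profiles (one column per type) by ordinary least squares without an
intercept — the cell is modeled as a non-negative mixture of known types.
Contributors with a two-sided t-test p < α (default 0.05) and a positive
coefficient are "significant"; the largest significant coefficient assigns
the type. No significant contributor → `excluded_unmatched`. The design
requires at least as many markers as dictionary types and full column
rank; collinear profiles raise an error naming the offending pair.

**Stage 3 — triage, report-only.** Excluded cells are k-means clustered on
standardized MFIs (seeded). Clusters whose top standardized marker exceeds
the runner-up by a dominance ratio (default 2) are flagged as
single-marker noise. The triage never reassigns cells: excluded cells stay
excluded. Finally, types on the panel's exclusion list (the shipped panel
excludes γδ T cells, whose channel is compromised by myeloid spillover)
are dropped from all downstream analysis.

## Lesion calling

Within each sample, tumor cells are nodes of a graph with an edge when
their 2D Euclidean centroid distance is ≤ 200 μm — the boundary is
inclusive exactly as stated, so a pair at exactly 200 μm is one lesion.
Connected components define lesions; the KD-tree pair query is exact, so
the partition equals the all-pairs definition (tested against a union-find
oracle). Lesions are numbered by their smallest member cell id, making
output independent of row order. Every phenotyped non-tumor cell within
200 μm of any member tumor cell joins that lesion; multiplicity is
preserved (a cell between two lesions counts once in each), and no
renormalization is applied. Lesions of 1–8 tumor cells are dormant, > 8
proliferative. Summaries report both pooled per-genotype means and the
mean of per-sample means, since the two differ when samples are unbalanced.

## Niche analysis

Per-lesion immune counts are compositional, so each lesion's counts x are
re-expressed as centered log-ratios, CLR_i = ln(x_i + c) − mean_j ln(x_j + c),
with pseudocount c = 1 by default (zero counts are common in small lesions
and CLR(0) is undefined; c is configurable and c = 0 demands all-positive
counts). CLR rows sum to zero by construction. Each cell type's CLR is
then standardized across lesions (ddof = 1); zero-variance columns become
zeros with a warning. CLR is deliberately not sub-compositionally
coherent — removing a type changes the remaining values — and a test
documents this as expected behavior.

Co-occurrence modules come from Pearson correlations across lesions,
average-linkage hierarchical clustering on distance 1 − r, and a cut to a
fixed number of modules (default 2, matching the two-niche structure this
analysis targets). PCA is computed by SVD of the column-centered
standardized matrix; each component's sign is fixed so its largest-|loading|
type loads positively, making scores reproducible across platforms.

## Regression models

All models code genotype with the control arm as reference. Three
treatments of the sample (mouse) grouping are available:

* `random_intercept` — a per-sample Gaussian random intercept. For the
  logistic tumor-fraction model the marginal likelihood is maximized with
  the per-cluster integral evaluated by adaptive Gauss–Hermite quadrature
  (default 25 nodes; the cluster mode is found by Newton steps and the
  quadrature is recentered and rescaled there). For the Gaussian PC1 model
  the random-intercept ML has a closed-form profile over the variance
  ratio and is solved by 1-D optimization; it is exactly well-behaved at
  the zero-variance boundary, where it collapses to OLS.
* `fixed_sample` — sample as a fixed covariate. Samples are nested in
  genotype, so dummies are added only while they increase the design rank
  (one reference sample per genotype keeps genotype identified). Note the
  statistical consequence: with a saturated nested design the genotype
  contrast is informed by the reference samples, so this mode is
  conservative for genotype inference.
* `cluster_robust` — pooled fit with a sample-clustered sandwich
  covariance. With few clusters (6 mice) these SEs are themselves noisy;
  the mode exists for sensitivity analysis.

**Tumor fraction.** Logistic regression of each cell's tumor indicator on
genotype; default grouping `random_intercept`. Complete separation raises
an error naming the degenerate arm.

**Lesion size.** Sizes are ≥ 1 by construction, so the model is a
zero-truncated NB2: log NB(y; μ, θ) − log(1 − (θ/(θ+μ))^θ) with log link
μ = exp(xβ) and variance μ + μ²/θ. The likelihood is implemented directly
in log-gamma/expm1 form (stable for small and large μ) and maximized by
L-BFGS over (β, log θ) from 5 seeded starts (gradient tolerance 1e-8);
standard errors come from the inverse observed information (numerical
Hessian). The documented default grouping is `fixed_sample` — an exact,
self-contained likelihood rather than an integrated random effect, which
for this model is available only through the other modes' approximations.
The implementation reproduces glmmTMB's `truncated_nbinom2` fit on a fixed
dataset to ~4 decimal places (frozen in the test suite).

**Niche PC1.** Gaussian model PC1 ~ size + genotype + size:genotype with
default grouping `random_intercept`. Size enters as the logged count by
default (sizes span 1 to >100; `size_scale="raw"` is available) and the
size covariate is centered, so the genotype main effect is evaluated at
the typical lesion size rather than extrapolated to a one-cell lesion —
without centering the main effect and interaction are nearly collinear
and genotype inference loses most of its power. The centering constant is
recorded in the fit metadata.

## Synthetic-data generator

The generator emulates the study design stage by stage:

* **Design**: 3 samples per genotype, 30 lesions per sample, a
  5 × 5 mm field per sample, 2,000 background immune cells per sample.
* **Lesion sizes** are zero-truncated NB2 with dispersion θ = 2 and
  genotype-specific *observed* means 16.8 (control) and 3.8 (knockout) —
  the generator solves the underlying NB mean whose truncated mean equals
  the requested value, so empirical means match the configured numbers
  directly. `ztnb_rvs` (underlying-mean parameterization) is exposed for
  model-recovery studies.
* **Geometry**: lesion centers are placed by rejection sampling with a
  minimum separation of 600 μm (3 × the 200 μm linking radius), so true
  lesions can never merge and ground-truth labels stay identifiable; a
  field too small for the requested placement raises a sizing error.
  Tumor cells scatter around their center with σ = 25 μm, which keeps
  every true lesion internally connected at 200 μm with overwhelming
  probability. Lesion-associated immune cells are uniform in an annulus
  (0.2–1.0 × 150 μm) around the center — inside the 200 μm capture radius
  — with type frequencies drawn from the lesion's niche profile;
  background cells are uniform over the field with a mostly-myeloid
  composition including a 0.5% γδ T trace.
* **Niches**: two profiles over nine immune types — niche 1 rich in
  CD4/CD8 T cells, macrophages and cDC2s; niche 2 rich in CD103⁺ cDCs,
  NK, NKT and monocytes/neutrophils. The assignment rule ties niche 2 to
  dormant size and knockout genotype (P(niche 2) = 0.55/0.05 for
  control dormant/proliferative, 0.95/0.50 for knockout). The paper-scale
  effect directions are design points: both ties are strong enough that a
  150-lesion study detects them reliably, which is what the acceptance
  checks verify.
* **Intensities**: each marker is log-normal, (ln 500, 0.35) when the
  cell's true type is positive for it and (ln 20, 0.35) otherwise —
  positive support and right skew are the minimal realism fluorescence
  requires; all parameters are per-marker configurable. An optional
  spillover term adds one shared log-normal background to both channels of
  a configured pair, to exercise the channel-subtraction step.
* **Rasterization** renders one disk per cell (radius from nucleus area)
  into a nuclear channel and MFI-scaled disks into marker channels, with a
  1 px Gaussian blur, for imaging round-trip tests.

What the generator does **not** emulate: nuclear morphology beyond disks,
optical PSFs, per-sample staining batch effects, cell-density gradients,
3D structure, and real marker co-expression noise (markers are
conditionally independent given the true type). Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
assumptions, not robustness to every artifact of real tissue imaging.

## Determinism and problem sizes

All randomness flows from a root seed fanned out per stage via
`SeedSequence([root, crc32(stage)])`; cell tables are written with floats
rounded to 9 significant digits so re-runs are byte-identical. The shipped
checks use: 50 random fields (≤ 2,000 cells) for the lesion oracle, the
default 28k-cell study for phenotype recovery, 2,000 draws for ZTNB
parameter recovery, 500 simulated studies for logistic CI coverage, 200
replicates at the 16.8-vs-3.8 design point for power, 1,000 label
permutations for type-I calibration, and 100 seeded 150-lesion datasets
for niche recovery — sizes chosen to give stable Monte-Carlo estimates of
each rate while keeping a full run to a few minutes on one CPU.

## Known limitations

* The random-intercept ZTNB (the full GLMM) is not implemented; grouping
  for the size model is by fixed effects or cluster-robust SEs. With no
  true sample-level variance this is exact; with strong sample effects the
  fixed-sample genotype contrast is conservative.
* Stage-2 significance uses classical t-tests with few residual degrees of
  freedom (markers − types); with small panels the regression rescue is
  intentionally strict, and its α is configurable.
* The elbow threshold assumes an (approximately) bimodal marker
  distribution; markers with no positive population in the field will
  still receive a threshold, and manual overrides are the intended remedy.
* CLR results depend on the pseudocount when many counts are zero; the
  default (1) is conventional but not canonical, and is recorded in
  output metadata.
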