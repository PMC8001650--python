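# Methods

This note documents the models, conventions and numerical choices behind
`petihc`, and what its synthetic ground truth does and does not establish.

## SUV quantification

SUV is computed per voxel as `C / (dose / weight)` with C in kBq/mL, dose in
kBq and weight in grams; under the standard 1 mL ≡ 1 g tissue assumption the
result is dimensionless. Decay correction of the dose
(`dose · 2^(−t/T½)`) is available but **off by default**: the plain formula
is the definition, and whether a study's scanner software already
decay-corrected is an acquisition property the caller must assert. ROI masks
are voxel-aligned boolean grids in the image's own 0-based index space; no
partial-volume weighting is applied. The ROI SD is the population SD
(a single-voxel ROI has SD 0). Frequency histograms cover [0, max] in
uniform bins (default width 0.1 SUV, configurable); the last bin is
right-closed so the maximum is always counted, and bin counts always sum to
the ROI voxel count. Caliper volume is the two-diameter ellipsoid formula
`(π/6)·transverse²·longitudinal`.

## IHC positivity pipeline

"Optimal thresholding" of tissue against white slide background is Otsu's
global threshold on grayscale luminance — the standard optimal global
threshold for a bimodal histogram; pixels darker than the threshold are
tissue. Colour clustering is k-means (k = 6 by default) in RGB with
k-means++ initialization and 10 restarts. The fit runs on the sorted unique
tissue colours weighted by multiplicity, which leaves the objective
identical to per-pixel fitting but makes the labelling deterministic for a
given seed and exactly invariant to pixel order — hence to rotations and
flips of the section.

"Positive" is defined by an HSV gate around a DAB-brown reference colour
(default RGB (130, 80, 50), hue ≈ 22.5°): a cluster is selected when its
mean colour lies within ±20° of the reference hue with saturation ≥ 0.15,
and the same test is then applied per pixel inside the selected clusters.
Hue is nearly invariant to staining intensity and illumination, which is
what separates DAB from the hematoxylin counterstain (hue ≈ 240°) robustly.
Noise removal drops 8-connected components smaller than 25 px. These colour
and size defaults are declared choices, not inferred from any particular
instrument; per-marker overrides go through `StainProfile`.

## Statistical suite

All tests are two-sided; p < 0.05 is the conventional significance level,
and no multiple-testing correction is applied beyond Tukey HSD after ANOVA.

* **Spearman**: Pearson correlation of mid-ranks; p from the
  t-approximation.
* **Kendall**: tau-b (tie-corrected). For n ≤ 10 without ties the two-sided
  p is exact: tau is a deterministic function of the inversion count, whose
  null distribution over all n! permutations (the Mahonian distribution) is
  built by polynomial convolution. With ties, an exact request falls back to
  seeded permutation resampling; otherwise the normal approximation is used.
* **Kolmogorov–Smirnov**: D is the supremum ECDF distance computed from the
  pooled order statistics. The default p evaluates the finite-sample KS
  distribution at the effective size n₁n₂/(n₁+n₂). The classic limiting
  form Q_KS(√en·D) was rejected as the default because at the small equal
  sample sizes used for calibration checks it is far too conservative
  (attained size ≈ 0.013 at n₁ = n₂ = 10 and α = 0.05); the finite-n form
  attains ≈ 0.051 there. A seeded permutation mode exists for verification;
  note that at n₁ = n₂ = 10 the *exact* conditional test is itself
  conservative (attained size ≈ 0.013) because D has granularity 1/10 —
  this is discreteness, not an implementation artifact, and no faithful
  permutation p can be better calibrated at that n.
* **ANOVA**: one-way F from the usual SS partition with Tukey HSD adjusted
  p from the studentized-range distribution (df = N − k). The mixed
  (between × repeated-measures) ANOVA uses the standard two-way mixed SS
  partition with **no sphericity correction** — a documented limitation,
  acceptable at two or three within levels. The design must be balanced;
  missing (subject, level) cells are named in the error. With zero variance
  everywhere the mixed-ANOVA F ratios are reported as NaN (0/0) rather
  than 0. Post hoc for the mixed design is Tukey across between-groups at
  each within level.
* **Power of a correlation test**: the exact method integrates the exact
  bivariate-normal sampling density of r (a Gauss hypergeometric form,
  evaluated in log space) over the rejection region |r| > r_crit, where
  r_crit is the null critical value from the t transform with n − 2 df;
  the smallest n reaching the target power is found by doubling plus
  bisection (power is monotone in n). A Fisher-z mode
  (arctanh(r) ≈ N(arctanh ρ, 1/(n−3))) is provided and labelled
  approximate; it agrees with the exact n within 1 over the relevant
  effect-size range. For |ρ| = 0.3333 and 0.4286 at α = 0.05 and 80% power
  the exact method gives n = 68 and 40.

## Cohort conventions

* The HER2 high/low threshold is the pooled mean of per-tumour HER2-tracer
  SUV_mean over all subjects (a fixed override is accepted); ties go to
  "high" (≥). Pooled was chosen over mean-of-cohort-means because neither
  is exactly recoverable from rounded cohort summaries, and pooled is the
  simpler estimand.
* Percent change is `(to − from)/from × 100`; the response analysis pairs
  days 3 → 6 by default, the baseline comparison uses day 0.
* Correlations across cohorts are Spearman; within a single cohort Kendall's
  tau is dispatched (group sizes of 7–9).
* Subjects missing either member of a pairwise analysis are excluded
  pairwise-complete, with the exclusion count logged.
* The glucose-stratified comparison splits at baseline FDG SUV_mean 0.15
  (ties high) and compares day-0→6 percent change by unpaired t.

## Synthetic world

* **Tumour-level SUV**: truncated-at-zero normals at the three cohorts'
  stated means/SDs (4.9 ± 1.5, 1.4 ± 0.2, 1.1 ± 0.4; n = 9/7/7). Truncation
  bias is negligible at these parameterizations (< 0.004 SUV).
* **Voxel law**: gamma at the tumour mean, parameterized by an intra-tumour
  CV (defaults 0.35/0.15/0.20 — the high-HER2 cohort gets the broadest
  within-tumour spread, mirroring its wider SUV histogram; true voxel
  distributions were never published, so these are declared assumptions).
  Phantoms are 32³ grids at 0.5 mm with a 3×3×4 mm ellipsoid tumour
  (~1200 ROI voxels) over a SUV-0.1 background; activity is stored as
  `SUV·dose/weight` so SUV conversion round-trips to floating-point
  accuracy.
* **Longitudinal link**: a Gaussian copula on the normal scores of the
  realized HER2 ranks injects the target Spearman correlations (Gaussian
  correlation 2·sin(πρ/6)) into the FDG baseline (uniform margin over
  0.05–0.35 SUV) and the day-3→6 percent change (normal margin, SD 35
  points, floored at −90%). Day 3 adds independent drift of the same SD.
  The conditional-independence construction keeps any pair of |ρ| < 1
  targets jointly feasible. Default targets −0.69 (baseline) and −0.59
  (response) are the study-scale effect sizes.
* **IHC sections**: white background (grey level 245), hematoxylin-coloured
  tissue ellipse, DAB blobs (radius 5–14 px) grown until the positive count
  reaches `round(f·tissue)`, the last blob trimmed outside-in so the
  ground-truth count is exact; per-pixel colour jitter SD 8 grey levels.

What a green test establishes: the quantification and statistics recover
the generating parameters of *this* world — separable stain colours, sharp
tissue boundary, no partial-volume blur, no scanner noise model, gamma
voxel textures, monotone copula dependence. It does not establish
performance on real scanner reconstructions (PSF, scatter, registration
error), real slides (stain deconvolution overlap, nuclei, artefacts,
pyramidal formats) or non-monotone dependencies; those are out of scope by
design.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng` (PCG64); a seed
fixes every generated artifact bit-for-bit. k-means clustering determinism
is guaranteed by the unique-colour weighting described above. Power
integration uses adaptive quadrature on the log-density; exact Kendall
null distributions are cached per n. Degenerate inputs (blank slide, empty
ROI, constant correlation input, all-zero-variance ANOVA, unbalanced mixed
design, unreachable power target) raise typed, named errors rather than
returning NaN silently, except where a NaN is the honest answer (0/0 F
ratios).

## Known limitations

* Mixed ANOVA has no sphericity (Greenhouse–Geisser) correction.
* The KS permutation mode is honest but conservative at very small n
  (discreteness of D); use the default finite-n p for calibrated decisions.
* The IHC pipeline assumes two dominant stain families separable in hue; it
  is not a stain-deconvolution method and does not count nuclei.
* Caliper volume assumes the standard prolate-ellipsoid approximation.
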