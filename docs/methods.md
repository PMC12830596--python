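# Methods

This note documents the statistical model behind `mitovar`, the synthetic
cohort generator's assumptions and defaults, and the numerical choices made
in the implementation. All quantities reported by the package are computed
from simulated data with known ground truth; nothing here is an empirical
claim about patient tissue.

## 1. Single-fibre classification

### 1.1 Frequentist prediction-interval classifier

Control fibres provide pairs (VDAC1, OXPHOS marker). An OLS fit of marker
on VDAC1 with residual SD `s`, control count `n`, mean `x̄` and centred sum
of squares `Sxx` defines the two-sided 95% prediction band

```
ŷ(x) ± t(0.975, n−2) · s · sqrt(1 + 1/n + (x − x̄)² / Sxx)
```

which by construction contains a fresh draw from the control population
with 95% probability (verified by simulation in the test suite). The
classifier fits this band on each of `n_models` bootstrap resamples of the
controls (default 10,000), labels each patient fibre −1/0/+1 per model, and
averages the labels into a certainty score in [−1, +1]. Final calls use a
non-strict ±0.95 rule: deficient iff mean label ≤ −0.95, overabundant iff
≥ +0.95, otherwise normal. When both patient and control tables carry a
`batch` column, regressions are fitted per batch so fibres are only judged
against controls stained alongside them. Sections with fewer than 100
fibres trigger a warning because their proportion estimates are unstable.

Numerics: the bootstrap uses a vectorised closed-form OLS on resample sums,
evaluated in chunks of 500 models to bound memory; resamples with a
degenerate predictor (all VDAC1 equal) are redrawn, capped at 100 attempts.

### 1.2 2D-mitoplot polygon consensus

Investigator annotations are polygons on the (VDAC1, marker) plane with a
category (`deficient` below the control cloud, `overabundant` above).
Membership uses boundary-inclusive even-odd point-in-polygon tests
(`shapely.covers`), giving each fibre a per-investigator label in
{−1, 0, +1}; a fibre inside both a deficient and an overabundant polygon of
the same investigator is a contradiction and raises an error. Consensus
certainty bootstraps investigators with replacement (`n_resamples`, default
10,000) and averages the drawn labels. Because each resample's mean label
is a draw-count-weighted mean of the fixed per-investigator labels, the
implementation computes the weighted mean from multinomial draw counts
directly — mathematically identical to materialising the resampled label
matrix, and much cheaper. The same ±0.95 call rule applies.

## 2. Benchmarking

Per-section, predicted calls are compared with ground-truth labels:

- **Cohen's kappa** between prediction and truth (and Fleiss' kappa for
  multi-rater agreement), implemented in closed form and verified in tests
  against scikit-learn and statsmodels. When both vectors are constant and
  identical, observed and expected agreement are both 1 and kappa is
  undefined; the package reports 1.0 for that case but flags the section
  `kappa_degenerate`, and the pipeline excludes flagged sections from
  weighted averages so perfect-by-vacuity sections do not inflate summary
  agreement.
- **Binary confusion metrics** (deficient vs not-deficient): FPR, FNR, PPV,
  sensitivity, F1. Ratios with zero denominators are reported as absent
  (`None`) rather than 0, and excluded from aggregation with a count.
- **Weighted bootstrap summaries**: section-level statistics are combined
  into a fibre-count-weighted mean with a 95% percentile CI from resampling
  sections with replacement (default 10,000 replicates).

Benchmarking defaults to the annotated ground-truth subregion of each
section (mimicking the fact that exhaustive expert labels are only
affordable on a small region) but can evaluate all fibres.

## 3. Variability engine

Per section, the deficient-fibre proportion p̂ = k/n is given a bootstrap
distribution. Resampling n fibres with replacement and recomputing the
proportion is distributionally identical to drawing Binomial(n, p̂)/n, so
the implementation samples the binomial directly; this is an exact
equivalence, not an approximation.

Section pairs are enumerated by anatomical relationship within patients:

- `intra_biopsy` — distinct sections of one biopsy;
- `intra_l_split` — sections across the two halves of a longitudinally
  split biopsy (requires recorded split pairs);
- `intra_muscle` — sections in different biopsies of the same muscle
  (`intra_QD`, `intra_TA` restrict to one muscle);
- `inter_muscle` — sections in different muscles of the same patient.

For each strategy, iterations first draw a pair uniformly, then one value
from each member's bootstrap distribution, and record the absolute
difference (default 1,000,000 iterations; implemented by drawing per-pair
counts once and vectorising the value draws). Distributions are summarised
by min, 2.5th, 25th, 50th, 75th, 97.5th percentiles and max, using
`np.quantile` with linear interpolation between order statistics. The
97.5th percentile is reported as the difference threshold; an observed
difference "exceeds" a threshold only if strictly greater.

The same machinery applies at biopsy level to mtDNAcn (using each biopsy's
full combinatorial copy-number distribution) and heteroplasmy (using the
three pyrosequencing replicates as the per-biopsy distribution).

## 4. mtDNA assays

### 4.1 Copy number (qPCR staged bootstrap)

Standard curves are straight lines Cq = intercept + slope·log10(copies).
Each bootstrap curve model draws one Cq per dilution with replacement and
fits OLS (vectorised closed form); at least 3 dilutions are required. The
amplification-efficiency diagnostic is `10^(−1/slope) − 1`. Per biopsy and
iteration, one curve model and one Cq replicate are drawn independently for
MT-ND1 and for B2M, copies are back-calculated as
`10^((Cq − intercept)/slope)`, and mtDNAcn per nucleus is
`ND1 / (B2M / 2)` (B2M is diploid-nuclear). Drawn curves with non-negative
slope are rejected and redrawn (capped). The reported point estimate is the
median of the per-biopsy distribution (default 100,000 iterations), which
is robust to the occasional wild curve model.

### 4.2 Heteroplasmy (pyrosequencing)

Per biopsy, heteroplasmy is the arithmetic mean of a triplicate in
[0, 100]%. Replication noise is summarised by the pooled SD across patient
groups: `sqrt(Σ(nᵢ−1)·varᵢ / Σ(nᵢ−1))`, skipping groups with fewer than
two biopsies.

## 5. Synthetic cohort generator

### 5.1 Hierarchy and intensity model

Patients → muscles (QD: quadriceps, TA: tibialis anterior) → biopsies →
3 sections → fibres. The default `study_design()` has 4 patients with 31
biopsies total (5/5, 4/3, 6/5, 1/2 across QD/TA) and four longitudinally
split biopsy pairs with recorded separations averaging 14.4 mm.

Per fibre, VDAC1 ~ Normal(1000, 200) truncated positive; each OXPHOS
marker follows its control line (NDUFB8: slope 0.8, intercept 150, residual
SD 40; MT-CO1: 0.6, 120, 30) plus Gaussian residuals. Systematic effects:

- **patient disparity** — a multiplicative factor on marker intensity
  (defaults 0.95 for NDUFB8, 0.97 for MT-CO1), representing real
  patient-vs-control staining differences not attributable to deficiency;
- **section batch effects** — per-section multiplicative gain
  (SD 0.05) and additive offset (SD 15 intensity units), representing
  staining-run variation. These are deliberately *not* modelled by the
  frequentist classifier (which only knows batch = patient), which is what
  makes it over-call deficiency — the failure mode the benchmarking stage
  is designed to expose. The defaults were chosen so the frequentist
  false-positive rate and kappa land in a realistic regime (tens of
  percent FPR, kappa near 0.6) rather than at either degenerate extreme.

### 5.2 Deficiency model

The true deficient proportion follows a logit-scale Gaussian random walk
over biopsy positions along the muscle (spatial drift SD 0.05 per √mm;
biopsies default 20 mm apart, with split pairs at their recorded
separations), plus a per-muscle logit offset (TA +0.25 by default) around
marker-specific means (NDUFB8 0.30, MT-CO1 0.09). Within a section,
exactly `round(p·n)` fibres are deficient — deterministic assignment, so
section-level ground truth is exact and tests can assert identities.
Deficient fibres are shifted down by 8 residual SDs by default (large
enough that ground truth is unambiguous); a small overabundance rate
(3·10⁻⁴) shifts fibres up. A contiguous index block of 5% of each section
is flagged as the annotated ground-truth subregion.

### 5.3 Annotations, plates, pyrosequencing

Investigator polygons are built from the convex hull of each section's
true-deficient (or overabundant) fibres, buffered by half a residual SD;
investigator disagreement is simulated by jittering polygon vertices with
Gaussian noise (SD in intensity units) and re-hulling. At zero jitter the
polygons reproduce ground truth exactly — the basis of the end-to-end
identity checks. qPCR plates encode per-biopsy true mtDNAcn (pipeline
default: Normal(1476, 517) clipped to [300, 3500] copies) through exact
standard-curve lines (slope −3.3219 ≙ 100% efficiency, intercept 38) with
Gaussian Cq noise (SD 0.2) on 6 replicates per target and a 6-point
10⁷→10² dilution series. Pyrosequencing triplicates draw biopsy means
around per-muscle means (between-biopsy SD 2.9) with replicate SD 1.0,
clipped to [0, 100], plus 0/16/52/92% calibration standards.

### 5.4 What the generator does and does not emulate

It emulates: hierarchical anatomy with spatially drifting mosaicism,
batch-effect-driven classifier failure, investigator disagreement, and
assay noise with realistic magnitudes. It does not emulate: fibre-type
composition, image segmentation errors, spatial correlation *within* a
section, non-linear staining saturation, qPCR inhibition, or any
patient-level correlation between heteroplasmy and deficiency burden.
Conclusions drawn from it are about the *methods'* behaviour, not about
tissue biology.

## 6. Reproducibility and numerical choices

- All stages take explicit integer seeds; the pipeline derives per-stage
  seeds as `sha256(f"{seed}:{stage}") mod 2³¹`, so stages are independent,
  reproducible, and valid NumPy seeds.
- Quantiles throughout use NumPy's default linear interpolation between
  order statistics.
- Default iteration counts (10,000 classifier models, 10,000 consensus and
  benchmark resamples, 10⁶ pairing iterations, 10⁵ qPCR iterations) follow
  the analysis design; the pipeline config scales them down for desk-scale
  runs without changing any algorithm.
- Monte Carlo equivalences used for speed (binomial shortcut for
  proportion bootstraps, weighted-mean form of the investigator bootstrap,
  sums-based vectorised bootstrap OLS) are exact distributional identities,
  each covered by tests comparing against the naive implementation.

## 7. Limitations

- Variability thresholds are percentiles of simulated difference
  distributions; their transfer to real tissue depends on generator
  parameters that are plausible but not fitted to data.
- The frequentist classifier's failure mode is induced by the specific
  batch-effect model; other mis-specifications (e.g. heteroscedastic
  residuals) are untested.
- Consensus certainty treats investigators as exchangeable; systematic
  inter-investigator bias is simulated only as independent jitter.
- Degenerate-kappa handling (flag and exclude) is a convention; other
  choices (e.g. imputing 1.0) would shift weighted summaries on cohorts
  with many single-class sections.
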