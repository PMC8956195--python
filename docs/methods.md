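# Methods

## The problem and the modelling chain

Oral epithelial dysplasia (OED) is a premalignant change of the oral
mucosa whose histopathological grade predicts malignant transformation
poorly.  FTIR micro-spectroscopy images a tissue section as a grid of
infrared absorbance spectra (one per ~5 µm pixel), and the chemical
fingerprint those spectra carry can be mined for prognosis.  This package
implements that analysis chain end to end:

1. **Segmentation** — two-tiered k-means isolates spectrally homogeneous
   epithelial regions on a hyperspectral tile.
2. **Quality control** — Hotelling's T² on a 5-component PCA model rejects
   anomalous spectra at 95% confidence.
3. **Pipeline search** — the preprocessing/classifier option table
   (3 smoothing × 3 baseline × 1 paraffin excision × 4 normalization ×
   3 scaling × 2 feature extraction × 3 classifiers = 648 method
   combinations) is searched, tuning each combination's hyperparameters by
   sequential model-based (Bayesian) optimization of the mean Matthews
   correlation coefficient (MCC) under leave-one-pair-out
   cross-validation (LOPOCV).
4. **Classification and evaluation** — PCA-LDA produces one linear
   discriminant (LD) score per spectrum; lesions are called transforming
   by an inclusive ≥50% majority vote over their spectra; the
   discriminant is projected back to wavenumbers as a weighting vector.

Because the original patient spectra are not public, a first-class
synthetic-data module generates cohorts with the statistical structure
the analysis assumes, providing ground truth for every stage.

## Generative model of the synthetic cohort

Per spectrum *i* of lesion *l* with class *c(l)* ∈ {T, NT}:

    s_i(ν) = t_i · [ B(ν) + e_i·D(ν) + p_i·P(ν) + q_i(ν) ] + ε_i(ν)

* `B(ν)` — eleven Gaussian tissue base bands (amide A/I/II, CH stretches,
  COO⁻, CH₂ bend, PO₂⁻, glycogen) with amplitudes typical of FFPE
  epithelium (amide I 0.85 at 1655 cm⁻¹).
* `D(ν)` — six narrow (σ = 8 cm⁻¹, amplitude 0.012) class-difference bands
  at 1678, 1653, 1628, 1574, 1242 and 1020 cm⁻¹ — the wavenumbers the
  weighting analysis is expected to recover.  The class-effect scalar
  `e_i = μ_c + u_l` has μ_T = `effect_size`, μ_NT = 0, and a per-lesion
  Gaussian random effect `u_l` (SD `lesion_sd`) shared by all spectra of
  a lesion.  In a T lesion a fraction `mixed_fraction_T` of spectra is
  drawn with μ = 0, modelling biopsies that contain non-transforming
  tissue.
* `P(ν)` — paraffin CH₂/CH₃ deformation bands at 1378 and 1462 cm⁻¹,
  confined to the 1340–1490 cm⁻¹ excision window so that tests can verify
  excision removes the contamination; `p_i` is a lognormal per-spectrum
  residual-wax factor (SD `paraffin_jitter`).  Real paraffin also absorbs
  near 2900 cm⁻¹; that band can be added through `paraffin_bands` but is
  off by default.
* `q_i(ν)` — a random polynomial of order ≤ `baseline_order` (default 2)
  standing in for broad scattering backgrounds; physically accurate
  (resonant-)Mie simulation is out of scope.
* `t_i = exp(N(0, thickness_sigma))` — a multiplicative section-thickness
  factor.  Vector normalization of two noise-free spectra with the same
  latent signal but different `t_i` is exactly identical — the property
  that makes normalization decisive in the pipeline ranking.
* `ε_i(ν)` — white noise, SD `noise_sd`.

### Defaults and the calibration choice

The cohort defaults mirror the study design: 10 T + 7 NT lesions,
3891–5437 spectra per lesion, 900–3800 cm⁻¹ at 4 cm⁻¹ (726 points),
128×128 tiles at 5.5 µm.  No spectral effect sizes are published, so the
class-effect scale was calibrated once — `effect_size` = 1.0,
`lesion_sd` = 0.45, `noise_sd` = 0.008, `thickness_sigma` = 0.25,
`mixed_fraction_T` = 0.25, `baseline_scale` = 0.04,
`paraffin_jitter` = 0.3 — so that the optimal preset reaches high but
imperfect lesion-level accuracy (~75–83% sensitivity/specificity across
seeds), the regime the method is designed for, and then frozen.  These
numbers are otherwise arbitrary and should not be read as estimates of
real OED spectral contrast.

What the generator does **not** emulate: realistic histological
morphology, spatial correlation between neighbouring pixels, Mie
scattering line-shape distortions, water-vapour residuals, detector
nonlinearity, and between-patient covariate structure (age, site,
smoking).  Tests passing on synthetic data therefore demonstrate that the
machinery is correct and well-calibrated under its stated assumptions,
not that the classifier's reported performance transfers to real tissue.

## Preprocessing operators

Canonical order: smoothing → baseline → paraffin excision →
normalization → scaling → feature extraction (classifier last).  Order
permutation is supported via `PipelineConfig.order` but excluded from the
default search space: the 648-combination count reflects method choices
only, and a fixed canonical order keeps that count reproducible.

* **Savitzky–Golay** smoothing/differentiation: windows {5,…,21}, poly
  order {2,3}, derivative order {1,2} (≤ poly order).  Edges are handled
  by polynomial fits over asymmetric windows (scipy's `interp` mode);
  derivatives are per cm⁻¹.  After excision the grid has a gap, so SG
  filters operate per contiguous segment.  The derivative window is its
  own hyperparameter even when smoothing is also on.
* **PCA denoising**: reconstruction from the fewest components reaching
  80–95% cumulative explained variance; fitted per training fold (not per
  image) for leakage safety.
* **Rubberband**: subtraction of the lower convex hull (monotone-chain
  construction, linear interpolation between hull points); output is
  non-negative with zero endpoints and invariant to affine offsets.
* **Paraffin excision**: the closed interval [1340, 1490] cm⁻¹ (endpoint
  convention chosen here; 38 grid points on the default axis, leaving
  688).  Always on.
* **Normalization**: vector (unit sum of squares), min–max, or amide I
  (division by the integrated absolute absorbance over 1600–1700 cm⁻¹ —
  the integral, rather than peak height, for noise robustness).  Computed
  on the excised grid, since excision precedes normalization in the
  canonical order.
* **Scaling / feature PCA**: per-wavenumber standard or min–max scaling
  and PCA to 90–98% explained variance, both fitted on training folds
  only.  A zero-variance channel standard-scales to 0 by convention.
  PCA uses a cheap truncated probe first and falls back to an exact
  covariance eigendecomposition when the variance target needs more
  components; selection of k is always exact.

Classifiers: logistic regression (C ∈ [0.001, 10], log-uniform), LDA, or
a 100-tree random forest ("max depth" option interpreted as unlimited
vs. depth-10-limited; min samples split {2..5}; min samples leaf {1,2};
bootstrap on/off).

## Cross-validation and the search

LOPOCV: every (T, NT) lesion pair is held out once — n_T × n_NT folds (70
at study size), training on the remaining lesions.  500 spectra per
lesion (study scale) are drawn once per lesion, with replacement when a
desk-scale lesion is smaller; the subsample is fixed across folds.  Fold
MCC is computed over the pooled spectra of the held-out pair — two
lesions give only two lesion-level outcomes, too few for a fold-level
MCC.  A zero denominator in the MCC is defined as 0; a fold whose
classifier fails scores 0 with a warning rather than aborting a search.
The same folds serve both the search and the final report; no nested CV
is attempted, so the best pipeline's score is mildly optimistic — a
limitation inherited from the design this package reproduces.

The hyperparameter optimizer is a Gaussian-process surrogate (Matérn
ν = 2.5 on a unit-cube encoding: ordinals on an even grid, the logistic C
on a log scale) with expected-improvement acquisition over 256 sampled
candidates per iteration, after an initial random design of
min(budget, max(3, budget/3)) points.  Default budget: 25 evaluations per
skeleton at full scale, 5 at test scale.  Per-skeleton seeds derive from
the master seed by stable CRC-32 hashing of the skeleton's method key, so
results are independent of execution order and fully reproducible.

## PCA-LDA, weighting and lesion calls

PCA (to the explained-variance target, default 90%) is followed by a
two-class Fisher discriminant on the scores: w = S_w⁻¹(μ_T − μ_NT) with
pooled within-class covariance plus a small trace-scaled ridge; the
threshold sits midway between the projected class means (equal priors),
oriented so T scores higher.  A spectrum exactly at threshold is called
NT.  Probabilities come from a one-dimensional logistic calibration of
the training LD scores — the original analysis shows probability maps
without naming a calibration, so this is a documented convention.

The weighting vector is loadingsᵀ·w, re-expanded on the excised axis,
unit-normalized, sign-fixed so the largest-magnitude element is positive.
"Top features" are local maxima of |w| ("weight-peak clusters", minimum
separation 2 grid steps) ranked by height — a broad hump counts once.
When the pipeline includes a derivative, weights live on
derivative-spectrum coordinates and band extrema shift by roughly the
band width; the band-recovery experiment therefore uses a non-derivative
pipeline (excision + vector normalization) with PCA at 99% explained
variance — the narrow planted bands carry little total variance, so a
90% basis truncates them — and a reduced between-lesion effect SD (0.2):
lesion random effects act exactly along the planted-band direction and
otherwise blur the peaks.  Under those conditions the six planted bands
are recovered at ≥5/6 (20-seed median); the 1653 cm⁻¹ band, sitting on
the amide I base band at 1655 cm⁻¹, is the one that typically merges
into its neighbour.

Lesion-level prognosis: T iff the fraction of spectra predicted T is
≥ the vote threshold (default 0.5, inclusive, configurable).  Report
aggregation: spectrum-level sensitivity/specificity per fold (mean ± SD
across folds); per-lesion correct-prediction frequency over each
lesion's test appearances (10 per NT, 7 per T at study size), with class
means ± SD of those frequencies as lesion-level sensitivity/specificity;
ROC curves vertically averaged (mean and median TPR) on a fixed 101-point
FPR grid with linear interpolation.

## Segmentation and QC conventions

Tier-1 k-means runs on tissue pixels only (background = mean absolute
absorbance below 25% of the image median, labelled −1), after an SG first
derivative (window 9, order 2) and vector normalization, reduced to 10
principal components: without the derivative the random scattering
baseline dominates the within-image variance and clustering splits on
baseline shape rather than tissue type.  Ten k-means++ restarts, lowest
inertia kept, fixed seed recorded.  Tier 2 re-clusters a selected subset
of tier-1 regions; which clusters feed the classifier is a
histopathology-informed call in practice, exposed as `--select-labels`
and made by ground-truth layer on synthetic data.

Hotelling QC uses the small-sample F form of the threshold,
T²_crit = k(n−1)(n+1)/(n(n−k)) · F_{k,n−k}(α), rather than the χ²
asymptote — exact at modest n, so clean Gaussian data retains the nominal
95% in expectation.  QC is per image/lesion by default (per-cohort
offered as a flag).

## Problem sizes used by tests and scripts

Test and analysis runs use desk-scale cohorts chosen as the smallest
sizes at which the statistical properties under test are stable: 120–160
spectra per lesion with a 100-spectrum balanced subsample for the
17-lesion evaluation runs; 12 lesions × 200 spectra for the reduced
16-skeleton search (36 folds, budget 5); 16 lesions × 120 spectra for the
band-recovery experiment; 10,000 spectra for the QC calibration check.
The full-scale defaults (spectra_per_lesion 3891–5437, 500-spectrum
subsample, 648 skeletons, budget 25) remain the library defaults.

## Known limitations

* Synthetic spectra are spatially independent; segmentation tests
  therefore exercise spectral, not spatial, structure.
* The GP surrogate treats ordinal hyperparameters as points on a line;
  categorical interactions beyond the skeleton split are not modelled.
* Lesion-level SDs are computed over per-lesion frequencies (n = 7–10),
  so they are themselves noisy.
* With a 17-lesion cohort, LOPOCV estimates have high variance; the
  package reproduces that design rather than improving on it.
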