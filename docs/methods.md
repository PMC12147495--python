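# Methods

## The prediction problem

Each material *i* in a study carries a fixed feature vector x_i and
n_i ≥ 1 repeated measurements of a response (here: bone formation rate
after implantation, in percent). The goal is to predict, for a new
material, not just the expected response but its distribution — in
particular its material-specific spread, which in animal studies
reflects biological and preparative variability.

## Sub-dataset ensemble

A *sub-dataset* keeps every material's features and draws exactly one
of its measurements uniformly at random. N sub-datasets (default 100)
give N training sets that differ only in which replicate each
multi-measured material contributed. One regression model is selected
and fitted per sub-dataset; its out-of-fold predictions give each
material one estimate per sub-dataset, so the N-vector of estimates is
the material's predictive sample. Its mean estimates the expected
response; its spread estimates the response variability, because
materials whose measurements scatter widely perturb the N training sets
— and therefore the N fitted models — more than stable ones.

Estimates are produced by double (nested) cross-validation: materials
are split into `outer_folds` (default 10) shuffled folds; within each
outer training set, every candidate method/hyperparameter pair is
scored by mean r² over `inner_folds` (default 5) inner folds on
standardised features (training-fold statistics only), and the winner,
refitted on the whole outer training set, predicts the held-out fold.
Selection therefore never sees test rows. With N = 100 and 10 outer
folds a run fits exactly 1,000 models and yields exactly 100 estimates
per material. Per-sub-dataset seeds derive from the single root seed
(`seed + j + 1` for sub-dataset j), so fold shuffles differ across
sub-datasets but the entire run is reproducible bit-for-bit for
deterministic learners.

Design choices worth stating:

* **Selection inside the outer folds** (proper nested CV) rather than
  once per sub-dataset on all rows: avoids selection leakage into the
  reported estimates.
* **Out-of-fold estimates as the predictive sample** rather than
  refit-on-all predictions: the predictive claim is about unseen
  materials, and out-of-fold values are the honest version of it.
* **Selection criterion** is mean inner-CV r², matching the reported
  mean-accuracy metric.
* The candidate zoo (13 methods: OLS, PLS, ridge, lasso, elastic net,
  linear SVR, Gaussian process, nonlinear SVR, decision tree, random
  forest, gradient boosting, XGBoost, LightGBM) uses small conventional
  grids (log-spaced regularisation, C/γ log grids, 1..10 PLS
  components, shallow-to-deep trees, ~100-tree ensembles). Grids are
  configuration, not constants; `fast_zoo()` provides reduced variants
  for routine runs and testing.

## Distributional evaluation

Measured values of material i are summarised as a Gaussian: mean =
arithmetic mean; SD = sample SD (n−1) when n_i ≥ 3. Materials measured
once or twice have no usable sample SD; their SD is substituted by the
mean of the sample SDs of all materials with n_i ≥ 3, and flagged. The
N predicted estimates are likewise summarised (N ≥ 2 always; a zero
numerical SD is floored at 1e-6 % and flagged). The substitution rule
never applies to the predicted side.

Per material, prediction quality is the Jensen–Shannon divergence
between the two Gaussians,

    D_JS(P,Q) = ½ [ D_KL(P‖M) + D_KL(Q‖M) ],   M = (P+Q)/2,

with D_KL(P‖Q) = ∫ p log(p/q) dx. M is the pointwise mixture density —
not a Gaussian — so D_JS has no closed form and is integrated
numerically: a uniform trapezoidal grid spanning
[min(μ)−10·max(σ), max(μ)+10·max(σ)] with 20,001 points. Log-densities
are computed analytically (not via exp then log), which keeps the
far-tail contributions exact where the densities themselves underflow
float64; with this, the numerical KL agrees with the closed-form
Gaussian KL to well below 1e-6 across σ ∈ [0.1, 10], and D_JS is stable
to < 1e-7 under grid doubling. Divergences are reported in nats
(bound ln 2 ≈ 0.6931); a `base="2"` switch rescales to bits. The
per-method aggregate is the arithmetic mean of per-material D_JS — the
simplest symmetric choice, stated here because other aggregations
(median, measurement-count weighting) are defensible too.

The mean-accuracy companion metric is the coefficient of determination
of per-material predicted means against measured means,
r² = 1 − Σ(m_i−p_i)²/Σ(m_i−m̄)², which is negative whenever the
predictor is worse than the constant-mean baseline.

Dispersion rectangles (for the mean-vs-mean scatter) use width =
2·SD_measured and height = 2·SD_predicted per material; the multiplier
is configurable and only affects plotting.

## Featurization

* **Spectral bands.** FT-IR and XRD traces are reduced to intensities
  at configured band positions (for calcium-phosphate implants, the
  characteristic hydroxyapatite and β-TCP bands). With window w > 0 the
  feature is the mean intensity within ±w of the position (robust to
  axis discretisation); w = 0 takes the nearest grid point. Band lists
  are configuration because the correct positions depend on instrument
  and phases.
* **LBP texture.** Each interior pixel of a grayscale image is coded by
  the 8 neighbour-minus-centre differences, binarised with a ≥ 0 tie
  rule (a constant image codes to 255), read clockwise from the
  top-left neighbour as the most significant bit. The 256-bin histogram
  (normalized by default) is the image's feature block. Codes depend
  only on the relative ordering of luminances, so they are invariant to
  brightness offsets and to any strictly monotone intensity transform.
  Borders are not padded — only interior pixels are coded.
* **Imputation.** Materials with a missing image contribute NaN LBP
  columns; missing cells are filled by iterative Gaussian-mixture
  conditional means: initialise with column means, fit a
  full-covariance GMM to the completed matrix, replace each missing
  cell by its mixture-weighted conditional mean given the row's
  observed cells, iterate to a 1e-3 per-cell tolerance. One component
  suffices for the default studies; the component count is capped by
  the number of complete rows. This is a deliberately simple
  conditional-mean imputer, not a full EM treatment of missingness.

## Synthetic studies

The generator emulates a 38-material artificial-bone study so that
every stage is testable without any external data. Two independent
latents drive everything:

* **c ~ U(0,1)** — phase composition (β-TCP-like fraction vs
  hydroxyapatite-like). Drives the true mean response through a
  saturating dose-response, μ(c) = 20 + 55 / (1 + e^{−8(c−0.5)}) %,
  i.e. from ~20 % to ~75 % with the transition around the balanced
  mixture. (A quadratic response surface is available as a config
  switch.)
* **u ~ U(0,1)** — crystallinity. Expressed mildly in peak sharpness
  and diffraction intensity and strongly in the image texture scale.

FT-IR traces are sums of Gaussian peaks at fixed phase-signature
positions (ν4/ν3 phosphate regions, 552–1120 cm⁻¹) with areas
proportional to the phase fractions; XRD likewise at the strongest
reflections (25.8–34.4° 2θ) with intensity growing mildly with
crystallinity. Images are Gaussian-filtered noise whose correlation
length follows u. Base features (heating temperature, reagent amount,
carbon beads, implantation weeks, relative density) carry only weak
composition signal plus noise — emulating a study where the synthesis
log is far less informative than the spectra, so the base-only feature
combo performs poorly and spectra-bearing combos well.

The material-specific measurement SD defaults to
σ(c) = 2 + 10·|2c − 1| % — the noise grows as the composition departs
from the balanced mixture, spanning the 2–12 % range, and is symmetric
in c, hence essentially uncorrelated with the monotone mean trend. This
link was chosen after an identifiability analysis: the ensemble's
predicted spread at x_i propagates the measurement variance of
materials *near x_i in feature space* (its own replicates never enter
its out-of-fold estimates), so a recoverable SD must be a smooth
function of directions the fitted models actually resolve — and the
models resolve exactly the directions that predict the mean (c). An SD
drawn independently of all features is structurally unrecoverable by
this (or any) pipeline and remains available as `sd_link="independent"`
for negative controls; `"crystallinity"` and `"mean"` links are also
provided. Even with the default link, recovery quality fluctuates
across generator seeds: 38 materials of which 17 contribute no variance
information (single measurements) and the rest estimate their variance
from 2–6 replicates leave the rank correlation between predicted and
true SD with substantial sampling noise (roughly 0.4–0.7 at N = 100
sub-datasets in our runs, occasionally lower).

Measurement counts follow a configured histogram; the default —
17 materials measured once, and {2: 2, 3: 3, 4: 4, 5: 6, 6: 6}
otherwise — reflects a study where roughly half the materials were
piloted once and the rest measured in groups of about 4–6 animals.
Measurements are i.i.d. N(μ_i, σ_i) clipped to [0, 100] %. The null
generator draws μ_i and σ_i independently of both latents, giving a
dataset where the honest result is r² ≤ 0 and high D_JS.

What the generator does *not* emulate: real HAp/β-TCP spectral physics
(peak shapes, baselines, preferred orientation), realistic SEM
morphology, correlated replicate structure (cage/operator effects), and
non-Gaussian response noise. Passing tests therefore show the
machinery is correct and that the method behaves as designed when its
assumptions hold — not that bone formation rates of real implants are
predictable at any particular accuracy.

## Numerical and degenerate-input conventions

* Sample SDs use the n−1 denominator throughout.
* Zero-variance training responses raise rather than fit.
* Inner-CV ties break toward the earlier candidate in zoo order.
* Densities below 1e-300 contribute zero to divergence integrands.
* Band positions with no axis point in range, images smaller than 3×3,
  all-missing feature columns, and fold counts exceeding the material
  count all raise typed errors rather than degrade silently.

## Problem sizes used in the shipped experiments

The study-scale experiments run at the emulated design's natural size:
38 materials, 100 sub-datasets, 5/10 nested folds (1,000 fitted models)
with the reduced two-method zoo (ridge + 50-tree random forest) for the
recovery run, and a 10-replicate × 8-combo sweep at 10 sub-datasets per
run with two fast linear methods (ridge, PLS) for the combination
ranking. The full 13-method zoo at 100 sub-datasets is the documented
default for real analyses.
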