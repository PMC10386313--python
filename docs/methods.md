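# Methods

## Model and estimation

The core model is probabilistic PCA: `x = W z + μ + ε` with `z ~ N(0, I_q)`
and isotropic noise `ε ~ N(0, σ² I_p)`, so the marginal is
`x ~ N(μ, W Wᵀ + σ² I)`. Estimation maximizes the *observed-data* likelihood
`Σᵢ log N(x_{oᵢ}; μ_{oᵢ}, W_{oᵢ}W_{oᵢ}ᵀ + σ² I)` by EM, where `oᵢ` is sample
i's set of observed coordinates:

- **E-step.** For each distinct observation pattern, the latent posterior is
  `z | x_o ~ N(M⁻¹ W_oᵀ (x_o − μ_o), σ² M⁻¹)` with `M = W_oᵀ W_o + σ² I_q`.
  Rows sharing a pattern are processed together; the study's block-missing
  design has only two patterns (complete, minerals-only), so this grouping
  is what makes the Monte-Carlo sweeps fast.
- **M-step.** `(W, μ)` are updated jointly by augmenting the latent vector
  with a constant 1 and solving one (q+1)×(q+1) normal-equation system per
  *pattern-membership signature* (set of variables observed in the same
  subset of patterns), then `σ²` in closed form. The joint update keeps the
  EM monotonicity guarantee exact; updating μ and W separately would not.
- **Convergence.** Relative log-likelihood change below `tol` (default 1e-8,
  `max_iter` 2000). Fits inside the Monte-Carlo validation loops use
  `tol = 1e-5`, `max_iter = 1000`: the tail of EM convergence here is a slow
  crawl along a flat ridge that changes %CC/RMSECV by far less than their
  Monte-Carlo spread, and the loop runner records run-level diagnostics
  (fraction converged, worst normalized log-likelihood increment) instead of
  warning per fit.
- **Identification.** After fitting, W is rotated by its SVD so `WᵀW` is
  diagonal with descending entries (ordered principal axes) and each
  component's largest-magnitude loading is positive. The marginal
  covariance is invariant to this rotation.
- **Numerics.** The log-likelihood is evaluated through a per-pattern
  eigendecomposition of `W_o W_oᵀ + σ² I`; the equivalent Woodbury form
  cancels catastrophically as σ² → 0. σ² is floored at
  `1e-9 × (total observed variance)/p` so that eigen-rounding noise
  (≈ machine-ε × ‖W‖²) stays well below σ² even on noiseless input; with
  autoscaled data this floor is ≈1e-9. Fully missing rows are excluded from
  fitting but are scored at the prior mean and reconstructed as μ.
- **Initialization.** Deterministic default: eigendecomposition of the
  mean-imputed covariance (for complete data this *is* the maximum-likelihood
  solution, so EM terminates immediately); an optional seeded random
  initialization exists for robustness checks.

Scores are posterior means; imputation uses `E[x_miss | x_obs] = μ_m + W_m E[z]`,
identical to the conditional-Gaussian formula on the model covariance.
Explained-variance fractions are eigenvalues of `W Wᵀ` divided by the total
per-variable observed variance of the calibration data.

## Preprocessing

"Unity variance" is implemented as full autoscaling — per-variable centering
and division by the n−1 standard deviation, computed over *observed* cells of
the calibration subset only — because the chemometric norm is autoscaling and
PPCA estimates μ regardless, making centering harmless and scale the
consequential part. The scaler is refitted on every Monte-Carlo calibration
set so no validation information leaks into the preprocessing. Variables with
fewer than two observed calibration values or zero variance are an error.

## Classification

LDA operates on PPCA scores: class centroids, pooled within-class covariance
(n−k denominator), equal priors (the design is balanced and the boundaries
are defined as equal-Mahalanobis-distance loci). During the validation sweep
the discriminant uses **all q retained components**; restriction to the first
two axes is available (`lda_first_two`) because two-axis score plots are how
the separation is visualized, but order selection by %CC is better served by
the full score vector. Ties in the arg-min are broken by class order
(alphabetical unless specified).

PLS-DA and PLS regression are the comparators and use only the mineral block
(PLS has no missing-data mechanism, and minerals are the only block observed
for every sample). They are backed by scikit-learn's NIPALS `PLSRegression`
with both blocks autoscaled; PLS-DA regresses a {0,1} one-hot indicator
matrix and decodes by arg-max with class-order tie-breaking. At
`n_lv = min(n−1, p_x)` with full-rank predictors the fit equals ordinary
least squares, which is the oracle the tests enforce.

## Validation protocols

**Classification (hybrid cross + external).** Per iteration and month,
round(0.85 · n_complete) complete samples (always leaving at least one out)
go to calibration; the remaining complete samples are the internal
cross-validation pool. The partial samples are split once per run: about a
third per month (nearest rounding, at least one where any exist) form a fixed
external pool that never enters calibration; the rest are calibration members
every iteration. On the default 45-sample design this reproduces exactly the
per-month calibration cells (10,2), (10,2), (8,4) and validation cells
(2,1), (2,1), (1,2), a 36-sample calibration set (22% partial) and a
9-sample validation set (44% partial). %CC is reported over all validation
samples, with an internal/external breakdown in the curve extras; the
selected order maximizes mean %CC with ties toward the smaller order.

**Imputation (Monte-Carlo CV).** Per iteration and month, round(0.2 ·
n_complete) complete samples (min 1) are held out and their whole FAME block
masked; the model is fitted on everything else (PPCA additionally uses the
partial samples; PLSR trains on complete calibration samples only) and the
held-out block is predicted from the minerals. RMSECV and R² are computed
per iteration on the autoscaled scale — the calibration FAME means are 0
there, so R² = 1 − SSE/Σx² — and averaged across iterations, which follows
the protocol's stated averaging; the fully pooled RMSE and the
original-scale RMSECV are additionally reported in the curve extras.
Partial samples have no FAME ground truth, so imputation metrics use only
held-out complete samples, while classification correctness for partial
samples uses their known month labels.

All randomness derives from one run seed: the external pool from
`default_rng([seed, 2**20])`, iteration i from `default_rng([seed, i])`, so
iterations are seed-indexed and order-independent and identical seeds give
bitwise-identical curves.

## Tukey comparisons from summary statistics

Macro-composition tables report only mean ± SD per month, so Tukey's HSD is
computed from summaries: pooled MSE = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1), studentized-range
statistic `q = |mᵢ−mⱼ| / √((MSE/2)(1/nᵢ+1/nⱼ))` (Tukey–Kramer for unequal n),
p-values from the studentized-range distribution with k groups and Σ(nᵢ−1)
degrees of freedom, significance at p < 0.05. Per-month n is not part of the
published summary; the package default assumption is n = 15 (45 samples over
three months). Compact letters come from the insert-and-absorb construction:
groups share a letter iff not significantly different, letters ordered by
descending mean. Degenerate zero-variance input uses the convention p = 1
for equal means, p = 0 otherwise. Note that at n = 15 not every published
superscript pattern is recoverable from the printed summaries — e.g. the
fat/dry-matter January–June contrast sits just below the critical q — which
is expected when the original letters were computed on raw data.

## Synthetic data generator

The generator emulates the *statistical structure the analysis assumes*, not
cheese chemistry: samples are drawn exactly from the PPCA model with
month-specific latent means, then the block-missing design is applied.

- **Design defaults** (the study's bookkeeping): months January/April/June;
  complete samples 12/12/9; partial samples 3/3/6; 73 FAME + 8 mineral
  variables. Partial samples lose the whole FAME block.
- **Latent structure**: true rank q = 5 with geometrically decaying
  component scales (ratio 0.7), so model orders around 5 are the sensible
  choice; isotropic noise sd 0.3 on roughly unit-scale variables.
- **Class geometry**: offsets live on the first two latent axes — January
  (+1,−1)·s, April (+1,+1)·s, June (−2,0)·s with separation s = 1.5 — echoing
  the observed score-plot geometry (winter/spring positive on axis 1, summer
  negative; spring positive on axis 2). Offsets sum to zero. Within-class
  covariance is shared across months (a homoscedastic, LDA-compatible
  assumption; the study conditions say nothing about season-specific
  covariance).
- **Marker variables**: rumenic, vaccenic, α-linolenic and EPA loadings are
  forced positive on both leading axes (spring association); oleic negative
  on axis 1 (summer); S, P, Ca (+,+); K, Zn (+,−); Na (−,+); Fe weak, Mg
  inert. Mineral loadings are shrunk by a factor 0.4 so the fatty-acid block
  carries most of the class signal — the regime in which feeding partial
  FAME information through PPCA visibly outperforms a minerals-only
  classifier, as this system shows.
- **Heterogeneous scales**: per-variable log-normal scale factors (σ = 0.4)
  on the loading rows and uniform baseline means make autoscaling
  consequential.

What the generator does **not** emulate: compositional closure of FAME
percentages, chain-length kinetics, realistic mineral magnitudes (trace
elements are generated on the same working scale as majors), non-Gaussian
tails, or batch/dairy effects. Passing tests therefore demonstrate the
correctness of the estimation and validation machinery under the model's own
assumptions, not the field performance of the classifier on real cheese.

## Problem sizes

The default test and acceptance runs use the study-scale design (45 samples,
81 variables), 20 Monte-Carlo iterations and model orders 1–8; parameter
recovery uses n = 2000 generated samples; oracle equivalences use small
instances (complete 80×10; a 6×3 matrix with two missing cells against a
generic numerical maximizer of the observed-data likelihood). These sizes
were chosen so every statistical check has comfortable resolution while the
whole suite remains quick to run.

## Known limitations

- EM converges slowly (sublinearly) near flat ridges of the likelihood; the
  default tolerance can require >1000 iterations on block-missing data. The
  eigendecomposition initialization makes complete-data fits immediate.
- No regularized or Bayesian variant: with q approaching the observed
  dimension per pattern, the pooled LDA covariance or the EM solution can be
  ill-conditioned; errors advise reducing the order.
- The PLS wrapper exposes exactly one algorithmic family (NIPALS with both
  blocks autoscaled); SIMPLS-style variants would differ beyond the
  least-squares limit.
- Classification of truly partial samples scores them from 8 mineral
  coordinates only; with weak mineral loadings those posteriors shrink
  toward the origin, which bounds external-validation accuracy below the
  internal one.
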