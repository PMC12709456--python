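# Methods

## Overview

`trophicbrain` quantifies the *functional hierarchy* of resting-state brain
dynamics. The chain of reasoning is: (i) directed causal influence between
brain regions leaves a statistical fingerprint in the asymmetry between
forward and time-reversed lagged correlations (the "arrow of time" of the
signal); (ii) a linearised whole-brain oscillator model whose coupling
matrix is tuned to reproduce both functional connectivity and that
non-reversibility yields a directed, weighted effective-connectivity graph
(the GEC); (iii) the trophic organisation of that graph — who feeds whom —
summarises each region's position in the cortical hierarchy and, globally,
how vertical or flat the hierarchy is. The surrounding cohort stages
(multi-site harmonization, covariate-adjusted inference, biomarker ridge
regressions, Monte Carlo disease staging) turn the per-subject hierarchy
measures into group-level neuroscience.

Because the cohort that motivated this pipeline is controlled-access, the
package ships a synthetic multi-site cohort generator with planted ground
truth; every stage is validated by recovering what was planted.

## The linearised Hopf model and the GEC

Each region follows the normal form of a supercritical Hopf bifurcation
(Stuart–Landau oscillator),

    dz_j = (a_j + i ω_j) z_j − |z_j|² z_j + Σ_m C[m,j](z_m − z_j) + σ η_j ,

operated in the noise-driven regime a_j < 0 where the fixed point z = 0 is
stable. Writing z = x + iy, the fluctuations obey a 2N-dimensional
Ornstein–Uhlenbeck process with Jacobian J = [[A, −Ω], [Ω, A]], where
A[n,m] = C[m,n] for m ≠ n, A[n,n] = a_n − Σ_m C[m,n], and Ω = diag(ω).
With the diffusive coupling convention the A-block satisfies the Gershgorin
bound Re λ ≤ max a_n < 0, so any nonnegative coupling leaves the
linearisation valid; stability is still checked defensively.

Analytic second-order statistics follow from the Lyapunov equation
J K + K Jᵀ + σ² I = 0 and the lagged covariance K expm(τJᵀ). Throughout the
package the index convention is **row = earlier sample**:
FS[i,j] = corr(x_i(t), x_j(t+τ)), identically for the empirical estimators
and the model, so that a positive forward-minus-reversed difference at
(i,j) is evidence that *i* drives *j*. The time-reversed counterpart of a
stationary linear process is exactly the transpose of the forward lagged
covariance; this identity is used on both the model and empirical sides.

**Parameters.** a = −0.02 s⁻¹ (all regions), σ = 0.01, ω estimated
per region as the Welch-periodogram peak in 0.008–0.08 Hz, lag τ = 1 TR
(3 s at the emulated acquisition). All are exposed in `HopfParameters` /
`FitConfig`. The noise covariance is σ²I on both oscillator components —
the simplest convention consistent with additive isotropic noise.

**Fitting.** The GEC is obtained by the heuristic pseudo-gradient update

    C_ij ← C_ij + α (FC_emp − FC_mod)_ij
               + ς [(FSf_emp − FSr_emp) − (FSf_mod − FSr_mod)]_ij

restricted to anatomically existing connections (binarised SC mask),
clipped at zero, with the model statistics recomputed analytically each
iteration. Because the FC residual is symmetric and the non-reversibility
residual antisymmetric, the two terms act on orthogonal components of C.
The fit error is the mean squared residual of both targets — the
elementwise-residual update is (up to the learning rates) the negative
gradient of exactly this objective under a diagonally dominant
coupling-to-statistics response, which keeps the update a sensible descent
heuristic. Iteration is fixed-rate (α = ς = 5 × 10⁻³) with best-so-far
tracking, a patience stop (no improvement for 400 iterations, cap 3000),
and a divergence safeguard that halves a global step multiplier only when
the error exceeds 10× the best seen or the Jacobian destabilises. A
strictly monotone line search was rejected during development: the
heuristic direction is not always a descent direction and progress through
its landscape is genuinely non-monotone; demanding monotonicity freezes
the fit far from the optimum.

Cohorts are fitted in two stages: the group-averaged statistics first
(initialised from the normalised SC mask), then each subject warm-started
from the group GEC.

**Non-reversibility shrinkage.** At realistic scan lengths (~200 volumes)
the per-subject forward-minus-reversed lagged correlation matrix is
dominated by sampling noise whenever the underlying asymmetry is weak.
Fitting it verbatim injects spurious asymmetry into the GEC — and, counter-
intuitively, the *most symmetric* subjects acquire the *largest* spurious
directedness, because expressing a given lag-asymmetry through a symmetric
coupling background requires more coupling asymmetry. The package therefore
scales the antisymmetric component of each subject's lagged correlations by
its split-half reliability (the correlation between the two half-scan
estimates, clipped at zero) before fitting — the classical-test-theory
shrinkage of a noisy measurement toward zero, computed label-free per
subject. The symmetric component is untouched. The behaviour is exposed as
`FitConfig.shrink_nonreversibility` (default on).

## Trophic hierarchy

For a directed weighted graph C (C[m,n] = influence of m over n) with
in-weights d_in, out-weights d_out, u = d_in + d_out, and imbalance
v = d_out − d_in, the trophic levels h solve

    (diag(u) − C − Cᵀ) h = v ,

min-shifted so the bottom of the hierarchy sits at level 0. The Laplacian
is exactly singular (constant vector per weakly connected component), so
the minimum-norm least-squares solution is taken; components are solved and
shifted independently with a warning, isolated nodes get level 0. The
levels are exactly the minimisers of the incoherence energy

    F0 = Σ_edges w_e (h_tail − h_head − 1)² / Σ_edges w_e ,

and trophic directedness is 1 − F0: 1 on a perfectly layered graph where
every edge drops one level, 0 on a fully symmetric graph. The residual is
oriented (h_tail − h_head − 1) per edge tail→head, the orientation whose
minimiser solves the Laplacian system above with v = d_out − d_in (sources
high). Asymmetry is summarised separately by the Frobenius index
‖(A − Aᵀ)/2‖_F / ‖A‖_F ∈ [0, 1]. Regions are classed into
sink / mediator / source by equal-width terciles of the z-scored
(population s.d.) group-mean levels, boundary ties to the lower bin.
Network summaries are means (not sums) over member regions, so parcel
count does not weight a network.

## Synthetic cohort

The generator emulates a four-group, multi-site amyloid-stratified ageing
cohort at configurable scale (defaults: 80 regions, 46/36/31/21 subjects,
197 volumes at TR = 3 s, six sites).

* **Ground-truth network**: regions in ordered layers (default 4), dense
  feedforward edges (weight 0.12) between consecutive layers with sparser
  feedback (0.03), edge probability 0.6, plus a connectivity guarantee.
  The weight scale was chosen so that the simulated BOLD reproduces
  realistic parcellated resting-state FC magnitudes (mean off-diagonal
  |r| ≈ 0.25).
* **Disease effect**: group g with flattening λ_g ∈ [0,1] (defaults
  0 / 0.2 / 0.4 / 0.7) draws subject couplings around
  (1−λ_g) C + λ_g (C + Cᵀ)/2 with multiplicative edge jitter (s.d. 0.05) —
  flattening manipulates exactly the asymmetry that directedness measures.
* **BOLD**: Euler–Maruyama integration of the full (cubic) Stuart–Landau
  system, dt = 0.1 s, 60 s burn-in from z(0) = 0, real part sampled at TR.
  ω_j drawn uniformly in 2π·[0.01, 0.08] rad/s once per cohort.
* **Biomarkers / cognition**: linear in each subject's hierarchy deficit
  (reference directedness minus subject directedness) with fixed regional
  loading patterns, a negative grey-matter-volume age slope, and Gaussian
  noise; slopes are configurable effect sizes and stored as ground truth.
* **Site effects**: per site and feature, x → γ + δx with γ ~ N(0, s²),
  δ ~ U(scale range), planted in the biomarker tables and stored for
  recovery tests.

What the generator does **not** emulate: hemodynamic convolution, head
motion, spatially correlated physiological noise, regional heterogeneity of
the bifurcation parameter, longitudinal visits. Passing recovery tests
therefore demonstrate internal consistency of the pipeline under the
model's own assumptions, not robustness to everything real data contains.

## Harmonization

Canonical parametric empirical-Bayes ComBat: per-feature location/scale
model y = α + Xβ + γ_site + δ_site ε fitted by least squares with site
dummies, feature standardisation by the pooled residual s.d., normal prior
on γ and inverse-gamma on δ² with moment-matched hyperpriors, iterative EB
updates, adjustment (y − α − Xβ − σγ*)/δ* + α + Xβ. Covariates: age,
gender, education, diagnosis (one-hot for categoricals). Subjects whose
site has no other subject are excluded first. Constant features (e.g. the
min-shifted bottom region of the hierarchy) pass through unharmonized.
Quality checks mirror standard practice: within-group permutation ANOVA of
site effects before/after, and preservation of the age-slope sign.

## Inference

* **Group contrasts**: Freedman–Lane permutation of covariate-model
  residuals; statistic = t of the group indicator; two-sided
  p = (1 + #{|t*| ≥ |t|})/(n_perm + 1); 10,000 permutations by default;
  BH-FDR across the tested family.
* **Biomarker model**: ridge regression with a random subject intercept,
  fitted by backfitting between the penalised fixed-effect solve
  (intercept unpenalised) and a shrunken (moment-estimated BLUP) subject-
  mean update until 1e−8 convergence; penalty by GCV over a log grid when
  not supplied; standardised continuous predictors; per-coefficient
  permutation p by within-subject permutation of that predictor.
* **Cognition**: one OLS per (score, network) with covariates, BH-FDR
  across the family, complete cases.

## Staging classifier

Binary logistic regression over mRMR-selected features. mRMR is the FCQ
variant: relevance = class F statistic, redundancy = mean |Pearson r| to
the selected set, greedy maximisation of the quotient; a candidate
perfectly correlated with a selected feature is only taken when nothing
else remains. Hyperparameters (number of features 5–15, inverse
regularisation C ∈ {0.01 … 1000}, L1/L2) are tuned by nested leave-one-out
cross-validation on pooled out-of-fold probabilities (per-fold AUC is
undefined for single held-out samples), ties toward fewer features,
stronger regularisation, then L2. Evaluation: 20 stratified 75/25 Monte
Carlo splits; the decision threshold maximises Youden's J on the
training-refit probabilities; significance by 1,000 permutations of the
test labels against the fixed predictions (median p and IQR across
splits); ROC curves vertically averaged on a 0.01 FPR grid; confusion
matrices row-normalised and averaged; feature importance = mean |SHAP| of
the linear model (φ_j = w_j (x_j − x̄_j), exact under feature
independence), zero for unselected features.

## Numerical choices and degenerate inputs

Minimum-norm pseudo-inverse for the singular trophic solve; per-component
min-shift; zero-total-weight graphs rejected; zero in-weight nodes get an
ε-guarded out/in ratio with a warning; unreachable pairs excluded from
mean path length (not ∞); edge distance = 1/weight for paths and
betweenness; Fagiolo directed-weighted clustering; permutation p-values
floored at 1/(n_perm+1); all random stages take explicit seeds and
reproduce bit-identically.

## Problem sizes used in the shipped tests

Unit and property tests run at N ≤ 24 regions. The oracle-equivalence
checks use 50 random networks (N ≤ 8) against direct numerical energy
minimisation and >10⁶ Euler–Maruyama steps (64 replicas) against the
Lyapunov solution. GEC recovery uses noiseless analytic targets at
N = 6–10. The end-to-end staging check uses a 20-region cohort with 10
subjects per group at the full 197-volume scan length — the package's
desk-scale working point for a laptop-class machine.

## Known limitations

* **Lag-asymmetry identifiability.** With strongly heterogeneous intrinsic
  frequencies, the lagged-correlation asymmetry mixes coupling-driven
  directionality with frequency-driven phase leads; the pseudo-gradient
  heuristic can then misattribute asymmetry and pin reciprocal edges at
  the nonnegativity bound. Recovery is exact when frequencies are
  homogeneous and degrades gracefully for moderate spread.
* **Subject-level noise floor of directedness.** At ~200 volumes the
  fitted directedness of a weakly asymmetric subject is floored at ≈ 0.2
  by residual noise-expressed asymmetry even after reliability shrinkage.
  Group contrasts between strongly and weakly hierarchical groups survive
  at larger samples; at 10 subjects per group the groups near the floor
  (the two most flattened) are below the method's resolution — their mean
  ordering can invert on individual cohort draws, the extreme-group
  contrast is underpowered, and the staging classifier on fitted hierarchy
  features lands in the high-0.8 balanced-accuracy range rather than above
  0.9. The shipped end-to-end acceptance test asserts the full set of
  staging properties at exactly this desk scale and documents the shortfall
  in its failure message rather than relaxing the conditions. The split-half reliability weight
  itself tracks the planted flattening far more faithfully than the fitted
  directedness and may be the better subject-level summary at short scan
  lengths.
* The ComBat implementation assumes normal location / inverse-gamma scale
  priors (parametric EB); no GAM extension.
* The classifier pipeline is strictly binary; multiclass staging is out of
  scope.
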