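# Methods

This note records the statistical model, the estimation choices, and the
design decisions behind `hteforest`, in the order the pipeline runs them.

## Generating model and synthetic cohorts

The synthetic generator (`hteforest.synthetic`) draws cohorts from

    Y = μ(X) + τ(X)·W + b_site + ε,      W ~ Bernoulli(e(X)),

with μ(x) linear in a configurable coefficient map, e(x) a logistic index
clipped to [0.05, 0.95] (overlap is guaranteed by construction), site
intercepts b ~ N(0, site_sd²) and noise ε ~ N(0, noise_sd²). Conditional
effects are a homogeneous intercept plus modifier terms of three forms —
linear γx, threshold γ·1[x>0], saturating γ·tanh(x) — chosen so that a
forest can represent them but a linear model cannot. Site effects act on
the outcome level, not on τ; this is the simplest structure that makes
cluster-robust standard errors consequential.

Continuous covariates are z-scaled; binary covariates are Bernoulli(0.3)
and left unscaled. All structural functions (μ, e, τ) are evaluated on the
z-scaled coordinates, so the returned truth ledger (`GroundTruth`) is
exactly consistent with the generated outcome: `true_ate` equals the
empirical mean of `true_tau` over the generated rows to machine precision.

Within a block, continuous covariates can be equicorrelated through a
shared factor (`block_correlation`). The reference heterogeneous cohort
(`three_modifier_spec`: n=4000, 21 sites, 55 covariates in
environment/PRS/brain blocks, three ±0.5 SD modifiers, correlation 0.6)
uses this deliberately: real instrument families are strongly correlated,
and the correlation keeps non-modifier siblings weakly informative — the
regime in which progressive importance-based pruning has a meaningful
funnel (all covariates → a dozen candidates → the modifiers) rather than
collapsing in one step. With fully independent covariates the first
intersection already isolates the modifiers and the second pruning pass
can only cut below them.

What the generator does *not* emulate: longitudinal correlation between
timepoints (outcomes are drawn independently given X and W), non-Gaussian
outcome tails, informative missingness (gaps are MCAR only), and
covariate measurement error. Passing tests therefore demonstrate correct
recovery under clean identifying assumptions, not robustness to their
violation.

## Nuisances and the honest causal forest

Propensity e(x) and marginal outcome mean m(x) are estimated by random
forest regressions with out-of-bag predictions (row i is never predicted
by a tree that saw row i), then e is clipped to [0.05, 0.95]. Oracle
callables can replace either fit; the simulation experiments use them to
isolate the component under test.

The causal forest (`hteforest.forest`, kernel in `hteforest._tree`) grows
trees on the residuals A = W − ê, R = Y − m̂:

* **Subsampling** draws whole sites (default rate 0.5) rather than rows,
  matching the clustering of the design.
* **Honesty**: the subsample is split in half; splits are chosen on one
  half only (the stopping rule also sees only that half), leaf moments
  come from the other. Deleting estimation-half observations can never
  change a split.
* **Splitting** uses gradient pseudo-outcomes: with node effect
  τ = Cov(A,R)/Var(A), each split-half row contributes
  ρᵢ = (Aᵢ−Ā)((Rᵢ−R̄) − (Aᵢ−Ā)τ), and the CART scan maximizes
  S_L²/n_L + S_R²/n_R over candidate thresholds. Equal gains resolve to
  the lowest covariate index, then the lowest threshold, so runs are
  reproducible under column shuffles combined with seed control.
* **Prediction** does not average per-leaf ratios — with min_node_size 5
  the honest leaves are tiny and the local ratio is unstable. Each leaf
  stores its estimation-half moment sums (ΣA, ΣR, ΣAR, ΣA², count); a
  prediction aggregates the moments across trees with weights 1/|leaf| and
  solves Cov_w(A,R)/Var_w(A) once. `oob_tau` applies the same kernel using
  only trees whose subsample excluded the row's site; rows covered by no
  tree are NaN, never silently imputed.

Defaults (`ForestParams`): 500 trees per seed (three seeds merged to 1500
by `fit_seed_ensemble`), honesty fraction 0.5, subsample rate 0.5,
min_node_size 5, mtry = ⌈√p⌉+20 capped at p, importance depth decay 2 with
depth cap 4. These follow common reference-engine conventions; all are
config-exposed because no single setting is canonical. Variable importance
is the depth-weighted split frequency Σ_d d^(−2)·counts[j,d] over depths
1–4, normalized to sum to one.

## Doubly robust estimands

AIPW scores are computed exactly by

    Γᵢ = τ̂⁻ⁱ(Xᵢ) + (Wᵢ−êᵢ)/(êᵢ(1−êᵢ))·(Yᵢ − m̂ᵢ − (Wᵢ−êᵢ)τ̂⁻ⁱ(Xᵢ)),

with τ̂⁻ⁱ the out-of-bag forest prediction. The ATE is mean(Γ) with the
cluster-robust variance Σ_g (Σ_{i∈g}(Γᵢ−Γ̄))²/n² and a two-sided normal
p-value. The calibration test regresses Y−m̂ on τ̄(W−ê) and (τ̂−τ̄)(W−ê)
without intercept (cluster-robust covariance); the coefficients are the
model-fit α and heterogeneity-index β, tested one-sided for positivity —
the reference-engine convention, since β>0 is the alternative of interest.
Degenerate cases (constant Γ, Var(τ̂)=0) are returned flagged, not as
silent numbers. BH-FDR is applied across a declared family; in the
pipeline the family is one run's headline models (last-reached stage,
random iteration 1, across all timepoint × outcome × stratum cells), and
every reported q traces to it.

## Three-step covariate selection

Each stage fits three *random iterations* (covariate order shuffled by an
order seed; three forests with distinct seeds merged) and retains the
covariates with importance strictly above the mean — strict, so exact ties
at the mean drop out. The intersection across iterations forms the next
stage's covariate set: first model (all covariates) → second model →
final model, which refits per iteration without further pruning. Nuisances
are refit on each stage's covariate set, since the covariate space
changes. Stage gates — ATE p < .05 AND one-sided heterogeneity p < .05,
evaluated on random iteration 1, the headline model — stop the procedure
when there is no heterogeneity to localize; an empty intersection stops
with a diagnostic by default (a top-k-by-mean-importance fallback is
config-exposed). Default seeds: orders (1,2,3), forests
((11,12,13),(21,22,23),(31,32,33)), all logged in the trace.

## GATE, group profiles, partial dependence

The GATE test ranks participants by out-of-bag τ̂ (ties broken by stable
row index), cuts near-equal groups (tertiles by default; sizes differ by
at most one), estimates each group's ATE from its AIPW scores with
cluster-robust SEs, and runs Welch t-tests on all pairwise score-mean
contrasts with BH-FDR across the three comparisons. Q3−Q1 is the headline
contrast; the monotonicity flag requires strictly increasing point
estimates. Group ATEs come from the scores, not raw outcome differences,
keeping GATE consistent with the doubly robust machinery. A constant τ̂
ranking is flagged "no ranking signal" rather than silently grouped.

Risk-group profiling compares each final-model covariate between the low-
and high-risk groups: Welch t-test for continuous covariates,
two-proportion z-test for binary ones, BH-FDR across the final set.

Partial dependence sweeps one covariate over its empirical quantiles at
100 equispaced probabilities (0.5%–99.5%; binary covariates use the
two-point grid {0,1}) with all other covariates pinned at median/mode,
scores the synthetic rows with the forest's standard prediction path, and
classifies the trend by Spearman rank correlation: risk if ρ ≥ 0.5 and
the curve range exceeds ε = 0.05 (on the standardized-outcome ITE scale),
protective if ρ ≤ −0.5, flat otherwise. Both thresholds are
config-exposed; they are qualitative conventions, not estimated
quantities.

Because a pinned-covariate sweep over an *uninformative* covariate is a
random step function, its rank correlation is often extreme by chance and
flatness rests on the range threshold alone. Two effects inflate that
range for small forests: kernel noise from tiny honest leaves, and chance
in-sample correlation (~1/√n) between the swept covariate and a true
modifier, which the forest legitimately fits. For interpretation-stage
partial dependence we therefore recommend — and the validation experiments
use — a smoothed forest (min_node_size 20, several hundred trees), which
suppresses both without affecting the sign recovery of real modifiers.

## Data preparation and pipeline

Complete-case filtering drops any row with a missing covariate, treatment
or outcome (no imputation, counts logged). The near-zero-variance filter
removes covariates whose most/second-most frequent value ratio exceeds 19
with under 10% distinct values, and always removes constants. Screening
regresses the outcome on each candidate feature plus a fixed adjustment
set (OLS), BH-adjusts across candidates, and keeps q < .05; collinear
designs are rejected naming the offending columns.

The pipeline runs the identical stage sequence per timepoint × outcome ×
stratum cell (stratified reruns are plain runs on row subsets; cells below
a minimum size are skipped with a logged reason), continues past per-cell
failures, and flags a cell's pattern as failed iff the Q3−Q1 GATE q ≥ .05
or the group ATEs are non-monotone — the two rejection modes of a
specificity analysis. Reports contain no timestamps and all seeds, so a
rerun with the same config is byte-identical.

## Problem sizes used in validation

The test and acceptance experiments run at desk scale, chosen to keep the
full suite in minutes while leaving each property comfortably powered:
reference selection cohorts n=4000 with 50-tree forests per seed (150
merged) and 100-tree nuisances; coverage and double-robustness at
n=2000–4000 with 50–100 replicates; calibration size at n=1000 with 200
replicates; GATE null behavior with 200 direct score simulations; PDP
classification at n=2000 with the smoothed 600-tree forest. Production
analyses should use the defaults (1500 merged trees, 200-tree nuisances).

## Known limitations

* Variance estimation for individual τ̂(x) (per-point confidence
  intervals) is not implemented; inference is at the ATE/GATE level.
* The splitting rule has no imbalance penalty, so nodes can become
  treatment-lopsided before the min-node rule binds; the AIPW step, not
  the raw leaves, carries the inferential guarantees.
* The heterogeneity index is attenuated (β < 1) when forest predictions
  are noisy, and the one-sided test is conservative in small samples.
* MCAR missingness and complete-case analysis are assumed; under MAR/MNAR
  the filtered cohort is a selected sample and estimates shift
  accordingly.
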