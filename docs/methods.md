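# Methods

This note documents the models, the fitting and comparison machinery, the
synthetic-data assumptions, and the numerical choices. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Discrepancy metrics

Self-utility distance is the mean absolute difference between a self profile
and a utility profile over pairwise-complete trait pairs; averaging (rather
than summing) keeps subjects with missing items comparable. The Euclidean
control variant is the plain root-sum-of-squares over used pairs and is *not*
normalised for missingness — `n_pairs_used` is reported so users can filter.
The Pearson variant is a similarity (its association with outcomes reverses
sign) and requires at least two pairs with variance on both sides. Subjects
failing a metric's preconditions get NaN with a logged reason rather than
aborting a cohort.

## Questionnaire scoring

Scales are scored as item sums after reverse-coding (`min + max − x`), with
the published reverse-key sets as defaults (clarity scale: all items except
6 and 11; Rosenberg: 2, 5, 6, 8, 9) and caller-supplied keys accepted. A
subject with any missing item gets a missing scale score; no imputation.
Exclusion follows the strict rule "more than 20% of responses missing":
exactly 20% is retained. Whether multiple response blocks count jointly or
separately is a design decision of the study being analysed; the rule is
applied per supplied response set.

## Learning models

Each of K = 50 traits appears exactly once. PE(t) = F(t) − U(t) uses the
*observed* (or simulated) response, not the model prediction. All trials
strictly before trial t contribute to its prediction (printed summation
bounds in common renderings of such models are treated as notational):

    Pm(t) = init(t) + sum_{i<t, answered} a_eff(i) * PE(i) * SIM(i, t)

with `init` either the constant 80 (default; high prior expectations toward
shared utility perceptions) or the subject's own self ratings
(supplementary variant, `init="self"`). Missed trials contribute no PE.
Models 1–3 emit P = Pm (model 1: P = β₀ + β₁·S instead); models 4–5 emit
P = γ·S + (1−γ)·Pm. For the asymmetric-rate models, a_eff = α⁺ when
|F − S| < |P − S| and α⁻ otherwise (ties take α⁻, the condition being a
strict inequality); by default the comparison uses the *emitted* prediction,
with `asym_compare="component"` switching to Pm — the choice is ambiguous
for the mixture models and therefore exposed.

Similarity entries are signed Pearson correlations of reference-panel
columns (pairwise-complete, ≥ 3 shared raters per pair) and are not
truncated: negative similarities spread sign-flipped updates. Feedback is
the reference-panel column mean rounded half-up to an integer on the 1–100
display scale.

### Observation model

Responses are Gaussian around P(t) with a free per-subject, per-model σ.
Simulation clips to [1, 100] and rounds to the integer slider output; the
likelihood deliberately ignores this censoring (the simplest model
consistent with continuous slider data). Consequence, verified in the test
suite: parameters of subjects whose trajectories ride the slider bounds are
mildly compressed; under the default conditions this is a small effect.

### Parameter transforms and priors

Learning rates and γ are logistic-bounded in (0,1), σ is log-positive,
regression betas unbounded. Fitting happens in the unconstrained space under
independent Gaussian priors with mean 0 and variance 6.25 ("wide" on the
logistic/log scales, the convention of the hierarchical toolboxes this
scheme mirrors); configurable.

## Hierarchical fitting and model comparison

Per subject × model: MAP by multi-start BFGS (3 starts initially: the prior
mean plus random draws from the prior; objective tolerance 1e−6), Laplace
evidence

    log Z ≈ log p(y|θ*) + log p(θ*) + (d/2) log 2π − ½ log det H,

with H the central-finite-difference Hessian of the negative log posterior
(ridge-regularised and flagged when not positive definite).

Across subjects, an empirical-Bayes scheme treats model identity as a random
effect. Iterate until both the model frequencies (tolerance 2e−3) and the
group priors (2% relative movement) stabilise, max 10 sweeps:

* E: responsibilities ∝ exp(log evidence + ψ(α_m) − ψ(Σα)), rows normalised;
  Dirichlet concentrations α_m = 1 + summed responsibilities.
* M: each model's group mean/variance = responsibility-weighted moments of
  the subject MAPs, with the initial wide prior contributing one
  pseudo-observation, and the weighted mean Laplace posterior variance
  subtracted from the moment variance (deconvolution) so the group variance
  reflects true heterogeneity rather than estimation noise; floored at 1e−3.
* Subjects are refit under the updated group priors, warm-started from their
  previous MAP (single start); models whose priors moved less than 1%
  are skipped that sweep.

This Laplace + empirical-Bayes + Dirichlet scheme implements the properties
that matter for the analyses (regularised individual estimates,
random-effects model identity, chance-corrected comparison); it is an
approximation to, not a reimplementation of, full variational hierarchical
Bayesian inference.

Comparison metrics: exceedance probability EP_m = Pr(frequency m largest)
from 10⁵ Monte-Carlo Dirichlet draws; Bayes omnibus risk
BOR = 1/(1 + exp(F₁ − F₀)) comparing the marginal likelihood of the
random-effects model (Monte-Carlo integral over a flat Dirichlet, 10⁵
seeded draws, chunked) against the equal-frequency null; and
PXP_m = EP_m·(1 − BOR) + BOR/M. All normalisations (responsibility rows,
frequencies, EP, PXP) are asserted in tests.

## Recovery and confusion studies

Defaults follow the study scale: 85 subjects, 50 trials, a synthetic
232-rater panel; true parameters α ~ U(0.02, 0.5), γ ~ U(0.05, 0.6),
σ ~ U(5, 15), bracketing the fitted population (reported mean γ 0.253,
SD 0.142). Recovery correlates true vs recovered parameters in natural
space (invariant to the internal transform). Confusion cohorts use
well-separated ranges — strongly split rates (α⁺ ∈ (0.45, 0.7) vs
α⁻ ∈ (0.02, 0.12)), γ ∈ (0.3, 0.6) — and, critically, draw the no-learning
intercept off the manifold β₀ = (1 − β₁)·P_init: on that manifold a linear
readout of self ratings is *exactly* reproduced by the self-anchored mixture
with a vanishing learning rate (γ = β₁), so no method could separate the two.

## Synthetic data

The generators define the conditions under which everything is tested:

* **Reference panel** (232 raters × 50 traits): ratings
  clip(round(μ_k + Λf + ε), 1, 100). The trait list is half positive, half
  negative adjectives, so the first factor is a bipolar evaluative factor
  with signed loadings (|N(12, 3)|, + for positive traits), plus 4 weaker
  unstructured factors (loadings N(0, 6)) and rater noise (sd 10); trait
  means are 50 ± 8 by valence (positive traits rated more useful). This
  yields similarities spanning roughly ±0.6 with mean |r| ≈ 0.36 and
  feedback values spanning roughly 25–70.
* **Survey cohorts**: utility = self + per-trait Laplace offsets whose
  per-subject scale ~ U(5, 35), truncated to keep ratings in range — the
  applied offsets are stored, so each subject's true SUD is known exactly.
  Ideal/ought profiles use the same construction (scale factors 0.9/0.8
  shared through the subject's scale, which induces the high inter-
  discrepancy correlations seen in such designs). A latent esteem factor
  correlates −0.52 with standardised SUD; clarity scores follow
  45 − 0.50·SUD + 4.5·esteem + N(0, 7.5), discretised onto 12–60 (esteem
  analogously onto 10–40). The coefficients were calibrated once by Monte
  Carlo at n = 10⁴ to put corr(SUD, SCC) near −0.55 and the esteem links
  near their published magnitudes.
* **Learning cohorts**: per subject a random trait order, integer self
  profile ~ U(30, 70), and a closed-loop simulation from the generating
  model; generating parameters are persisted for oracle tests.

What the generators do **not** emulate: the semantic structure of the real
adjective lexicon (labels are placeholders), response-time effects, slider
anchoring habits, within-block order effects, and any real-data missingness
mechanism (missingness is injected independently per trial when requested).
Passing tests therefore certify the pipeline's correctness and its behaviour
under plausible conditions, not distributional fidelity to the deposited
data.

## Statistical layer

Regression operations run on standardised outcome and predictors, either
from raw data (OLS via statsmodels) or from a correlation matrix with n —
the two modes agree to 1e−10 on identical data, and matrix mode is how
published analyses are reproduced without raw data. Note the convention:
standardising *both* sides; printed betas produced under other conventions
will not match, though R², F, and commonality components do.

Commonality analysis solves the linear system linking all-subsets R² values
to the 2^p − 1 commonality coefficients (for every non-empty predictor set
A, R²(A) = Σ of components C(S) over subsets S intersecting A); components
sum to the full R² by construction. Adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).
Best-subset search is exhaustive (≤ 15 candidates) with
BIC = n·ln(RSS/n) + k·ln(n), k counting predictors, intercept, and error
variance.

Fisher intervals use tanh(atanh r ± z·(n − 2)^(−1/2)). The variance
denominator is this package's convention: the CI method behind published
trait-survey intervals is typically unstated, and 1/(n−2) reproduces the
published interval for r = −0.566, n = 155 exactly at three decimals, where
the textbook 1/(n−3) differs in the last digit; the latter is available via
`se_offset=3`. p values use t = r√((n−2)/(1−r²)).

The temporal trend in |PE| is tested with a fixed-knot cubic B-spline basis
of trial index (interior knots at trial quantiles, default 4 spline df, one
basis column dropped against the intercept) with subject fixed intercepts,
F-testing the spline block. This is a deliberate simplification of a
penalised GAM: estimated effective degrees of freedom are smoother-specific
and not reproducible across toolboxes, while the fixed-basis F-test answers
the same question (is there a smooth time trend?) reproducibly.

## Problem sizes and runtimes

The slow validations are simulation-scale choices of this package: parameter
recovery uses 85 subjects × 3 seeds (≈ half a minute); model recovery fits
all five models to ten 85-subject cohorts (≈ 1 minute per cohort); the
confusion test in the suite runs a reduced 2-model design, with the full
5 × 5 matrix available through `model_confusion` / the `confuse` CLI.

## Known limitations

* The observation model ignores slider censoring and integer rounding;
  parameters of extreme trajectories are slightly compressed.
* Laplace evidence is a quadratic approximation; on very short sessions
  (≈ 12 trials) it can deviate by ~0.2 nats from exhaustive integration
  (verified against a dense grid; < 0.1 nats by ~30 trials).
* The empirical-Bayes scheme is not a full variational treatment; Dirichlet
  concentrations are driven by hard subject-level Laplace evidences.
* Synthetic similarity structure is an assumption (see above); analyses of
  real sessions should build SIM from the actual reference panel.
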