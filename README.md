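# sudlearn

Self-utility distance and trait-utility social learning: a Python toolkit for
quantifying the mismatch between a person's self-concept and the perceived
usefulness of their traits, and for modelling how people learn trait
utilities from social feedback.

## The scientific problem

People describe themselves with trait adjectives ("sociable", "anxious", ...)
and, separately, judge how *useful* each trait is in their current life.
**Self-utility distance (SUD)** summarises the mismatch between the two
profiles: for self ratings `s_k` and utility ratings `u_k` over K traits
(1–100 slider scales),

    SUD = (1/K') * sum_k |s_k - u_k|        (pairwise-complete, K' pairs used)

— an average Manhattan distance, normalised for missing items.  High SUD
signals an unresolved "change signal": one's attributes feel misaligned with
what the environment rewards.  SUD correlates negatively with self-concept
clarity (SCC) and self-esteem (SE), and the package reproduces the standard
survey toolchain around that claim: Fisher-z confidence intervals,
hierarchical regression with F-change, commonality analysis (unique vs shared
R² components), variance-inflation factors, and exhaustive best-subset BIC
selection — from raw data *or* from a printed correlation matrix.

The learning layer asks *how* trait-utility estimates are formed.  In a
50-trial task a participant states a utility estimate U(t) for one trait per
trial and then sees feedback F(t) (a reference group's average rating).  The
prediction error PE(t) = F(t) − U(t) generalises to not-yet-rated traits
through inter-trait similarity SIM (Pearson correlations over an independent
reference panel).  Five generative models are compared:

1. **No learning** — P(t) = β₀ + β₁·S(t): a linear readout of self ratings.
2. **Fine granularity** — P(t) = P(1) + Σ_{i<t} α·PE(i)·SIM(i,t).
3. **Two learning rates** — as (2) with α⁺ when feedback pulls the estimate
   toward the self rating (|F−S| < |P−S|) and α⁻ otherwise.
4. **Self-adjusted granularity** — Pᵐ as in (2), emitted prediction
   P(t) = γ·S(t) + (1−γ)·Pᵐ(t): the self-concept anchors learning.
5. Model 4 with the asymmetric rates of model 3.

Responses are modelled as Gaussian around P(t) with free σ.  Fitting is
hierarchical and Bayesian: per-subject MAP estimates with Laplace model
evidence, empirical-Bayes group priors, model identity as a random effect
(Dirichlet posterior over model frequencies), and model comparison by
**protected exceedance probability** (PXP), which corrects the exceedance
probability for the chance that all models are equally frequent via the
Bayes omnibus risk.  Parameter-recovery and model-confusion studies validate
the whole pipeline on synthetic cohorts.

## Worked example

```python
import numpy as np
from sudlearn import (SyntheticCohortSpec, gen_reference_panel,
                      gen_learning_cohort, HierarchicalTraitUtility)

panel = gen_reference_panel(seed=900001)           # 232 raters x 50 traits
spec = SyntheticCohortSpec(n_subjects=85, model_id=4, seed=1)
sessions, truth, sim = gen_learning_cohort(spec, panel)

fit = HierarchicalTraitUtility(sessions, sim, model_ids=[1, 2, 3, 4, 5]).fit(seed=101)
print(fit.summary())
```

```
Hierarchical trait-utility model comparison
  subjects: 85   models: [1, 2, 3, 4, 5]
  converged: True after 7 iterations
  Bayes omnibus risk: 0.0000

   model  frequency       EP      PXP    alpha
       1     0.0111   0.0000   0.0000     1.00
       2     0.0120   0.0000   0.0000     1.08
       3     0.0114   0.0000   0.0000     1.03
       4     0.9542   1.0000   1.0000    85.88
       5     0.0113   0.0000   0.0000     1.01

  PXP winner: model 4
```

A cohort simulated from the self-adjusted model is attributed back to it
with PXP = 1: almost all of the 85 subjects' responsibilities land on model
4 (Dirichlet concentration 85.9 of 90), no other model is ever the likely
generator, and the omnibus risk that the differences are chance is zero.
Per-subject parameter estimates are in `fit.params_table(4)`; correlating
them with `truth` gives the parameter-recovery quality — 0.936 for the
learning rate and 0.965 for the anchoring weight γ in this run.

The survey layer works the same way from printed summary statistics alone:

```python
from sudlearn import commonality
import numpy as np

R = np.array([[1, -0.566, 0.589],      # SCC, SUD, SE correlation matrix
              [-0.566, 1, -0.459],
              [0.589, -0.459, 1]])
res = commonality(corr=R, n=155, names=["SUD", "SE"])
print(res.unique, round(res.common_total, 4), round(res.adj_r2, 3))
```

```
{'SUD': 0.1107, 'SE': 0.1373} 0.2096 0.451
```

i.e. SUD uniquely explains 11.1% of clarity variance, self-esteem 13.7%,
with 21.0% shared, and the two-predictor model reaches adjusted R² = 0.451.

A thin CLI (`sudlearn study1|study2|fit|recover|confuse|synth|run`) wraps these stages
for shell use; every stochastic stage takes an explicit `--seed` and writes a
JSON summary with the seeds and a config hash.

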