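"""Hierarchical Bayesian fitting and random-effects model comparison.

Per subject and model, parameters are estimated by MAP in an unconstrained
space under a Gaussian prior, and model evidence is approximated by Laplace's
method at the mode.  Across subjects, an empirical-Bayes scheme treats model
identity as a random effect: responsibilities (posterior probabilities that a
subject's data came from each model) weight the update of each model's group
prior, subjects are refit under the updated priors, and a Dirichlet posterior
over model frequencies yields exceedance probabilities.  The protected
exceedance probability (PXP) corrects the exceedance probability for the
possibility that all models are equally frequent, via the Bayes omnibus risk
(BOR).

The scheme mirrors the behaviour of hierarchical Bayesian inference toolboxes
for behavioural model comparison (regularised individual estimates, random-
effects model identity, PXP); it uses Laplace evidence plus empirical-Bayes
moment updates rather than a full variational treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess

from .learning import (
    LearningSession,
    SimilarityMatrix,
    TraitUtilityModel,
    get_model_spec,
)

__all__ = [
    "GaussianPrior",
    "SubjectFit",
    "fit_subject_map",
    "HierarchicalTraitUtility",
    "HierarchicalResults",
    "fit_hierarchical",
    "protected_exceedance",
    "parameter_recovery",
    "model_confusion",
    "RecoveryReport",
    "ConfusionMatrixReport",
    "default_param_sampler",
]

logger = logging.getLogger(__name__)

#: default prior variance in the unconstrained space ("wide Gaussian priors")
DEFAULT_PRIOR_VAR = 6.25


@dataclass
class GaussianPrior:
    """Independent Gaussian prior over the unconstrained parameter vector."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.var = np.atleast_1d(np.asarray(self.var, dtype=float))
        if self.var.shape != self.mean.shape:
            raise ValueError("prior mean and var must have the same shape")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    @classmethod
    def wide(cls, d: int, var: float = DEFAULT_PRIOR_VAR) -> "GaussianPrior":
        return cls(np.zeros(d), np.full(d, var))

    def logpdf(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(
            -0.5 * np.sum(np.log(2.0 * np.pi * self.var))
            - 0.5 * np.sum((x - self.mean) ** 2 / self.var)
        )


@dataclass
class SubjectFit:
    subject_id: object
    model_id: int
    x_map: np.ndarray            # MAP in the unconstrained space (free params)
    params: dict                 # natural-space parameters at the MAP
    log_posterior: float         # joint log density at the MAP
    log_evidence: float          # Laplace approximation
    hessian_logdet: float
    converged: bool
    n_restarts_used: int
    hessian_regularized: bool = False
    free_names: tuple = ()
    posterior_var: np.ndarray | None = None  # diag of inverse Hessian at the MAP


def _negative_log_posterior(model: TraitUtilityModel, prior: GaussianPrior):
    def nlp(x):
        try:
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                ll = model.loglike_free(x)
        except (FloatingPointError, OverflowError, ValueError):
            return np.inf
        if not np.isfinite(ll):
            return np.inf
        return -(ll + prior.logpdf(x))

    return nlp


def fit_subject_map(
    model: TraitUtilityModel,
    prior: GaussianPrior | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> SubjectFit:
    """MAP estimate with multi-start quasi-Newton optimisation and Laplace
    log-evidence:

        log Z ~= log p(y|theta*) + log p(theta*) + (d/2) log 2pi
                 - (1/2) log det H,

    with H the Hessian of the negative log-posterior at the mode theta*.
    A non-positive-definite Hessian is ridge-regularised and flagged.
    """
    d = model.n_free
    if prior is None:
        prior = GaussianPrior.wide(d)
    if prior.mean.size != d:
        raise ValueError(f"prior dimension {prior.mean.size} != {d} free parameters")
    nlp = _negative_log_posterior(model, prior)
    rng = np.random.default_rng(seed)
    starts = []
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
    starts.append(prior.mean.copy())
    sd = np.sqrt(prior.var)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(prior.mean + rng.normal(size=d) * sd)
    # n_restarts caps the total number of starts; a provided warm start
    # counts first, so refits with n_restarts=1 are warm-start only
    starts = starts[: max(1, n_restarts)]

    best = None
    n_used = 0
    for x0 in starts:
        if not np.isfinite(nlp(x0)):
            continue
        n_used += 1
        res = optimize.minimize(nlp, x0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return SubjectFit(
            model.session.subject_id, model.model_id, np.full(d, np.nan), {},
            -np.inf, -np.inf, np.nan, False, n_used, free_names=model.free_names,
        )

    x_map = best.x
    log_post = -best.fun
    hess = approx_hess(x_map, nlp)
    hess = 0.5 * (hess + hess.T)
    eigvals = np.linalg.eigvalsh(hess)
    regularized = False
    if eigvals.min() <= 1e-10:
        ridge = abs(eigvals.min()) + 1e-6
        hess = hess + ridge * np.eye(d)
        regularized = True
        logger.debug(
            "subject %r model %d: non-positive-definite Hessian, ridge %.2e applied",
            model.session.subject_id, model.model_id, ridge,
        )
    sign, logdet = np.linalg.slogdet(hess)
    log_evidence = log_post + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    post_var = np.diag(np.linalg.inv(hess)).copy()
    return SubjectFit(
        model.session.subject_id,
        model.model_id,
        x_map,
        model.params_from_free(x_map),
        log_post,
        float(log_evidence),
        float(logdet),
        bool(best.success or np.isfinite(log_evidence)),
        n_used,
        hessian_regularized=regularized,
        free_names=model.free_names,
        posterior_var=post_var,
    )


# ---------------------------------------------------------------------------
# random-effects model comparison


def protected_exceedance(
    alpha: np.ndarray,
    log_evidence: np.ndarray | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
):
    """Exceedance probability, Bayes omnibus risk, and protected EP.

    EP_m = Pr(freq_m is the largest) under the Dirichlet(alpha) posterior,
    estimated from Monte-Carlo draws.  BOR compares the marginal likelihood of
    the random-effects model (frequencies ~ flat Dirichlet) against the null
    of equal frequencies, using the per-subject log evidences;
    PXP_m = EP_m * (1 - BOR) + BOR / M.

    Returns (EP, BOR, PXP).  BOR is NaN when no evidence matrix is given.
    """
    alpha = np.asarray(alpha, dtype=float)
    m = alpha.size
    if m < 2:
        raise ValueError("at least two models are required")
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=m) / n_draws

    if log_evidence is None:
        return ep, float("nan"), ep.copy()

    lev = np.asarray(log_evidence, dtype=float)
    if lev.ndim != 2 or lev.shape[1] != m:
        raise ValueError("log_evidence must be (n_subjects, n_models)")
    shift = lev.max(axis=1, keepdims=True)
    lev0 = lev - shift  # per-subject shift cancels in F1 - F0
    # null: every subject's model drawn with probability 1/M
    f0 = float(np.sum(special.logsumexp(lev0, axis=1) - np.log(m)))
    # alternative: Monte-Carlo marginal over frequencies ~ Dirichlet(1,...,1)
    log_terms = np.empty(n_draws)
    chunk = 5000
    for lo in range(0, n_draws, chunk):
        r = rng.dirichlet(np.ones(m), size=min(chunk, n_draws - lo))
        # (c, n, m): per-subject mixture likelihood under each frequency draw
        t = special.logsumexp(lev0[None, :, :] + np.log(r)[:, None, :], axis=2)
        log_terms[lo:lo + len(r)] = t.sum(axis=1)
    f1 = float(special.logsumexp(log_terms) - np.log(n_draws))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = ep * (1.0 - bor) + bor / m
    return ep, bor, pxp


@dataclass
class HierarchicalResults:
    """Group-level fit: priors per model, responsibilities, Dirichlet posterior
    over model frequencies, and comparison metrics."""

    model_ids: list
    subject_ids: list
    subject_fits: dict                 # (subject_id, model_id) -> SubjectFit
    responsibilities: pd.DataFrame     # subjects x models, rows sum to 1
    dirichlet_alpha: np.ndarray
    model_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    bor: float
    pxp: np.ndarray
    group_means: dict                  # model_id -> unconstrained mean vector
    group_vars: dict
    log_evidence: pd.DataFrame         # subjects x models
    converged: bool
    n_iter: int
    config: dict = field(default_factory=dict)

    @property
    def winner(self) -> int:
        return int(self.model_ids[int(np.argmax(self.pxp))])

    def params_table(self, model_id: int) -> pd.DataFrame:
        """Natural-space MAP parameters of every subject under one model."""
        rows = {}
        for sid in self.subject_ids:
            rows[sid] = self.subject_fits[(sid, model_id)].params
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        lines = [
            "Hierarchical trait-utility model comparison",
            f"  subjects: {len(self.subject_ids)}   models: {self.model_ids}",
            f"  converged: {self.converged} after {self.n_iter} iterations",
            f"  Bayes omnibus risk: {self.bor:.4f}",
            "",
            f"  {'model':>6} {'frequency':>10} {'EP':>8} {'PXP':>8} {'alpha':>8}",
        ]
        for j, m in enumerate(self.model_ids):
            lines.append(
                f"  {m:>6} {self.model_frequencies[j]:>10.4f} "
                f"{self.exceedance_prob[j]:>8.4f} {self.pxp[j]:>8.4f} "
                f"{self.dirichlet_alpha[j]:>8.2f}"
            )
        lines.append("")
        lines.append(f"  PXP winner: model {self.winner}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_ids": [int(m) for m in self.model_ids],
            "model_frequencies": [float(v) for v in self.model_frequencies],
            "dirichlet_alpha": [float(v) for v in self.dirichlet_alpha],
            "exceedance_prob": [float(v) for v in self.exceedance_prob],
            "bor": float(self.bor),
            "pxp": [float(v) for v in self.pxp],
            "winner": self.winner,
            "group_means": {str(m): [float(v) for v in mu] for m, mu in self.group_means.items()},
            "group_vars": {str(m): [float(v) for v in vv] for m, vv in self.group_vars.items()},
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "config": self.config,
        }


class HierarchicalTraitUtility:
    """Random-effects fit of one or more learning models to a cohort.

    Iterates: per-subject MAP + Laplace evidence under each model's current
    group prior; responsibilities from evidences and the expected log model
    frequencies; moment updates of group means/variances (regularised by the
    initial wide prior); Dirichlet concentrations = 1 + summed
    responsibilities.  Stops when model frequencies change by less than
    ``tol`` or after ``max_iter`` sweeps.
    """

    def __init__(
        self,
        sessions: list[LearningSession],
        similarity: SimilarityMatrix | None,
        model_ids=(1, 2, 3, 4, 5),
        init: str = "constant",
        asym_compare: str = "emitted",
        sigma_fixed: float | None = None,
        prior_var: float = DEFAULT_PRIOR_VAR,
    ):
        if len(sessions) < 2:
            raise ValueError("hierarchical fitting needs at least two subjects")
        self.sessions = sessions
        self.model_ids = [int(m) for m in model_ids]
        if not self.model_ids:
            raise ValueError("at least one model is required")
        self.similarity = similarity
        self.prior_var = float(prior_var)
        self.models = {
            (s.subject_id, m): TraitUtilityModel(
                s, similarity, m, init=init,
                asym_compare=asym_compare, sigma_fixed=sigma_fixed,
            )
            for s in sessions
            for m in self.model_ids
        }
        self.config = {
            "init": init, "asym_compare": asym_compare,
            "sigma_fixed": sigma_fixed, "prior_var": prior_var,
        }

    def fit(
        self,
        seed: int = 0,
        max_iter: int = 10,
        tol: float = 2e-3,
        n_restarts: int = 3,
        refit_restarts: int = 1,
        mc_draws: int = 100_000,
        kappa0: float = 1.0,
        nu0: float = 1.0,
        var_floor: float = 1e-3,
    ) -> HierarchicalResults:
        rng = np.random.default_rng(seed)
        subject_ids = [s.subject_id for s in self.sessions]
        n, m = len(subject_ids), len(self.model_ids)
        priors = {
            mid: GaussianPrior.wide(self.models[(subject_ids[0], mid)].n_free, self.prior_var)
            for mid in self.model_ids
        }
        wide = {mid: priors[mid] for mid in self.model_ids}
        fits: dict = {}
        lev = np.empty((n, m))

        refit_priors: dict = {}

        def refit_all(first: bool) -> None:
            for j, mid in enumerate(self.model_ids):
                # skip models whose group prior has stabilised: their
                # subject posteriors (and evidences) would barely move
                last = None if first else refit_priors.get(j)
                if last is not None:
                    dmean = np.max(np.abs(priors[mid].mean - last.mean) / np.sqrt(last.var))
                    dvar = np.max(np.abs(priors[mid].var - last.var) / last.var)
                    if max(dmean, dvar) < 0.01:
                        continue
                refit_priors[j] = priors[mid]
                for i, sid in enumerate(subject_ids):
                    prev = fits.get((sid, mid))
                    fit = fit_subject_map(
                        self.models[(sid, mid)],
                        prior=priors[mid],
                        n_restarts=n_restarts if first else refit_restarts,
                        seed=int(rng.integers(2**31 - 1)),
                        start=None if prev is None else prev.x_map,
                    )
                    fits[(sid, mid)] = fit
                    lev[i, j] = fit.log_evidence

        refit_all(first=True)
        alpha = np.ones(m)
        freqs = alpha / alpha.sum()
        prev_priors = {mid: (priors[mid].mean, priors[mid].var) for mid in self.model_ids}
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: responsibilities from evidence + expected log frequency
            elogq = special.digamma(alpha) - special.digamma(alpha.sum())
            logits = lev + elogq[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            resp = np.exp(logits)
            resp /= resp.sum(axis=1, keepdims=True)
            alpha = 1.0 + resp.sum(axis=0)
            new_freqs = alpha / alpha.sum()

            # M-step: responsibility-weighted moments, shrunk toward the wide prior
            for j, mid in enumerate(self.model_ids):
                w = resp[:, j]
                xs = np.stack([fits[(sid, mid)].x_map for sid in subject_ids])
                ok = np.isfinite(xs).all(axis=1)
                w = np.where(ok, w, 0.0)
                n_eff = w.sum()
                mu0, v0 = wide[mid].mean, wide[mid].var
                mean = (kappa0 * mu0 + (w[:, None] * np.where(ok[:, None], xs, 0.0)).sum(axis=0)) / (
                    kappa0 + n_eff
                )
                dev = np.where(ok[:, None], (xs - mean) ** 2, 0.0)
                if n_eff > 0:
                    moment = (w[:, None] * dev).sum(axis=0) / n_eff
                    # deconvolve per-subject estimation noise (Laplace posterior
                    # variance) so the group variance reflects true heterogeneity
                    pv = np.stack([
                        fits[(sid, mid)].posterior_var
                        if fits[(sid, mid)].posterior_var is not None
                        else np.zeros_like(mu0)
                        for sid in subject_ids
                    ])
                    noise = (w[:, None] * np.where(ok[:, None], pv, 0.0)).sum(axis=0) / n_eff
                    var_hat = np.maximum(moment - noise, var_floor)
                else:
                    var_hat = v0
                var = (nu0 * v0 + n_eff * var_hat) / (nu0 + n_eff)
                priors[mid] = GaussianPrior(mean, np.maximum(var, var_floor))

            # convergence requires both stable frequencies and stable group
            # priors (with a single model the frequencies are trivially
            # constant, so the prior criterion is the binding one)
            prior_shift = 0.0
            for mid in self.model_ids:
                pm, pv = prev_priors[mid]
                prior_shift = max(
                    prior_shift,
                    float(np.max(np.abs(priors[mid].mean - pm) / np.sqrt(pv))),
                    float(np.max(np.abs(np.log(priors[mid].var / pv)))),
                )
            prev_priors = {mid: (priors[mid].mean, priors[mid].var) for mid in self.model_ids}
            done = np.max(np.abs(new_freqs - freqs)) < tol and prior_shift < 0.02
            freqs = new_freqs
            if done and it > 1:
                converged = True
                break
            refit_all(first=False)

        if m >= 2:
            ep, bor, pxp = protected_exceedance(
                alpha, lev, n_draws=mc_draws, seed=int(rng.integers(2**31 - 1))
            )
        else:
            ep, bor, pxp = np.ones(1), 0.0, np.ones(1)
        if not converged:
            logger.warning("hierarchical fit stopped at max_iter=%d without convergence", max_iter)

        resp_df = pd.DataFrame(resp, index=subject_ids, columns=self.model_ids)
        lev_df = pd.DataFrame(lev, index=subject_ids, columns=self.model_ids)
        return HierarchicalResults(
            self.model_ids, subject_ids, fits, resp_df, alpha, freqs,
            ep, float(bor), pxp,
            {mid: priors[mid].mean for mid in self.model_ids},
            {mid: priors[mid].var for mid in self.model_ids},
            lev_df, converged, it,
            config={**self.config, "seed": seed, "max_iter": max_iter, "tol": tol,
                    "n_restarts": n_restarts, "refit_restarts": refit_restarts,
                    "gtol": 1e-6},
        )


def fit_hierarchical(sessions, similarity, model_ids=(1, 2, 3, 4, 5), seed=0, **kwargs):
    """Functional wrapper around :class:`HierarchicalTraitUtility`."""
    model_kwargs = {
        k: kwargs.pop(k)
        for k in ("init", "asym_compare", "sigma_fixed", "prior_var")
        if k in kwargs
    }
    model = HierarchicalTraitUtility(sessions, similarity, model_ids, **model_kwargs)
    return model.fit(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# recovery and confusion


@dataclass
class RecoveryReport:
    model_id: int
    param_names: list
    true_values: pd.DataFrame       # subjects x params
    recovered_values: pd.DataFrame
    correlations: dict              # param -> Pearson r (NaN with reason if degenerate)
    notes: dict = field(default_factory=dict)


@dataclass
class ConfusionMatrixReport:
    model_ids: list
    counts: np.ndarray              # rows: generating model, cols: PXP winner
    proportions: np.ndarray
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.model_ids, columns=self.model_ids)


_DEFAULT_RANGES = {
    "alpha": (0.02, 0.5),
    "alpha_plus": (0.02, 0.5),
    "alpha_minus": (0.02, 0.5),
    "gamma": (0.05, 0.6),
    "sigma": (5.0, 15.0),
    "beta0": (5.0, 30.0),
    "beta1": (0.3, 0.9),
}

#: well-separated ranges used for model-confusion cohorts, chosen so that each
#: model's signature (asymmetry, self anchoring, slope) is expressed strongly.
#: The no-learning intercept is kept off the manifold beta0 = (1 - beta1) * 80,
#: on which a pure linear readout is exactly reproduced by the self-anchored
#: mixture with a vanishing learning rate (gamma = beta1).
_SEPARATED_RANGES = {
    **_DEFAULT_RANGES,
    "alpha_plus": (0.45, 0.7),
    "alpha_minus": (0.02, 0.12),
    "gamma": (0.3, 0.6),
    "alpha": (0.2, 0.6),
    "sigma": (5.0, 10.0),
    "beta0": (-15.0, 0.0),
    "beta1": (0.8, 1.0),
}


def default_param_sampler(model_id: int, ranges: dict | None = None):
    """Uniform sampler over per-parameter ranges (defaults bracket the fitted
    population: learning rates U(0.02, 0.5), gamma U(0.05, 0.6), sigma U(5, 15))."""
    spec = get_model_spec(model_id)
    ranges = {**_DEFAULT_RANGES, **(ranges or {})}

    def sample(rng: np.random.Generator) -> dict:
        return {name: float(rng.uniform(*ranges[name])) for name in spec.param_names}

    return sample


def parameter_recovery(
    model_id: int,
    n_subjects: int = 85,
    n_traits: int = 50,
    seed: int = 0,
    param_sampler=None,
    design=None,
    fit_kwargs: dict | None = None,
) -> RecoveryReport:
    """Simulate a cohort from one model, refit it hierarchically, and report
    the Pearson correlation between true and recovered parameters in natural
    space."""
    from .synthetic import SyntheticCohortSpec, gen_learning_cohort, gen_reference_panel

    if param_sampler is None:
        param_sampler = default_param_sampler(model_id)
    spec = SyntheticCohortSpec(
        n_subjects=n_subjects, n_traits=n_traits, model_id=model_id, seed=seed
    )
    if design is None:
        panel = gen_reference_panel(
            n_traits=n_traits, n_ref=spec.n_reference, seed=seed + 1_000_003
        )
    else:
        panel = design
    sessions, true_df, similarity = gen_learning_cohort(
        spec, panel, param_sampler=param_sampler
    )
    fit_kwargs = dict(fit_kwargs or {})
    results = HierarchicalTraitUtility(
        sessions, similarity, model_ids=[model_id]
    ).fit(seed=seed + 7, **fit_kwargs)
    recovered = results.params_table(model_id).loc[true_df.index]

    correlations, notes = {}, {}
    for name in true_df.columns:
        t = true_df[name].to_numpy(float)
        r = recovered[name].to_numpy(float)
        if np.std(t) == 0 or np.std(r) == 0:
            correlations[name] = float("nan")
            notes[name] = "degenerate: zero variance"
        else:
            correlations[name] = float(np.corrcoef(t, r)[0, 1])
    return RecoveryReport(model_id, list(true_df.columns), true_df, recovered,
                          correlations, notes)


def model_confusion(
    model_ids=(1, 2, 3, 4, 5),
    n_subjects_per_cell: int = 20,
    n_traits: int = 50,
    n_reps: int = 1,
    seed: int = 0,
    ranges: dict | None = None,
    fit_kwargs: dict | None = None,
) -> ConfusionMatrixReport:
    """Generate cohorts from each model (well-separated parameters), fit all
    models hierarchically, and tabulate the PXP winner per cell."""
    from .synthetic import SyntheticCohortSpec, gen_learning_cohort, gen_reference_panel

    model_ids = [int(m) for m in model_ids]
    if len(model_ids) < 2:
        raise ValueError("confusion analysis needs at least two models")
    ranges = {**_SEPARATED_RANGES, **(ranges or {})}
    k = len(model_ids)
    counts = np.zeros((k, k), dtype=int)
    failures = []
    fit_kwargs = dict(fit_kwargs or {})
    panel = gen_reference_panel(n_traits=n_traits, seed=seed + 500_009)
    for rep in range(n_reps):
        for gi, gen_model in enumerate(model_ids):
            cell_seed = seed + 10_007 * rep + 101 * gi
            spec = SyntheticCohortSpec(
                n_subjects=n_subjects_per_cell, n_traits=n_traits,
                model_id=gen_model, seed=cell_seed,
            )
            sampler = default_param_sampler(gen_model, ranges)
            try:
                sessions, _, similarity = gen_learning_cohort(
                    spec, panel, param_sampler=sampler
                )
                res = HierarchicalTraitUtility(
                    sessions, similarity, model_ids=model_ids
                ).fit(seed=cell_seed + 13, **fit_kwargs)
                counts[gi, model_ids.index(res.winner)] += 1
            except Exception as exc:  # logged, not fatal for other cells
                failures.append({"rep": rep, "generating_model": gen_model, "error": str(exc)})
                logger.warning("confusion cell (rep=%d, gen=%d) failed: %s", rep, gen_model, exc)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        proportions = np.where(row_sums > 0, counts / row_sums, np.nan)
    return ConfusionMatrixReport(model_ids, counts, proportions, failures)
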