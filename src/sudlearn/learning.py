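"""Trait-utility learning: similarity/feedback construction and the five
generative models of how people update utility estimates from social feedback.

A subject sees each of K traits once (T = K trials).  On trial t they state a
utility estimate U(t) for the trait shown and then see feedback F(t), the
reference group's average utility rating.  The prediction error
PE(t) = F(t) - U(t) spreads to not-yet-rated traits in proportion to
inter-trait similarity (Pearson correlations over an independent reference
panel), scaled by a learning rate.

Model 1   no learning: P(t) = b0 + b1 * S(t), a linear readout of self ratings.
Model 2   fine granularity: P(t) = P_init + sum_{i<t} a * PE(i) * SIM(i, t).
Model 3   as Model 2 with asymmetric rates: a+ applies when feedback pulls the
          estimate toward the self rating (|F - S| < |P - S|), a- otherwise.
Model 4   as Model 2 plus the self-concept as a reference point:
          P(t) = g * S(t) + (1 - g) * Pm(t), g in (0, 1).
Model 5   Model 4 with the asymmetric rates of Model 3.

Responses are modelled as Gaussian around P(t) with free sd sigma; simulation
is closed-loop (each simulated response feeds the next update).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ratings import RatingTable

__all__ = [
    "SimilarityMatrix",
    "FeedbackSchedule",
    "LearningSession",
    "PredictionTrace",
    "ModelSpec",
    "MODEL_PARAM_NAMES",
    "get_model_spec",
    "to_natural",
    "to_transformed",
    "build_similarity_matrix",
    "compute_feedback",
    "predict_trajectory",
    "model_loglik",
    "simulate_subject",
    "TraitUtilityModel",
    "read_sessions",
    "write_sessions",
]

DEFAULT_P_INIT = 80.0

# ---------------------------------------------------------------------------
# data containers


@dataclass
class SimilarityMatrix:
    """K x K inter-trait similarity (signed Pearson correlations)."""

    trait_labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.trait_labels)
        if self.values.shape != (k, k):
            raise ValueError(f"similarity must be {k}x{k}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("similarity diagonal must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-10):
            raise ValueError("similarity entries must lie in [-1, 1]")
        self._index = {lab: i for i, lab in enumerate(self.trait_labels)}

    def submatrix(self, labels) -> np.ndarray:
        idx = [self._index[lab] for lab in labels]
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.trait_labels, columns=self.trait_labels)


@dataclass
class FeedbackSchedule:
    """Integer feedback value in [1, 100] per trait (reference-panel mean)."""

    trait_labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.trait_labels),):
            raise ValueError("one feedback value per trait required")
        if np.any((self.values < 1) | (self.values > 100)):
            raise ValueError("feedback values must lie in [1, 100]")
        self._index = {lab: i for i, lab in enumerate(self.trait_labels)}

    def value_for(self, label) -> float:
        return float(self.values[self._index[label]])


@dataclass
class LearningSession:
    """One subject's ordered learning run: trait shown, S, U (may be missing), F."""

    subject_id: object
    traits: list
    S: np.ndarray
    U: np.ndarray
    F: np.ndarray
    p_init: float = DEFAULT_P_INIT

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        t = len(self.traits)
        if len(set(self.traits)) != t:
            raise ValueError("each trait must appear exactly once")
        for name, arr in (("S", self.S), ("U", self.U), ("F", self.F)):
            if arr.shape != (t,):
                raise ValueError(f"{name} must have length {t}")
        if np.isnan(self.S).any() or np.isnan(self.F).any():
            raise ValueError("S and F must be fully observed")
        for name, arr in (("S", self.S), ("F", self.F)):
            if np.any((arr < 1) | (arr > 100)):
                raise ValueError(f"{name} values must lie in [1, 100]")
        obs = self.U[~np.isnan(self.U)]
        if np.any((obs < 1) | (obs > 100)):
            raise ValueError("U values must lie in [1, 100]")
        if not (1 <= self.p_init <= 100):
            raise ValueError("p_init must lie in [1, 100]")

    @property
    def n_trials(self) -> int:
        return len(self.traits)

    @property
    def answered(self) -> np.ndarray:
        return ~np.isnan(self.U)


@dataclass
class PredictionTrace:
    """Trial-wise model output: emitted prediction P, learning component Pm
    (equal to P except under the self-anchored mixtures), and PE = F - U
    (NaN on unanswered trials)."""

    P: np.ndarray
    Pm: np.ndarray
    PE: np.ndarray


# ---------------------------------------------------------------------------
# model specifications and parameter transforms

MODEL_PARAM_NAMES = {
    1: ("beta0", "beta1", "sigma"),
    2: ("alpha", "sigma"),
    3: ("alpha_plus", "alpha_minus", "sigma"),
    4: ("alpha", "gamma", "sigma"),
    5: ("alpha_plus", "alpha_minus", "gamma", "sigma"),
}

MODEL_LABELS = {
    1: "no learning",
    2: "fine granularity",
    3: "fine granularity (2 LR)",
    4: "self-adjusted granularity",
    5: "self-adjusted granularity (2 LR)",
}

#: transform of each parameter between the unconstrained fitting space and
#: the natural space: learning rates and gamma are logistic-bounded in (0,1),
#: sigma is log-positive, regression betas are unbounded.
_TRANSFORMS = {
    "beta0": "identity",
    "beta1": "identity",
    "alpha": "unit",
    "alpha_plus": "unit",
    "alpha_minus": "unit",
    "gamma": "unit",
    "sigma": "positive",
}


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    param_names: tuple
    label: str

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def transforms(self) -> tuple:
        return tuple(_TRANSFORMS[p] for p in self.param_names)


def get_model_spec(model_id: int) -> ModelSpec:
    if model_id not in MODEL_PARAM_NAMES:
        raise ValueError(f"unknown model id {model_id}; expected 1-5")
    return ModelSpec(model_id, MODEL_PARAM_NAMES[model_id], MODEL_LABELS[model_id])


from scipy.special import expit as _expit


def _logit(p):
    return np.log(p) - np.log1p(-p)


def to_natural(spec: ModelSpec, x: np.ndarray) -> dict:
    """Map an unconstrained parameter vector to named natural parameters."""
    out = {}
    for name, xi in zip(spec.param_names, np.asarray(x, dtype=float)):
        t = _TRANSFORMS[name]
        if t == "unit":
            out[name] = float(_expit(xi))
        elif t == "positive":
            out[name] = float(np.exp(xi))
        else:
            out[name] = float(xi)
    return out


def to_transformed(spec: ModelSpec, params: dict) -> np.ndarray:
    """Inverse of `to_natural`; validates natural-space bounds."""
    x = np.empty(spec.n_params)
    for i, name in enumerate(spec.param_names):
        v = float(params[name])
        t = _TRANSFORMS[name]
        if t == "unit":
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
            x[i] = _logit(v)
        elif t == "positive":
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            x[i] = np.log(v)
        else:
            x[i] = v
    return x


def _validate_params(spec: ModelSpec, params: dict) -> dict:
    missing = set(spec.param_names) - set(params)
    if missing:
        raise ValueError(f"model {spec.model_id} missing parameters: {sorted(missing)}")
    for name in spec.param_names:
        v = float(params[name])
        t = _TRANSFORMS[name]
        if t == "unit" and not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if t == "positive" and v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return {k: float(params[k]) for k in spec.param_names}


# ---------------------------------------------------------------------------
# similarity and feedback from a reference panel


def build_similarity_matrix(reference: RatingTable, min_pairs: int = 3) -> SimilarityMatrix:
    """Pairwise-complete Pearson correlations between trait columns of a
    reference panel; the diagonal is forced to 1."""
    df = reference.data
    for lab in df.columns:
        col = df[lab].dropna()
        if col.size == 0 or float(col.std(ddof=0)) == 0.0:
            raise ValueError(f"zero-variance reference column for trait {lab!r}")
    notna = df.notna().to_numpy(dtype=int)
    pair_counts = notna.T @ notna
    if pair_counts.min() < min_pairs:
        i, j = np.unravel_index(np.argmin(pair_counts), pair_counts.shape)
        raise ValueError(
            f"traits {df.columns[i]!r}/{df.columns[j]!r} share only "
            f"{pair_counts[i, j]} raters (< {min_pairs})"
        )
    corr = df.corr(method="pearson", min_periods=min_pairs).to_numpy()
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(list(df.columns), corr)


def compute_feedback(reference: RatingTable) -> FeedbackSchedule:
    """Feedback per trait = reference-panel column mean, rounded half-up to an
    integer score on the 1-100 display scale."""
    df = reference.data
    if df.isna().all(axis=0).any():
        lab = df.columns[df.isna().all(axis=0)][0]
        raise ValueError(f"trait {lab!r} has no reference ratings")
    means = df.mean(axis=0, skipna=True).to_numpy()
    rounded = np.floor(means + 0.5)  # round half-up
    return FeedbackSchedule(list(df.columns), np.clip(rounded, 1, 100))


# ---------------------------------------------------------------------------
# trajectory engine


def _asym_recursion(S, U, F, sim_t, init_vec, a_plus, a_minus, gamma, mixed, use_emitted):
    """Sequential update for the asymmetric-rate models (observed responses)."""
    T = S.shape[0]
    pm = init_vec.copy()
    P = np.empty(T)
    Pm = np.empty(T)
    for t in range(T):
        Pm[t] = pm[t]
        p = gamma * S[t] + (1.0 - gamma) * pm[t] if mixed else pm[t]
        P[t] = p
        u = U[t]
        if np.isnan(u):
            continue
        pe = F[t] - u
        ref = p if use_emitted else pm[t]
        a = a_plus if abs(F[t] - S[t]) < abs(ref - S[t]) else a_minus
        for j in range(T):
            pm[j] += a * pe * sim_t[t, j]
    return P, Pm


try:  # JIT the inner recursion when numba is available (pure speed-up)
    from numba import njit as _njit

    _asym_recursion = _njit(cache=True)(_asym_recursion)
except ImportError:  # pragma: no cover
    pass


def _trajectory(
    model_id: int,
    params: dict,
    S: np.ndarray,
    U: np.ndarray,
    F: np.ndarray,
    sim_t: np.ndarray,
    init_vec: np.ndarray,
    asym_compare: str = "emitted",
    rng: np.random.Generator | None = None,
    sigma_sim: float | None = None,
):
    """Shared recursion for prediction (U observed) and closed-loop simulation
    (rng given: U is drawn trial-by-trial).  Returns (P, Pm, PE, U_out)."""
    T = len(S)
    simulate = rng is not None
    U_out = np.array(U, dtype=float, copy=True)

    if model_id == 1:
        P = params["beta0"] + params["beta1"] * S
        if simulate:
            U_out = _draw_responses(P, sigma_sim, rng)
        PE = F - U_out
        PE[np.isnan(U_out)] = np.nan
        return P, P.copy(), PE, U_out

    two_rates = model_id in (3, 5)
    mixed = model_id in (4, 5)
    gamma = params["gamma"] if mixed else 0.0
    a_plus = params["alpha_plus"] if two_rates else params["alpha"]
    a_minus = params["alpha_minus"] if two_rates else params["alpha"]

    if not two_rates and not simulate:
        # learning rate is constant and PE is data: Pm is linear in alpha
        pe = F - U_out
        pe_w = np.where(np.isnan(pe), 0.0, pe)
        spread = np.triu(pe_w[:, None] * sim_t, k=1).sum(axis=0)
        Pm = init_vec + a_plus * spread
        P = gamma * S + (1.0 - gamma) * Pm if mixed else Pm
        PE = np.where(np.isnan(U_out), np.nan, pe)
        return P, Pm, PE, U_out

    if two_rates and not simulate:
        P, Pm = _asym_recursion(
            S, U_out, F, sim_t, init_vec.astype(float), a_plus, a_minus,
            gamma, mixed, asym_compare == "emitted",
        )
        PE = np.where(np.isnan(U_out), np.nan, F - U_out)
        return P, Pm, PE, U_out

    pm = init_vec.astype(float).copy()
    P = np.empty(T)
    Pm = np.empty(T)
    PE = np.full(T, np.nan)
    abs_fs = np.abs(F - S)
    for t in range(T):
        Pm[t] = pm[t]
        P[t] = gamma * S[t] + (1.0 - gamma) * pm[t] if mixed else pm[t]
        if simulate:
            U_out[t] = _draw_responses(np.array([P[t]]), sigma_sim, rng)[0]
        u = U_out[t]
        if np.isnan(u):
            continue
        pe = F[t] - u
        PE[t] = pe
        if two_rates:
            ref = P[t] if asym_compare == "emitted" else Pm[t]
            a_eff = a_plus if abs_fs[t] < abs(ref - S[t]) else a_minus
        else:
            a_eff = a_plus
        pm = pm + a_eff * pe * sim_t[t]
    return P, Pm, PE, U_out


def _draw_responses(P, sigma, rng):
    """Slider responses: Gaussian around P, clipped to [1, 100], integer."""
    u = P + rng.normal(0.0, 1.0, size=P.shape) * sigma if sigma > 0 else P.copy()
    return np.clip(np.round(u), 1, 100).astype(float)


# ---------------------------------------------------------------------------
# statsmodels-style per-subject model


class TraitUtilityModel:
    """One subject's learning session under one of the five generative models.

    Parameters
    ----------
    session : LearningSession
    similarity : SimilarityMatrix
        Inter-trait similarity; ignored by Model 1.
    model_id : int in 1..5
    init : {"constant", "self"}
        Initial prediction for every trait: the constant ``p_init`` (default
        80, high expectations toward shared utility perceptions), or the
        subject's own self rating of that trait (supplementary variant).
    asym_compare : {"emitted", "component"}
        For the asymmetric-rate models, whether the rate-selection condition
        |F - S| < |P - S| compares at the emitted prediction (default) or at
        the learning component Pm.
    sigma_fixed : float, optional
        Fix the response sd instead of fitting it (drops sigma from the free
        parameter vector).
    """

    def __init__(
        self,
        session: LearningSession,
        similarity: SimilarityMatrix | None,
        model_id: int,
        init: str = "constant",
        asym_compare: str = "emitted",
        sigma_fixed: float | None = None,
    ):
        self.session = session
        self.spec = get_model_spec(model_id)
        self.model_id = model_id
        if init not in ("constant", "self"):
            raise ValueError("init must be 'constant' or 'self'")
        if asym_compare not in ("emitted", "component"):
            raise ValueError("asym_compare must be 'emitted' or 'component'")
        self.init = init
        self.asym_compare = asym_compare
        if model_id != 1:
            if similarity is None:
                raise ValueError(f"model {model_id} requires a similarity matrix")
            self.sim_t = similarity.submatrix(session.traits)
        else:
            self.sim_t = None
        self.similarity = similarity
        self._init_vec = (
            session.S.copy() if init == "self" else np.full(session.n_trials, session.p_init)
        )
        if sigma_fixed is not None and sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be positive")
        self.sigma_fixed = sigma_fixed
        self.free_names = tuple(
            n for n in self.spec.param_names if not (n == "sigma" and sigma_fixed is not None)
        )

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def params_from_free(self, x: np.ndarray) -> dict:
        """Natural parameter dict from the unconstrained free vector."""
        out = {}
        for name, xi in zip(self.free_names, np.asarray(x, dtype=float)):
            t = _TRANSFORMS[name]
            out[name] = float(_expit(xi)) if t == "unit" else (
                float(np.exp(xi)) if t == "positive" else float(xi)
            )
        if self.sigma_fixed is not None:
            out["sigma"] = float(self.sigma_fixed)
        return out

    def free_from_params(self, params: dict) -> np.ndarray:
        full = to_transformed(self.spec, {**params, **(
            {"sigma": self.sigma_fixed} if self.sigma_fixed is not None else {})})
        keep = [i for i, n in enumerate(self.spec.param_names) if n in self.free_names]
        return full[keep]

    def loglike_free(self, x: np.ndarray) -> float:
        return self.loglike(self.params_from_free(x))

    # -- forward predictions -------------------------------------------------

    def predict(self, params: dict) -> PredictionTrace:
        p = _validate_params(self.spec, params)
        P, Pm, PE, _ = _trajectory(
            self.model_id, p, self.session.S, self.session.U, self.session.F,
            self.sim_t, self._init_vec, self.asym_compare,
        )
        return PredictionTrace(P, Pm, PE)

    def loglike(self, params: dict) -> float:
        """Gaussian log-likelihood of the answered responses at sd sigma.

        Responses are treated as continuous; clipping at the slider bounds is
        ignored in the likelihood.
        """
        p = _validate_params(self.spec, params)
        sigma = p["sigma"]
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        mask = self.session.answered
        if not mask.any():
            raise ValueError("session has no answered trials")
        trace = self.predict(p)
        resid = self.session.U[mask] - trace.P[mask]
        n = resid.size
        return float(
            -0.5 * n * np.log(2.0 * np.pi * sigma**2) - 0.5 * np.sum(resid**2) / sigma**2
        )

    def loglike_transformed(self, x: np.ndarray) -> float:
        return self.loglike(to_natural(self.spec, x))

    # -- simulation ----------------------------------------------------------

    def simulate(self, params: dict, seed=None, rng=None) -> LearningSession:
        """Closed-loop simulation: each trial's response is drawn around the
        model's prediction given the *simulated* history, clipped to [1, 100]
        and rounded to the integer slider output."""
        p = _validate_params(self.spec, params)
        if rng is None:
            rng = np.random.default_rng(seed)
        U_blank = np.full(self.session.n_trials, np.nan)
        _, _, _, U_sim = _trajectory(
            self.model_id, p, self.session.S, U_blank, self.session.F,
            self.sim_t, self._init_vec, self.asym_compare,
            rng=rng, sigma_sim=p["sigma"],
        )
        return replace(self.session, U=U_sim)

    def fit(self, prior=None, n_restarts: int = 10, seed: int = 0, start=None):
        from .inference import fit_subject_map  # lazy: avoids a cycle

        return fit_subject_map(
            self, prior=prior, n_restarts=n_restarts, seed=seed, start=start
        )


# ---------------------------------------------------------------------------
# functional surface


def predict_trajectory(model_id: int, params: dict, session: LearningSession,
                       similarity: SimilarityMatrix | None = None, **kwargs) -> PredictionTrace:
    return TraitUtilityModel(session, similarity, model_id, **kwargs).predict(params)


def model_loglik(model_id: int, params: dict, session: LearningSession,
                 similarity: SimilarityMatrix | None = None, **kwargs) -> float:
    return TraitUtilityModel(session, similarity, model_id, **kwargs).loglike(params)


def simulate_subject(model_id: int, params: dict, frame: LearningSession,
                     similarity: SimilarityMatrix | None = None, seed=None, **kwargs) -> LearningSession:
    """Simulate a session on a frame (trait order, S, F, p_init); frame.U is ignored."""
    return TraitUtilityModel(frame, similarity, model_id, **kwargs).simulate(params, seed=seed)


# ---------------------------------------------------------------------------
# session CSV I/O (long format: subject_id, trial, trait, S, U, F)


def read_sessions(path, p_init: float = DEFAULT_P_INIT) -> list[LearningSession]:
    df = pd.read_csv(path)
    required = {"subject_id", "trial", "trait", "S", "U", "F"}
    if not required.issubset(df.columns):
        raise ValueError(f"session CSV must have columns {sorted(required)}")
    sessions = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("trial")
        sessions.append(
            LearningSession(
                sid, list(g["trait"]),
                g["S"].to_numpy(float), g["U"].to_numpy(float), g["F"].to_numpy(float),
                p_init=p_init,
            )
        )
    return sessions


def write_sessions(sessions, path) -> None:
    rows = []
    for s in sessions:
        for t in range(s.n_trials):
            rows.append(
                {"subject_id": s.subject_id, "trial": t + 1, "trait": s.traits[t],
                 "S": s.S[t], "U": s.U[t], "F": s.F[t]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
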