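"""Synthetic cohorts emulating the three study designs.

Three generators cover the data structures the analysis stages consume:

* a reference panel of raters with correlated trait columns (latent-factor
  model), from which similarity matrices and feedback schedules are built;
* survey cohorts with a known linear link from self-utility distance (SUD)
  and a latent esteem factor to clarity/esteem questionnaire scores;
* closed-loop learning cohorts generated from any of the five learning
  models, with the generating parameters persisted for oracle tests.

All generators are fully seeded; ground truth (offsets, parameters, model
identity) is always returned alongside the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .learning import (
    FeedbackSchedule,
    LearningSession,
    SimilarityMatrix,
    TraitUtilityModel,
    build_similarity_matrix,
    compute_feedback,
)
from .ratings import RatingTable

__all__ = [
    "SyntheticCohortSpec",
    "SurveyCohort",
    "gen_reference_panel",
    "gen_survey_cohort",
    "gen_learning_cohort",
    "trait_labels",
]

logger = logging.getLogger(__name__)


def trait_labels(k: int) -> list[str]:
    """Placeholder adjective labels (the published 50-word lexicon can be
    substituted wherever labels are accepted)."""
    return [f"trait_{i + 1:02d}" for i in range(k)]


@dataclass
class SyntheticCohortSpec:
    """Study conditions for the generators.

    The defaults follow the study design: 50 traits per session, a 232-rater
    reference panel, 85-subject learning cohorts, initial prediction 80.
    Survey-link coefficients are calibrated so that SUD correlates with the
    clarity score at roughly -0.55 and with the esteem factor at roughly
    -0.46 in large cohorts.
    """

    n_subjects: int
    n_traits: int = 50
    n_reference: int = 232
    n_factors: int = 5
    loading_scale: float = 6.0
    panel_noise_sd: float = 10.0
    model_id: int = 4
    seed: int = 0
    sigma: float | None = None          # overrides the sampler's sigma when set
    miss_prob: float = 0.0
    p_init: float = 80.0
    # survey link: SCC_raw = a0 - a_sud * SUD + a_se * esteem + N(0, noise_sd)
    a0: float = 45.0
    a_sud: float = 0.50
    a_se: float = 4.5
    scc_noise_sd: float = 7.5
    esteem_sud_corr: float = 0.52
    sud_scale_range: tuple = (5.0, 35.0)
    self_range: tuple = (30, 70)

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_traits", "n_reference", "n_factors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ValueError("miss_prob must lie in [0, 1)")


# ---------------------------------------------------------------------------
# reference panel


def gen_reference_panel(
    n_traits: int = 50,
    n_ref: int = 232,
    n_factors: int = 5,
    seed: int = 0,
    loading_scale: float = 6.0,
    noise_sd: float = 10.0,
    valence_loading: float = 12.0,
    trait_mean_spread: float = 8.0,
    loadings: np.ndarray | None = None,
) -> RatingTable:
    """Latent-factor rating panel: rating = clip(round(mu_k + L f + eps), 1, 100).

    The trait list the generators emulate is half positive, half negative
    adjectives, and utility ratings of valenced traits are dominated by a
    bipolar evaluative factor: positive traits are judged useful, negative
    ones not, and raters differ in how strongly they polarise.  The first
    latent factor therefore carries signed loadings of magnitude
    ``valence_loading`` (+ for the first half of the traits, - for the second
    half); the remaining ``n_factors - 1`` factors carry weaker unstructured
    loadings (sd ``loading_scale``), giving a realistic spread of positive
    and negative inter-trait correlations within and across valence.
    Per-trait means mu_k = 50 + valence_k * ``trait_mean_spread`` + noise
    make feedback values span the scale.  Passing explicit ``loadings``
    ((n_traits, n_factors)) bypasses the valence structure entirely.
    """
    if n_ref < 10:
        raise ValueError("a reference panel needs at least 10 raters")
    if n_factors > n_traits:
        raise ValueError("n_factors cannot exceed the number of traits")
    rng = np.random.default_rng(seed)
    valence = np.where(np.arange(n_traits) < (n_traits + 1) // 2, 1.0, -1.0)
    if loadings is None:
        loadings = rng.normal(0.0, loading_scale, size=(n_traits, n_factors))
        loadings[:, 0] = valence * np.abs(rng.normal(valence_loading, 3.0, size=n_traits))
        mu = 50.0 + valence * trait_mean_spread + rng.normal(0.0, 5.0, size=n_traits)
    else:
        loadings = np.asarray(loadings, dtype=float)
        if loadings.shape != (n_traits, n_factors):
            raise ValueError(f"loadings must be ({n_traits}, {n_factors})")
        mu = np.full(n_traits, 50.0)
    factors = rng.normal(size=(n_ref, n_factors))
    noise = rng.normal(0.0, noise_sd, size=(n_ref, n_traits))
    ratings = np.clip(np.round(mu + factors @ loadings.T + noise), 1, 100)
    df = pd.DataFrame(ratings, columns=trait_labels(n_traits),
                      index=[f"rater_{i + 1:03d}" for i in range(n_ref)])
    return RatingTable(df, "reference")


# ---------------------------------------------------------------------------
# survey cohorts


@dataclass
class SurveyCohort:
    tables: dict                    # block -> RatingTable (self/utility/ideal/ought)
    scores: pd.DataFrame            # per subject: SCC, SE, true_SUD and friends
    offsets: dict                   # block -> DataFrame of applied offsets


def _offset_block(rng, self_vals, scales, dist_scale=1.0):
    """Per-trait Laplace offsets, truncated so self + offset stays in [1, 100];
    the *applied* offsets are returned, so mean |offset| is exact ground truth."""
    n, k = self_vals.shape
    raw = rng.laplace(0.0, 1.0, size=(n, k)) * (scales[:, None] * dist_scale)
    return np.clip(raw, 1.0 - self_vals, 100.0 - self_vals)


def gen_survey_cohort(spec: SyntheticCohortSpec) -> SurveyCohort:
    """Self/utility/ideal/ought tables plus questionnaire scores.

    The utility profile is the self profile plus per-trait offsets, so each
    subject's true SUD (mean |offset|) is known exactly.  A latent esteem
    factor correlated with SUD drives the esteem score; the clarity score
    follows the configured linear link and is discretised onto the 12-60 summed
    scale (esteem onto 10-40).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.n_traits
    labels = trait_labels(k)
    subjects = [f"subj_{i + 1:04d}" for i in range(n)]

    lo, hi = spec.self_range
    self_vals = rng.integers(lo, hi + 1, size=(n, k)).astype(float)
    scales = rng.uniform(*spec.sud_scale_range, size=n)

    offsets = {b: _offset_block(rng, self_vals, scales, d)
               for b, d in (("utility", 1.0), ("ideal", 0.9), ("ought", 0.8))}
    tables = {"self": RatingTable(pd.DataFrame(self_vals, index=subjects, columns=labels), "self")}
    for block, delta in offsets.items():
        tables[block] = RatingTable(
            pd.DataFrame(self_vals + delta, index=subjects, columns=labels), block
        )

    true_sud = np.abs(offsets["utility"]).mean(axis=1)
    z_sud = (true_sud - true_sud.mean()) / true_sud.std() if true_sud.std() > 0 else np.zeros(n)
    c = spec.esteem_sud_corr
    esteem = -c * z_sud + np.sqrt(max(0.0, 1.0 - c**2)) * rng.normal(size=n)

    scc_raw = spec.a0 - spec.a_sud * true_sud + spec.a_se * esteem \
        + rng.normal(0.0, spec.scc_noise_sd, size=n)
    se_raw = 25.0 + 4.0 * esteem + rng.normal(0.0, 2.0, size=n)
    out_of_range = np.mean((scc_raw < 12) | (scc_raw > 60))
    if out_of_range > 0.05:
        logger.warning("survey link puts %.1f%% of clarity scores out of range; "
                       "they will be clipped", 100 * out_of_range)
    scc = np.clip(np.round(scc_raw), 12, 60)
    se = np.clip(np.round(se_raw), 10, 40)

    scores = pd.DataFrame(
        {"SCC": scc, "SE": se, "true_SUD": true_sud, "esteem_latent": esteem},
        index=subjects,
    )
    offset_frames = {b: pd.DataFrame(v, index=subjects, columns=labels)
                     for b, v in offsets.items()}
    return SurveyCohort(tables, scores, offset_frames)


# ---------------------------------------------------------------------------
# learning cohorts


def gen_learning_cohort(
    spec: SyntheticCohortSpec,
    panel: RatingTable,
    param_sampler=None,
    feedback: FeedbackSchedule | None = None,
    similarity: SimilarityMatrix | None = None,
):
    """Closed-loop learning sessions from one generating model.

    Per subject: a random trait order, a fresh self profile, parameters drawn
    from ``param_sampler``, and a simulated session via the model's own
    closed-loop simulator.  Returns (sessions, true-parameter DataFrame,
    similarity matrix).
    """
    from .inference import default_param_sampler

    if param_sampler is None:
        param_sampler = default_param_sampler(spec.model_id)
    if similarity is None:
        similarity = build_similarity_matrix(panel)
    if feedback is None:
        feedback = compute_feedback(panel)
    rng = np.random.default_rng(spec.seed)
    labels = list(panel.data.columns)
    if len(labels) != spec.n_traits:
        raise ValueError("panel trait count does not match the cohort spec")

    sessions, rows, index = [], [], []
    lo, hi = spec.self_range
    for i in range(spec.n_subjects):
        sid = f"subj_{i + 1:04d}"
        params = dict(param_sampler(rng))
        if spec.sigma is not None:
            params["sigma"] = float(spec.sigma)
        order = rng.permutation(spec.n_traits)
        traits = [labels[j] for j in order]
        s = rng.integers(lo, hi + 1, size=spec.n_traits).astype(float)
        f = np.array([feedback.value_for(t) for t in traits])
        frame = LearningSession(sid, traits, s, np.full(spec.n_traits, np.nan),
                                f, p_init=spec.p_init)
        model = TraitUtilityModel(frame, similarity, spec.model_id)
        session = model.simulate(params, rng=rng)
        if spec.miss_prob > 0:
            miss = rng.random(spec.n_traits) < spec.miss_prob
            u = session.U.copy()
            u[miss] = np.nan
            session = LearningSession(sid, traits, s, u, f, p_init=spec.p_init)
        sessions.append(session)
        rows.append(params)
        index.append(sid)
    true_df = pd.DataFrame(rows, index=index)
    return sessions, true_df, similarity
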