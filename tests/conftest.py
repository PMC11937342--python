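import numpy as np
import pandas as pd
import pytest

from sudlearn.learning import LearningSession, SimilarityMatrix, build_similarity_matrix
from sudlearn.synthetic import gen_reference_panel


@pytest.fixture(scope="session")
def panel():
    """Valence-structured 232-rater reference panel over 50 traits."""
    return gen_reference_panel(n_traits=50, n_ref=232, seed=900001)


@pytest.fixture(scope="session")
def similarity(panel):
    return build_similarity_matrix(panel)


@pytest.fixture(scope="session")
def toy_similarity():
    """Deterministic 12-trait similarity with smooth positive structure."""
    k = 12
    m = np.eye(k)
    for i in range(k):
        for j in range(k):
            if i != j:
                m[i, j] = 0.5 * np.exp(-abs(i - j) / 3.0)
    return SimilarityMatrix([f"x{i}" for i in range(k)], m)


def make_session(seed=0, k=12, subject_id="s1", p_init=80.0, missing=()):
    """Deterministic hand-rolled session on k traits."""
    rng = np.random.default_rng(seed)
    S = rng.integers(20, 81, k).astype(float)
    U = rng.integers(10, 91, k).astype(float)
    F = rng.integers(30, 71, k).astype(float)
    for t in missing:
        U[t] = np.nan
    return LearningSession(subject_id, [f"x{i}" for i in range(k)], S, U, F, p_init=p_init)


@pytest.fixture
def session():
    return make_session(seed=3)


@pytest.fixture
def rating_frame():
    return pd.DataFrame(
        [[50.0, 60.0, 70.0], [40.0, np.nan, 90.0]],
        index=["a", "b"],
        columns=["kind", "lazy", "honest"],
    )
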