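import numpy as np
import pandas as pd
import pytest

from sudlearn.learning import (
    LearningSession,
    SimilarityMatrix,
    TraitUtilityModel,
    build_similarity_matrix,
    compute_feedback,
    get_model_spec,
    read_sessions,
    to_natural,
    to_transformed,
    write_sessions,
)
from sudlearn.ratings import RatingTable

from conftest import make_session


def ref_table(values, cols):
    idx = [f"r{i}" for i in range(len(values))]
    return RatingTable(pd.DataFrame(values, index=idx, columns=cols), "reference")


class TestSimilarity:
    def test_identical_columns_correlate_one(self):
        vals = np.column_stack([np.arange(10, 30, 2.0)] * 2 + [np.linspace(5, 95, 10)])
        sim = build_similarity_matrix(ref_table(vals, ["a", "b", "c"]))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_reflected_column_correlates_minus_one(self):
        x = np.arange(10, 30, 2.0)
        sim = build_similarity_matrix(ref_table(np.column_stack([x, 101 - x]), ["a", "b"]))
        assert sim.values[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(9)
        vals = np.clip(rng.normal(50, 15, size=(5000, 2)).round(), 1, 100)
        sim = build_similarity_matrix(ref_table(vals, ["a", "b"]))
        assert abs(sim.values[0, 1]) < 0.05

    def test_zero_variance_column_rejected(self):
        vals = np.column_stack([np.full(10, 50.0), np.arange(1.0, 11)])
        with pytest.raises(ValueError, match="flat"):
            build_similarity_matrix(ref_table(vals, ["flat", "b"]))

    def test_symmetric_unit_diagonal_enforced(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            SimilarityMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))


class TestFeedback:
    @pytest.mark.parametrize(
        "column, expected",
        [([60, 70, 80], 70), ([60, 61], 61), ([50, np.nan, 70], 60)],
    )
    def test_column_mean_rounded_half_up(self, column, expected):
        vals = np.column_stack([column, np.linspace(20, 80, len(column))])
        fb = compute_feedback(ref_table(vals, ["a", "b"]))
        assert fb.value_for("a") == expected

    def test_all_missing_column_rejected(self):
        vals = np.column_stack([[np.nan, np.nan], [50.0, 60.0]])
        with pytest.raises(ValueError, match="a"):
            compute_feedback(ref_table(vals, ["a", "b"]))


class TestTransforms:
    @pytest.mark.parametrize("model_id", [1, 2, 3, 4, 5])
    def test_round_trip(self, model_id):
        spec = get_model_spec(model_id)
        rng = np.random.default_rng(model_id)
        x = rng.normal(size=spec.n_params)
        x2 = to_transformed(spec, to_natural(spec, x))
        np.testing.assert_allclose(x, x2, atol=1e-10)

    def test_bounds_enforced(self):
        spec = get_model_spec(4)
        with pytest.raises(ValueError):
            to_transformed(spec, {"alpha": 1.5, "gamma": 0.3, "sigma": 5.0})


class TestPredictions:
    def test_no_learning_when_alpha_zero(self, toy_similarity):
        sess = make_session(seed=1)
        for mid, params in ((2, {"alpha": 0.0, "sigma": 5.0}),
                            (3, {"alpha_plus": 0.0, "alpha_minus": 0.0, "sigma": 5.0})):
            trace = TraitUtilityModel(sess, toy_similarity, mid).predict(params)
            np.testing.assert_array_equal(trace.Pm, np.full(12, 80.0))

    def test_worked_spread_example(self):
        """A PE of 30 spread through similarity 0.5 at unit learning rate
        moves the next trait's prediction from 80 to 95."""
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        sess = LearningSession("w", ["a", "b"], np.array([50.0, 50.0]),
                               np.array([30.0, np.nan]), np.array([60.0, 70.0]))
        trace = TraitUtilityModel(sess, sim, 2).predict({"alpha": 1.0, "sigma": 5.0})
        assert trace.Pm[1] == pytest.approx(95.0)
        assert trace.PE[0] == pytest.approx(30.0)

    def test_gamma_one_copies_self_ratings(self, toy_similarity):
        sess = make_session(seed=2)
        trace = TraitUtilityModel(sess, toy_similarity, 4).predict(
            {"alpha": 0.4, "gamma": 1.0, "sigma": 5.0}
        )
        np.testing.assert_allclose(trace.P, sess.S)

    def test_linear_model_is_linear_readout(self, session):
        trace = TraitUtilityModel(session, None, 1).predict(
            {"beta0": 5.0, "beta1": 0.7, "sigma": 5.0}
        )
        np.testing.assert_allclose(trace.P, 5.0 + 0.7 * session.S)

    def test_identity_similarity_means_no_spread(self):
        sess = make_session(seed=5)
        sim = SimilarityMatrix(sess.traits, np.eye(12))
        trace = TraitUtilityModel(sess, sim, 2).predict({"alpha": 0.8, "sigma": 5.0})
        np.testing.assert_array_equal(trace.Pm, np.full(12, 80.0))

    def test_self_initialization_with_zero_rate_tracks_self(self, toy_similarity):
        sess = make_session(seed=6)
        trace = TraitUtilityModel(sess, toy_similarity, 2, init="self").predict(
            {"alpha": 0.0, "sigma": 5.0}
        )
        np.testing.assert_allclose(trace.Pm, sess.S)

    def test_mixture_identity_holds_exactly(self, toy_similarity):
        sess = make_session(seed=7)
        params = {"alpha_plus": 0.5, "alpha_minus": 0.1, "gamma": 0.35, "sigma": 5.0}
        trace = TraitUtilityModel(sess, toy_similarity, 5).predict(params)
        np.testing.assert_allclose(
            trace.P, 0.35 * sess.S + 0.65 * trace.Pm, atol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reduction_chain(self, toy_similarity, seed):
        """Nested models coincide trial-by-trial at their boundary values:
        equal rates collapse 3 -> 2 and 5 -> 4; gamma = 0 collapses 4 -> 2
        and 5 -> 3."""
        sess = make_session(seed=seed, missing=(4,))
        p2 = TraitUtilityModel(sess, toy_similarity, 2).predict({"alpha": 0.3, "sigma": 5.0})
        p3 = TraitUtilityModel(sess, toy_similarity, 3).predict(
            {"alpha_plus": 0.3, "alpha_minus": 0.3, "sigma": 5.0})
        p4 = TraitUtilityModel(sess, toy_similarity, 4).predict(
            {"alpha": 0.3, "gamma": 0.0, "sigma": 5.0})
        p5e = TraitUtilityModel(sess, toy_similarity, 5).predict(
            {"alpha_plus": 0.3, "alpha_minus": 0.3, "gamma": 0.0, "sigma": 5.0})
        p5g = TraitUtilityModel(sess, toy_similarity, 5).predict(
            {"alpha_plus": 0.3, "alpha_minus": 0.3, "gamma": 0.4, "sigma": 5.0})
        p4g = TraitUtilityModel(sess, toy_similarity, 4).predict(
            {"alpha": 0.3, "gamma": 0.4, "sigma": 5.0})
        for other in (p3, p4, p5e):
            np.testing.assert_allclose(p2.P, other.P, atol=1e-10)
        np.testing.assert_allclose(p4g.P, p5g.P, atol=1e-10)

    def test_relabeling_invariance(self, toy_similarity):
        sess = make_session(seed=8)
        params = {"alpha": 0.4, "sigma": 5.0}
        base = TraitUtilityModel(sess, toy_similarity, 2).predict(params)
        # permute trait identities consistently in the session and the matrix
        perm = np.random.default_rng(0).permutation(12)
        new_labels = [f"y{i}" for i in range(12)]
        relabeled = SimilarityMatrix(
            [new_labels[np.where(perm == i)[0][0]] for i in range(12)],
            toy_similarity.values,
        )
        sess2 = LearningSession(
            "s1", [new_labels[np.where(perm == i)[0][0]] for i in range(12)],
            sess.S, sess.U, sess.F,
        )
        other = TraitUtilityModel(sess2, relabeled, 2).predict(params)
        np.testing.assert_allclose(base.Pm, other.Pm)


class TestLoglik:
    def test_zero_residuals_closed_form(self, toy_similarity):
        # alpha = 0 keeps P at 80 on every trial, so U = 80 gives zero
        # residuals and the log-likelihood collapses to -(T/2) log(2 pi s^2)
        base = make_session(seed=9)
        sess = LearningSession("s1", base.traits, base.S, np.full(12, 80.0), base.F)
        ll = TraitUtilityModel(sess, toy_similarity, 2).loglike({"alpha": 0.0, "sigma": 10.0})
        assert ll == pytest.approx(-(12 / 2) * np.log(2 * np.pi * 100.0))

    def test_three_trial_hand_computation(self):
        sim = SimilarityMatrix(["a", "b", "c"], np.eye(3))
        sess = LearningSession("h", ["a", "b", "c"], np.array([50.0, 50, 50]),
                               np.array([70.0, 85.0, 75.0]), np.array([60.0, 60, 60]))
        ll = TraitUtilityModel(sess, sim, 2).loglike({"alpha": 0.0, "sigma": 10.0})
        resid = np.array([70.0, 85.0, 75.0]) - 80.0
        expected = float(np.sum(-0.5 * np.log(2 * np.pi * 100) - resid**2 / 200.0))
        assert ll == pytest.approx(expected)

    def test_dropping_a_response_removes_exactly_its_term(self, toy_similarity):
        sess = make_session(seed=10)
        params = {"alpha": 0.0, "sigma": 8.0}  # no learning: trials independent
        model = TraitUtilityModel(sess, toy_similarity, 2)
        full = model.loglike(params)
        t = 5
        trace = model.predict(params)
        term = (-0.5 * np.log(2 * np.pi * 64.0)
                - (sess.U[t] - trace.P[t]) ** 2 / (2 * 64.0))
        dropped = make_session(seed=10, missing=(t,))
        ll = TraitUtilityModel(dropped, toy_similarity, 2).loglike(params)
        assert ll == pytest.approx(full - term)

    def test_sigma_must_be_positive(self, session, toy_similarity):
        with pytest.raises(ValueError):
            TraitUtilityModel(session, toy_similarity, 2).loglike({"alpha": 0.2, "sigma": 0.0})


class TestSimulation:
    def test_noiseless_simulation_emits_clipped_rounded_predictions(self, toy_similarity):
        frame = make_session(seed=11)
        model = TraitUtilityModel(frame, toy_similarity, 2)
        sim_sess = model.simulate({"alpha": 0.3, "sigma": 0.0}, seed=1)
        # closed loop: recompute predictions from the simulated responses
        trace = TraitUtilityModel(sim_sess, toy_similarity, 2).predict(
            {"alpha": 0.3, "sigma": 0.0})
        np.testing.assert_array_equal(sim_sess.U, np.clip(np.round(trace.P), 1, 100))

    def test_seed_reproducibility(self, toy_similarity):
        frame = make_session(seed=12)
        model = TraitUtilityModel(frame, toy_similarity, 2)
        a = model.simulate({"alpha": 0.3, "sigma": 8.0}, seed=5)
        b = model.simulate({"alpha": 0.3, "sigma": 8.0}, seed=5)
        c = model.simulate({"alpha": 0.3, "sigma": 8.0}, seed=6)
        np.testing.assert_array_equal(a.U, b.U)
        assert not np.array_equal(a.U, c.U)

    def test_self_copy_limit(self, toy_similarity):
        frame = make_session(seed=13)
        sim_sess = TraitUtilityModel(frame, toy_similarity, 4).simulate(
            {"alpha": 0.3, "gamma": 1.0, "sigma": 0.0}, seed=2)
        np.testing.assert_array_equal(sim_sess.U, frame.S)


class TestSessionIO:
    def test_round_trip(self, tmp_path):
        sessions = [make_session(seed=s, subject_id=f"p{s}", missing=(2,)) for s in range(3)]
        path = tmp_path / "sessions.csv"
        write_sessions(sessions, path)
        back = read_sessions(path)
        assert len(back) == 3
        for a, b in zip(sessions, back):
            assert a.traits == b.traits
            np.testing.assert_array_equal(a.S, b.S)
            np.testing.assert_array_equal(a.F, b.F)
            np.testing.assert_array_equal(np.isnan(a.U), np.isnan(b.U))

    def test_each_trait_exactly_once(self):
        with pytest.raises(ValueError, match="exactly once"):
            LearningSession("x", ["a", "a"], np.array([50.0, 50]),
                            np.array([50.0, 50]), np.array([50.0, 50]))
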