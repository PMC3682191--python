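"""Unit and property tests for estimation, whitening and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from repdim.core import (
    PatternDataset,
    between_class_cov_white,
    classify_full,
    classify_reduced,
    crossval_accuracy_curve,
    discriminative_directions,
    estimate_means,
    estimate_within_cov,
    fit_classifier,
    project_to_feature_space,
    whitening_transform,
)
from repdim.simulate import (
    SimConfig,
    make_random_features,
    simulate_dataset,
)


def _random_spd(rng, p):
    A = rng.standard_normal((p, p))
    return A @ A.T + p * np.eye(p) * 0.1


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------

class TestPatternDataset:
    def test_rejects_missing_condition_in_run(self):
        with pytest.raises(ValueError, match="missing condition"):
            PatternDataset(np.zeros((3, 2)), [1, 2, 1], [1, 1, 2])

    def test_rejects_single_condition(self):
        with pytest.raises(ValueError, match="K = 2"):
            PatternDataset(np.zeros((2, 2)), [1, 1], [1, 2])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            PatternDataset(np.array([[np.nan], [1.0]]), [1, 2], [1, 1])

    def test_rejects_label_length_mismatch(self):
        with pytest.raises(ValueError, match="condition"):
            PatternDataset(np.zeros((3, 1)), [1, 2], [1, 1, 1])


# ---------------------------------------------------------------------------
# means and covariance
# ---------------------------------------------------------------------------

class TestMeansAndCovariance:
    def test_hand_means(self, tiny_dataset):
        assert np.array_equal(estimate_means(tiny_dataset).ravel(), [2.0, 3.0])

    def test_single_trial_per_class_returns_trials(self, rng):
        vals = rng.standard_normal((3, 4))
        ds = PatternDataset(vals, [1, 2, 3], [1, 1, 1])
        assert np.allclose(estimate_means(ds), vals)

    def test_missing_condition_in_subset_is_named(self, tiny_dataset):
        with pytest.raises(ValueError, match="condition 2"):
            estimate_means(tiny_dataset, trials=np.array([True, False, True, False]))

    def test_means_converge_to_true_means(self, rng):
        # many runs, strong signal: estimated means approach sum_d u_d f_k^d
        spec = make_random_features(4, 2, rng)
        cfg = SimConfig(P=10, n_runs=400, sigma_a2=2.0)
        sd = simulate_dataset(spec, cfg, rng)
        est = estimate_means(sd.data)
        err = np.abs(est - sd.true_means).max()
        assert err < 4.0 / np.sqrt(400)  # ~3 SEs of the trial mean

    def test_hand_pooled_scatter_and_regularization(self, tiny_dataset):
        # per-class scatter 2 each, dof (2-1)*2 = 2 -> 2.0; +1% of diag -> 2.02
        cov = estimate_within_cov(tiny_dataset)
        assert cov.shape == (1, 1)
        assert np.isclose(cov[0, 0], 2.02)
        raw = estimate_within_cov(tiny_dataset, reg_fraction=0.0)
        assert np.isclose(raw[0, 0], 2.0)

    def test_identical_trials_give_zero_scatter(self):
        ds = PatternDataset(
            np.array([[1.0, 2.0]] * 2 + [[3.0, 1.0]] * 2),
            [1, 1, 2, 2], [1, 2, 1, 2],
        )
        raw = estimate_within_cov(ds, reg_fraction=0.0)
        assert np.allclose(raw, 0.0)
        with pytest.warns(RuntimeWarning, match="identically zero"):
            cov = estimate_within_cov(ds)
        assert np.all(np.diag(cov) > 0)

    def test_matches_textbook_pooled_covariance_oracle(self, rng):
        # independent naive loop implementation, no regularization
        vals = rng.standard_normal((24, 5))
        cond = np.repeat([1, 2, 3], 8)
        run = np.tile([1, 2], 12)
        ds = PatternDataset(vals, cond, run)
        scatter = np.zeros((5, 5))
        dof = 0
        for k in (1, 2, 3):
            X = vals[cond == k]
            mu = X.mean(axis=0)
            for x in X:
                d = (x - mu)[:, None]
                scatter += d @ d.T
            dof += len(X) - 1
        assert np.allclose(estimate_within_cov(ds, reg_fraction=0.0),
                           scatter / dof)


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

class TestWhitening:
    def test_identity_and_diagonal_closed_forms(self):
        assert np.allclose(whitening_transform(np.eye(3)), np.eye(3))
        assert np.allclose(whitening_transform(np.diag([4.0, 9.0])),
                           np.diag([0.5, 1.0 / 3.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(p=st.integers(2, 40), seed=st.integers(0, 2**31 - 1))
    def test_whitening_identity_property(self, p, seed):
        cov = _random_spd(np.random.default_rng(seed), p)
        W = whitening_transform(cov)
        assert np.allclose(W, W.T)
        assert np.allclose(W @ cov @ W, np.eye(p), atol=1e-8)

    def test_whitening_identity_large(self, rng):
        cov = _random_spd(rng, 200)
        W = whitening_transform(cov)
        assert np.abs(W @ cov @ W - np.eye(200)).max() < 1e-8

    def test_near_singular_matrix_is_floored(self):
        cov = np.diag([1.0, 1e-30])
        with pytest.warns(RuntimeWarning, match="clipped"):
            W = whitening_transform(cov)
        assert np.all(np.isfinite(W))


# ---------------------------------------------------------------------------
# between-class covariance and discriminative directions
# ---------------------------------------------------------------------------

class TestBetweenClass:
    def test_equal_means_give_zero(self):
        assert np.allclose(between_class_cov_white(np.ones((4, 3))), 0.0)

    def test_two_class_closed_form(self):
        B = between_class_cov_white(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        assert np.allclose(B, [[1.0, 0.0], [0.0, 0.0]])

    def test_trace_identity(self, rng):
        # trace equals mean squared distance of class means to the grand mean
        M = rng.standard_normal((5, 7))
        B = between_class_cov_white(M)
        dev = M - M.mean(axis=0)
        assert np.isclose(np.trace(B), np.mean(np.sum(dev**2, axis=1)))

    def test_diagonal_eigvecs(self):
        vecs, vals = discriminative_directions(np.diag([3.0, 1.0, 0.0]), 2)
        assert np.allclose(vals, [3.0, 1.0])
        assert np.allclose(np.abs(vecs), np.eye(3)[:, :2])

    def test_noiseless_one_dim_has_single_nonzero_eigenvalue(self, rng):
        spec = make_random_features(4, 1, rng)
        cfg = SimConfig(P=20, n_runs=4, sigma_a2=1.0, noise_var=1.0)
        sd = simulate_dataset(spec, cfg, rng)
        # true means carry a strictly 1-D signal
        B = between_class_cov_white(sd.true_means)
        vecs, vals = discriminative_directions(B, 3)
        assert vals[0] > 1e-6
        assert np.all(vals[1:] < 1e-10 * vals[0])

    def test_first_eigvec_maximizes_projected_separation(self, rng):
        # Monte-Carlo oracle: S(w) = w^T B w over 10,000 random unit vectors
        M = rng.standard_normal((4, 6))
        B = between_class_cov_white(M)
        vecs, vals = discriminative_directions(B, 3)
        w = rng.standard_normal((10000, 6))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        s = np.einsum("ij,jk,ik->i", w, B, w)
        assert s.max() <= vals[0] + 1e-12
        assert np.isclose(vecs[:, 0] @ B @ vecs[:, 0], vals[0])

    def test_rank_bound(self, sim_dataset):
        model = fit_classifier(sim_dataset.data)
        vals = np.linalg.eigvalsh(model.between_cov_white)
        thresh = 1e-10 * np.trace(model.between_cov_white)
        assert np.sum(vals > thresh) <= sim_dataset.data.n_conditions - 1

    def test_orthonormal_eigvecs_and_descending_eigvals(self, sim_dataset):
        model = fit_classifier(sim_dataset.data)
        V = model.eigvecs
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
        assert np.all(np.diff(model.eigvals) <= 1e-12)
        assert np.all(model.eigvals >= 0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassify:
    def test_pattern_at_class_mean_is_assigned_to_it(self, rng):
        means = np.eye(3) * 4
        ds = PatternDataset(
            np.vstack([means + 0.01 * rng.standard_normal((3, 3)) for _ in range(2)]),
            np.tile([1, 2, 3], 2), np.repeat([1, 2], 3),
        )
        model = fit_classifier(ds)
        for k in range(3):
            assert classify_full(model, model.class_means[k]) == k + 1

    def test_midpoint_rule_one_unit(self):
        # means 0 and 2, unit variance: decision boundary at 1
        ds = PatternDataset(
            np.array([[-1.0], [1.0], [1.0], [3.0]]),
            [1, 1, 2, 2], [1, 2, 1, 2],
        )
        model = fit_classifier(ds, reg_fraction=0.0)
        assert np.allclose(model.class_means.ravel(), [0.0, 2.0])
        assert classify_full(model, np.array([0.9])) == 1
        assert classify_full(model, np.array([1.1])) == 2

    def test_matches_generative_log_probability_oracle(self, rng):
        # independent oracle: argmax_k of the full Gaussian log-density,
        # including all class-independent constant terms
        spec = make_random_features(3, 2, rng)
        cfg = SimConfig(P=8, n_runs=5, sigma_a2=0.5)
        sd = simulate_dataset(spec, cfg, rng)
        model = fit_classifier(sd.data)
        Sinv = np.linalg.inv(model.within_cov)
        Y = rng.standard_normal((50, 8))
        expect = []
        for y in Y:
            logp = [
                -0.5 * (y - mk) @ Sinv @ (y - mk) for mk in model.class_means
            ]
            expect.append(model.classes[int(np.argmax(logp))])
        assert np.array_equal(classify_full(model, Y), np.array(expect))

    def test_agrees_with_sklearn_lda(self, rng):
        # well-conditioned case (n >> P), no regularization: identical pooled
        # covariance and uniform priors, so predictions must agree
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        vals = rng.standard_normal((120, 4))
        cond = np.tile([1, 2, 3], 40)
        vals[cond == 2] += 1.0
        vals[cond == 3, 0] -= 1.5
        ds = PatternDataset(vals, cond, np.repeat([1, 2], 60))
        model = fit_classifier(ds, reg_fraction=0.0)
        lda = sklearn.LinearDiscriminantAnalysis(
            solver="lsqr", priors=[1 / 3] * 3
        ).fit(vals, cond)
        Y = rng.standard_normal((200, 4))
        assert np.array_equal(classify_full(model, Y), lda.predict(Y))

    def test_reduced_full_equivalence(self, sim_dataset, rng):
        model = fit_classifier(sim_dataset.data)
        Y = np.vstack([sim_dataset.data.values, rng.standard_normal((100, 30))])
        assert np.array_equal(classify_reduced(model, Y, 3), classify_full(model, Y))

    def test_reduced_matches_distance_form_oracle(self, rng):
        # brute force: whiten, project onto top-d eigenvectors, assign to the
        # nearest projected class mean in squared Euclidean distance
        spec = make_random_features(4, 3, rng)
        sd = simulate_dataset(spec, SimConfig(P=12, n_runs=4, sigma_a2=0.8), rng)
        model = fit_classifier(sd.data)
        Y = rng.standard_normal((120, 12))
        for d in (1, 2, 3):
            Wd = model.eigvecs[:, :d]
            zm = (model.class_means @ model.whitener) @ Wd
            zy = (Y @ model.whitener) @ Wd
            dist = ((zy[:, None, :] - zm[None]) ** 2).sum(-1)
            expect = model.classes[np.argmin(dist, axis=1)]
            assert np.array_equal(classify_reduced(model, Y, d), expect)

    def test_d_out_of_range(self, sim_dataset):
        model = fit_classifier(sim_dataset.data)
        for d in (0, 4):
            with pytest.raises(ValueError, match="d must be"):
                classify_reduced(model, sim_dataset.data.values[0], d)

    def test_dimension_mismatch(self, sim_dataset):
        model = fit_classifier(sim_dataset.data)
        with pytest.raises(ValueError, match="units"):
            classify_full(model, np.zeros(7))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class TestCrossval:
    def test_chance_level_at_zero_signal(self, rng):
        spec = make_random_features(4, 2, rng)
        cfg = SimConfig(P=40, n_runs=10, trials_per_cond_per_run=3, sigma_a2=0.0)
        sd = simulate_dataset(spec, cfg, rng)
        curve = crossval_accuracy_curve(sd.data)
        n = curve.n_test_trials
        se = np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(curve.accuracy - 0.25) < 3 * se)

    def test_matches_naive_reimplementation(self, sim_dataset):
        # oracle repeats the whole procedure with fresh per-fold fits
        data = sim_dataset.data
        curve = crossval_accuracy_curve(data)
        for di, d in enumerate(curve.dims):
            correct = 0
            for r in data.runs:
                model = fit_classifier(data, trials=data.run != r)
                test = data.run == r
                pred = classify_reduced(model, data.values[test], int(d))
                correct += int(np.sum(pred == data.condition[test]))
            assert correct == curve.n_correct[di]

    def test_requires_two_runs(self):
        ds = PatternDataset(np.random.default_rng(0).standard_normal((4, 2)),
                            [1, 2, 1, 2], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="2 runs"):
            crossval_accuracy_curve(ds)

    def test_best_dim_tie_goes_to_smallest(self):
        curve_args = dict(dims=np.array([1, 2, 3]), n_test_trials=32)
        from repdim.core import AccuracyCurve
        c = AccuracyCurve(n_correct=np.array([20, 20, 10]), **curve_args)
        assert c.best_dim == 1


# ---------------------------------------------------------------------------
# feature-space projection
# ---------------------------------------------------------------------------

class TestProjection:
    def test_distances_equal_mahalanobis_at_full_d(self, sim_dataset):
        model = fit_classifier(sim_dataset.data)
        pc = project_to_feature_space(model, 3)
        maha = pdist(model.class_means @ model.whitener)
        assert np.allclose(pdist(pc.coords), maha, rtol=1e-10)

    def test_projected_variance_equals_eigenvalues(self, sim_dataset):
        model = fit_classifier(sim_dataset.data)
        pc = project_to_feature_space(model, 3)
        dev = pc.coords - pc.coords.mean(axis=0)
        per_dim = (dev**2).sum(axis=0) / pc.coords.shape[0]
        assert np.allclose(per_dim, model.eigvals, atol=1e-10)

    def test_identical_class_means_project_identically(self, rng):
        vals = np.ones((8, 5)) + 0.3 * rng.standard_normal((8, 5))
        # condition 2 trials duplicate condition 1 trials -> identical means
        vals[1::2] = vals[0::2]
        ds = PatternDataset(vals, [1, 2, 1, 2, 1, 2, 1, 2],
                            [1, 1, 2, 2, 3, 3, 4, 4])
        model = fit_classifier(ds)
        pc = project_to_feature_space(model, 1)
        assert np.allclose(pc.coords[0], pc.coords[1])
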