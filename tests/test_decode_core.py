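"""Normalization, feature selection, SVM-vs-QP oracle, cross-validation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from memdecode.decode_core import (
    CvScheme,
    LabeledPatterns,
    anova_select,
    balanced_subsample,
    cross_validate,
    detrend_zscore_trials,
    fit_linear_classifier,
    spatial_zscore,
)


class TestSpatialZscore:
    def test_mean_zero_sd_one(self, rng):
        X = rng.standard_normal((10, 40))
        Z = spatial_zscore(X)
        assert np.allclose(Z.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(Z.std(axis=1), 1.0, atol=1e-10)

    def test_offset_and_scale_invariance(self, rng):
        X = rng.standard_normal((5, 30))
        assert np.allclose(spatial_zscore(X), spatial_zscore(X + 7.5), atol=1e-10)
        assert np.allclose(spatial_zscore(X), spatial_zscore(3.2 * X + 1.0), atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spatial_zscore(np.ones((3, 5)))


class TestDetrendZscore:
    def test_linear_trajectory_zeroed(self):
        X = np.outer(np.arange(20.0), np.ones(4))
        with pytest.warns(UserWarning, match="constant"):
            Z = detrend_zscore_trials(X)
        assert np.allclose(Z, 0.0)

    def test_output_standardized(self, rng):
        X = rng.standard_normal((50, 8)) + np.outer(np.arange(50), rng.standard_normal(8))
        Z = detrend_zscore_trials(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_idempotent_after_first_pass(self, rng):
        X = rng.standard_normal((30, 6))
        once = detrend_zscore_trials(X)
        twice = detrend_zscore_trials(once)
        assert np.allclose(once, twice, atol=1e-10)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            detrend_zscore_trials(np.zeros((2, 4)))


class TestAnovaSelect:
    def test_planted_informative_feature_ranked_first(self, rng):
        y = np.repeat([0, 1], 50)
        X = rng.standard_normal((100, 100))
        X[:, 42] += 5.0 * (y - 0.5)
        sel = anova_select(X, y, 1)
        assert sel.tolist() == [42]

    def test_select_all_is_identity(self, rng):
        X = rng.standard_normal((20, 7))
        y = np.repeat([0, 1], 10)
        assert anova_select(X, y, 7).tolist() == list(range(7))

    def test_tie_break_lowest_index(self):
        y = np.repeat([0, 1], 4)
        col = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        X = np.column_stack([col, col, col])  # identical F scores
        assert anova_select(X, y, 2).tolist() == [0, 1]

    def test_no_leakage_from_test_rows(self, rng):
        """Selection computed on a training fold must be unchanged by any
        modification of test rows (mutation test)."""
        X = rng.standard_normal((60, 30))
        y = np.repeat([0, 1], 30)
        train = np.arange(40)
        sel_before = anova_select(X[train], y[train], 5)
        X_mut = X.copy()
        X_mut[40:] = 1e6 * rng.standard_normal((20, 30))
        sel_after = anova_select(X_mut[train], y[train], 5)
        assert sel_before.tolist() == sel_after.tolist()

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            anova_select(rng.standard_normal((10, 3)), np.repeat([0, 1], 5), 4)


def _qp_svm_oracle(X, y, C=1.0):
    """Brute-force soft-margin SVM: minimize 0.5||w||^2 + C sum(xi) s.t.
    y_i (w.x_i + b) >= 1 - xi_i, xi >= 0, solved as a generic NLP."""
    n, d = X.shape
    ys = np.where(y == np.unique(y)[1], 1.0, -1.0)

    def unpack(z):
        return z[:d], z[d], z[d + 1 :]

    def obj(z):
        w, b, xi = unpack(z)
        return 0.5 * w @ w + C * xi.sum()

    cons = [
        {"type": "ineq", "fun": lambda z, i=i: ys[i] * (z[:d] @ X[i] + z[d]) - 1 + z[d + 1 + i]}
        for i in range(n)
    ] + [{"type": "ineq", "fun": lambda z, i=i: z[d + 1 + i]} for i in range(n)]
    z0 = np.zeros(d + 1 + n)
    res = minimize(obj, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 2000, "ftol": 1e-12})
    assert res.success
    w, b, _ = unpack(res.x)
    return w, b


class TestLinearClassifier:
    def test_separable_toy_perfect_training(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1])
        clf = fit_linear_classifier(X, y)
        assert (clf.predict(X) == y).all()

    def test_label_flip_flips_weights(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.repeat([0, 1], 15)
        a = fit_linear_classifier(X, y, tol=1e-8)
        b = fit_linear_classifier(X, 1 - y, tol=1e-8)
        assert np.allclose(a.weights, -b.weights, atol=1e-5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_qp_oracle_on_six_points(self, seed):
        """The fitted separator attains the same hinge-loss objective and
        weight vector as a brute-force constrained optimizer (the bias is
        compared through the objective because it can be non-unique)."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        X[y == 1] += 1.0  # overlapping classes: some slack is active
        clf = fit_linear_classifier(X, y, C=1.0, tol=1e-8)
        w, b = _qp_svm_oracle(X, y, C=1.0)
        ys = np.where(y == 1, 1.0, -1.0)

        def objective(wv, bv):
            margins = 1 - ys * (X @ wv + bv)
            return 0.5 * wv @ wv + np.clip(margins, 0, None).sum()

        assert np.allclose(clf.weights, w, atol=1e-4)
        assert objective(clf.weights, clf.bias) == pytest.approx(objective(w, b), abs=1e-6)

    def test_tie_goes_to_first_class(self):
        from memdecode.decode_core import LinearDecisionFunction

        clf = LinearDecisionFunction(np.array([1.0]), 0.0, np.array(["a", "b"]))
        assert clf.predict(np.array([[0.0]]))[0] == "a"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_classifier(np.zeros((3, 2)), np.zeros(3))


def _make_patterns(rng, n_subj=6, n_per_class=10, n_feat=8, signal=None, group_flip=None):
    Xs, ys, sids, runs = [], [], [], []
    code = rng.standard_normal(n_feat)
    for s in range(n_subj):
        y = np.tile(np.repeat([0, 1], n_per_class // 2), 2)
        X = rng.standard_normal((len(y), n_feat))
        if signal is not None:
            sgn = 1.0
            if group_flip is not None:
                sgn = 1.0 if s < n_subj // 2 else -1.0
            X += signal * sgn * np.outer(y - 0.5, code)
        Xs.append(X)
        ys.append(y)
        sids.append(np.full(len(y), s))
        runs.append(np.repeat(np.arange(4), len(y) // 4))
    import pandas as pd

    meta = pd.DataFrame({"run": np.concatenate(runs)})
    return LabeledPatterns(np.vstack(Xs), np.concatenate(ys), np.concatenate(sids), meta)


class TestCrossValidate:
    def test_null_accuracy_near_chance(self, rng):
        pats = _make_patterns(rng, n_subj=10, n_per_class=20)
        res = cross_validate(pats, CvScheme("leave_one_subject_out"))
        n = len(pats.y)
        assert abs(res.mean_accuracy - 0.5) < 3 * np.sqrt(0.25 / n) + 0.05

    def test_informative_feature_gives_high_accuracy(self, rng):
        pats = _make_patterns(rng, signal=4.0)
        res = cross_validate(pats, CvScheme("leave_one_subject_out"))
        assert res.mean_accuracy > 0.9

    def test_between_within_dissociation_for_group_flipped_signal(self, rng):
        """A signal whose sign flips between counterbalanced halves of the
        cohort decodes at chance across subjects but far above chance
        within each subject."""
        pats = _make_patterns(rng, n_subj=8, n_per_class=28, signal=4.0, group_flip=True)
        loso = cross_validate(pats, CvScheme("leave_one_subject_out"))
        # the flipped code cannot support above-chance transfer across the
        # cohort (training folds are group-imbalanced, so a strong shared
        # code is learned with the majority group's sign and scores at or
        # below chance on the held-out subject)
        assert loso.mean_accuracy <= 0.5
        within = []
        for s in range(8):
            idx = np.where(pats.subject_ids == s)[0]
            within.append(
                cross_validate(pats.subset(idx), CvScheme("k_fold_within", k=7)).mean_accuracy
            )
        assert np.mean(within) > 0.85

    def test_permutation_null_calibrated(self, rng):
        """Mean LOSO accuracy over 200 label permutations stays within
        three standard errors of chance."""
        pats = _make_patterns(rng, n_subj=6, n_per_class=10)
        means, total = [], 0
        for _ in range(200):
            perm = rng.permutation(len(pats.y))
            shuffled = LabeledPatterns(pats.X, pats.y[perm], pats.subject_ids, pats.meta)
            res = cross_validate(shuffled, CvScheme("leave_one_subject_out"))
            means.append(res.mean_accuracy)
            total += res.n_test.sum()
        se = np.sqrt(0.25 / total)
        assert abs(np.mean(means) - 0.5) < 3 * se + 0.01

    def test_degenerate_fold_identified(self, rng):
        X = rng.standard_normal((8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        sids = np.array([0, 0, 0, 0, 1, 1, 1, 1])  # leaving subject 1 out: one class
        pats = LabeledPatterns(X, y, sids)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(pats, CvScheme("leave_one_subject_out"))


class TestBalancedSubsample:
    def test_fraction_one_identity(self, rng):
        pats = _make_patterns(rng)
        out = balanced_subsample(pats, 1.0, seed=0)
        assert out.X.shape == pats.X.shape

    def test_half_of_sixty_sixty(self, rng):
        y = np.repeat([0, 1], 60)
        pats = LabeledPatterns(rng.standard_normal((120, 4)), y, np.zeros(120))
        out = balanced_subsample(pats, 0.5, seed=1)
        assert (out.y == 0).sum() == 30 and (out.y == 1).sum() == 30

    def test_seed_reproducible(self, rng):
        pats = _make_patterns(rng)
        a = balanced_subsample(pats, 0.5, seed=3)
        b = balanced_subsample(pats, 0.5, seed=3)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_tiny_class_rejected(self, rng):
        y = np.array([0, 1, 1, 1])
        pats = LabeledPatterns(rng.standard_normal((4, 2)), y, np.zeros(4))
        with pytest.raises(ValueError, match="balance"):
            balanced_subsample(pats, 0.3, seed=0)
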