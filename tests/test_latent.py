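"""NIPALS PCA / PLS-DA / OPLS-DA fits and cross-validation."""

import numpy as np
import pytest

from aromapanel.latent import (assign_folds, cross_validate, encode_classes,
                               fit_opls, fit_pca, fit_pls, model_summary)
from aromapanel.preprocess import scale_matrix


def _two_class_y(n_per=6):
    return ["A"] * n_per + ["B"] * n_per


class TestPCA:
    def test_collinear_data_needs_one_component(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, [1.0, -2.0, 0.5])
        X -= X.mean(0)
        model = fit_pca(X, 2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4000, 2))
        X -= X.mean(0)
        evr = fit_pca(X, 2).explained_variance_ratio
        assert evr[0] == pytest.approx(0.5, abs=0.05)
        assert evr[1] == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_svd_oracle(self, rng):
        X = rng.normal(size=(15, 6))
        X -= X.mean(0)
        model = fit_pca(X, 3)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        for a in range(3):
            sign = np.sign(model.loadings_pred[:, a] @ Vt[a])
            np.testing.assert_allclose(model.loadings_pred[:, a],
                                       sign * Vt[a], atol=1e-8)
            np.testing.assert_allclose(model.scores_pred[:, a],
                                       sign * U[:, a] * s[a], atol=1e-8)

    def test_component_budget_enforced(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(4, 10)), 5)


class TestPLS:
    def test_perfectly_proportional_column_gives_r2y_one(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        X = np.column_stack([2.0 * (y - y.mean())])
        model = fit_pls(X, y, 1)
        assert model.r2y == pytest.approx(1.0, abs=1e-12)

    def test_y_orthogonal_to_x_triggers_null_component(self):
        # X column orthogonal to centered y
        y = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        model = fit_pls(X, y, 1)
        assert abs(model.r2y) < 1e-10

    def test_first_weight_matches_closed_form_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n, p = rng.integers(4, 12), rng.integers(2, 8)
            X = rng.normal(size=(int(n), int(p)))
            X -= X.mean(0)
            y = rng.normal(size=int(n))
            w_oracle = X.T @ (y - y.mean())
            w_oracle /= np.linalg.norm(w_oracle)
            model = fit_pls(X, y, 1)
            np.testing.assert_allclose(model.weights_pred[:, 0], w_oracle,
                                       atol=1e-10)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_pls(rng.normal(size=(6, 3)), np.ones(6), 1)

    def test_toy_4x2_first_weight(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.5, 1.0], [-0.5, -1.0]])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = fit_pls(X - X.mean(0), y, 1).weights_pred[:, 0]
        expect = (X - X.mean(0)).T @ (y - 0.5)
        expect /= np.linalg.norm(expect)
        np.testing.assert_allclose(w, expect, atol=1e-12)


class TestOPLS:
    def _signal_data(self, rng, n_per=6, p=5):
        labels = _two_class_y(n_per)
        y = encode_classes(labels).y_matrix[:, 0]
        X = np.outer(y - y.mean(), rng.normal(size=p))
        X += 0.05 * rng.normal(size=X.shape)
        return X - X.mean(0), y, labels

    def test_no_orthogonal_structure_degenerates_to_pls(self, rng):
        y = np.array([0.0] * 6 + [1.0] * 6)
        X = np.outer(y - y.mean(), [1.0, 2.0, -1.0])
        with pytest.warns(UserWarning, match="orthogonal"):
            model = fit_opls(X, y, n_orth=1)
        assert model.n_orth_components == 0
        pls = fit_pls(X, y, 1)
        np.testing.assert_allclose(np.abs(model.scores_pred),
                                   np.abs(pls.scores_pred), atol=1e-8)

    def test_variance_split_sums_to_one(self, rng):
        for _ in range(20):
            X, y, _ = self._signal_data(rng)
            X += rng.normal(size=X.shape)  # add orthogonal structure
            X -= X.mean(0)
            model = fit_opls(X, y, n_orth=1)
            resid = np.sum(model.residual ** 2) / np.sum(X ** 2)
            assert model.r2x_total + resid == pytest.approx(1.0, abs=1e-8)
            assert 0 <= model.r2x_pred <= model.r2x_total <= 1

    def test_predictive_and_orthogonal_scores_are_orthogonal(self, rng):
        X, y, _ = self._signal_data(rng)
        X += rng.normal(size=X.shape)
        X -= X.mean(0)
        model = fit_opls(X, y, n_orth=1)
        assert abs(model.scores_pred[:, 0] @ model.scores_orth[:, 0]) < 1e-8

    def test_zero_orth_reproduces_pls_exactly(self, rng):
        X, y, _ = self._signal_data(rng)
        opls = fit_opls(X, y, n_orth=0)
        pls = fit_pls(X, y, 1)
        np.testing.assert_allclose(np.abs(opls.scores_pred),
                                   np.abs(pls.scores_pred), atol=1e-10)
        assert opls.r2y == pytest.approx(pls.r2y, abs=1e-10)

    def test_predictive_score_separates_synthetic_groups(self, synth_table):
        sub = synth_table.subset_regions(("BJ", "SD"))
        scaled = scale_matrix(sub.values)
        model = fit_opls(scaled, encode_classes(sub.region_labels))
        t = model.scores_pred[:, 0]
        sd_side = np.array([r == "SD" for r in sub.region_labels])
        assert np.all(t[sd_side] > 0) and np.all(t[~sd_side] < 0)

    def test_multicolumn_y_rejected(self, rng):
        X = rng.normal(size=(9, 4))
        with pytest.raises(ValueError, match="single-column"):
            fit_opls(X, np.eye(3).repeat(3, axis=0), n_orth=1)


class TestCrossValidation:
    SPEC = {"kind": "opls_da", "n_pred": 1, "n_orth": 1}

    def test_fold_sizes_and_coverage(self):
        labels = _two_class_y(12)
        assignment = assign_folds(labels, 7, seed=1)
        sizes = sorted(np.bincount(assignment, minlength=7), reverse=True)
        assert sizes == [4, 4, 4, 3, 3, 3, 3]
        assert set(assignment) == set(range(7))

    def test_each_training_fold_keeps_both_classes(self):
        labels = _two_class_y(12)
        assignment = assign_folds(labels, 7, seed=5)
        for k in range(7):
            train = [labels[i] for i in range(24) if assignment[i] != k]
            assert set(train) == {"A", "B"}

    def test_information_leak_gives_near_perfect_q2(self):
        # y duplicated as columns of X: perfect information by construction
        labels = _two_class_y(12)
        y = encode_classes(labels).y_matrix[:, 0]
        X = np.column_stack([y, 2.0 * y - 0.3])
        cv = cross_validate(self.SPEC, X, labels, folds=7, seed=1)
        assert cv.q2y > 0.99

    def test_structureless_data_rarely_beats_the_mean(self):
        rng = np.random.default_rng(0)
        labels = _two_class_y(12)
        negative = 0
        for rep in range(100):
            X = rng.normal(size=(24, 10))
            cv = cross_validate(self.SPEC, X, labels, folds=7, seed=rep)
            negative += cv.q2y <= 0
        assert negative >= 90

    def test_every_sample_predicted_once(self, rng):
        labels = _two_class_y(6)
        X = rng.normal(size=(12, 4))
        cv = cross_validate(self.SPEC, X, labels, folds=3, seed=2)
        assert cv.fold_assignments.shape == (12,)
        assert all(np.any(cv.fold_assignments == k) for k in range(3))

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(self.SPEC, rng.normal(size=(10, 3)),
                           _two_class_y(5), folds=40, seed=1)


class TestModelSummary:
    def test_perfect_fit_bounds(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        X = np.column_stack([3.0 * (y - y.mean())])
        model = fit_pls(X, y, 1)
        s = model_summary(model)
        assert s["r2y"] == pytest.approx(1.0) and s["q2y"] is None

    def test_synthetic_pair_model_is_strong(self, synth_table):
        sub = synth_table.subset_regions(("BJ", "SD"))
        scaled = scale_matrix(sub.values)
        model = fit_opls(scaled, encode_classes(sub.region_labels))
        cv = cross_validate(self.spec(), sub.values, sub.region_labels,
                            folds=7, seed=1)
        s = model_summary(model, cv)
        assert s["r2y"] > 0.9 and s["q2y"] > 0.9
        assert s["components"] == "1 predictive + 1 orthogonal"

    @staticmethod
    def spec():
        return {"kind": "opls_da", "n_pred": 1, "n_orth": 1}
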