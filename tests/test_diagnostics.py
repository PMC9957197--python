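"""S-plot, VIP, jack-knife intervals, permutation validation, SUS plots."""

import numpy as np
import pytest

from aromapanel.diagnostics import (SPlotRow, jackknife_ci, permutation_test,
                                    s_plot, sus_plot, vip_scores)
from aromapanel.latent import CVResult, cross_validate, encode_classes, fit_opls
from aromapanel.preprocess import scale_matrix

SPEC = {"kind": "opls_da", "n_pred": 1, "n_orth": 1}


def _fit_pair(table, pair):
    sub = table.subset_regions(pair)
    scaled = scale_matrix(sub.values)
    model = fit_opls(scaled, encode_classes(sub.region_labels))
    return sub, scaled, model


class TestSPlot:
    def test_column_proportional_to_score_has_unit_correlation(self):
        # every column collinear with y, so t is collinear with each column
        y = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([3.0 * (y - 0.5), -2.0 * (y - 0.5)])
        model = fit_opls(X, y, n_orth=0)
        rows = s_plot(model, X, ["up", "down"])
        assert rows[0].p_corr == pytest.approx(1.0, abs=1e-10)
        assert rows[1].p_corr == pytest.approx(-1.0, abs=1e-10)

    def test_p_corr_equals_sample_correlation_oracle(self, rng):
        for _ in range(10):
            y = np.array([0.0] * 12 + [1.0] * 12)
            X = rng.normal(size=(24, 6)) + np.outer(y, rng.normal(size=6))
            X -= X.mean(0)
            model = fit_opls(X, y, n_orth=1)
            rows = s_plot(model, X, [f"c{j}" for j in range(6)])
            t = model.scores_pred[:, 0]
            for j, row in enumerate(rows):
                assert row.p_corr == pytest.approx(
                    np.corrcoef(t, X[:, j])[0, 1], abs=1e-10)

    def test_pure_noise_column_rarely_reliable(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            y = np.array([0.0] * 12 + [1.0] * 12)
            X = np.column_stack([5 * (y - 0.5) + 0.1 * rng.normal(size=24),
                                 rng.normal(size=24)])
            X -= X.mean(0)
            model = fit_opls(X, y, n_orth=0)
            rows = s_plot(model, X, ["signal", "noise"])
            hits += abs(rows[1].p_corr) >= 0.5
        assert hits < 15  # |corr| of noise at n=24 is almost always < 0.5

    def test_zero_variance_column_never_selected(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.column_stack([y - 0.5, np.zeros(4)])
        model = fit_opls(X, y, n_orth=0)
        rows = s_plot(model, X, ["sig", "flat"])
        assert np.isnan(rows[1].p_corr) and not rows[1].selected

    def test_synthetic_bj_sd_selects_the_reported_compounds(self, synth_table):
        sub, scaled, model = _fit_pair(synth_table, ("BJ", "SD"))
        rows = s_plot(model, scaled, sub.compound_names)
        selected = {r.compound for r in rows if r.selected}
        assert {"Methyl acetate", "(E)-Hex-2-enal", "Benzaldehyde",
                "[(Z)-Hex-3-enyl] acetate"} <= selected


class TestVIP:
    def test_equal_weights_normalize_to_one(self):
        y = np.array([0.0] * 4 + [1.0] * 4)
        X = np.tile((y - 0.5)[:, None], (1, 5))
        model = fit_opls(X, y, n_orth=0)
        for _, v in vip_scores(model, list("abcde")):
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_variable_gets_sqrt_p(self, rng):
        y = np.array([0.0] * 6 + [1.0] * 6)
        X = np.column_stack([y - 0.5] + [np.zeros(12)] * 3)
        model = fit_opls(X, y, n_orth=0)
        vips = dict(vip_scores(model, list("abcd")))
        assert vips["a"] == pytest.approx(2.0, abs=1e-10)  # sqrt(4)
        assert vips["b"] == 0.0

    def test_sum_of_squares_equals_p(self, synth_table):
        for pair in [("BJ", "SD"), ("BJ", "HB"), ("HB", "SD")]:
            sub, scaled, model = _fit_pair(synth_table, pair)
            vips = np.array([v for _, v in vip_scores(model, sub.compound_names)])
            assert np.sum(vips ** 2) == pytest.approx(len(sub.compounds),
                                                      abs=1e-8)

    def test_lactone_discriminates_bj_from_hb(self, synth_table):
        sub, scaled, model = _fit_pair(synth_table, ("BJ", "HB"))
        vips = dict(vip_scores(model, sub.compound_names))
        assert vips["5-Ethyloxolan-2-one"] > 1.0


class TestJackknife:
    def test_identical_fold_loadings_give_zero_width(self):
        cv = CVResult(q2y=0.9, press=0.1,
                      fold_assignments=np.zeros(7, int),
                      per_fold_loadings=[np.array([0.5, -0.2])] * 7,
                      per_fold_predictions=np.zeros((7, 1)))
        for ci in jackknife_ci(cv, ["a", "b"]):
            assert ci.half_width == 0.0 and ci.df == 6

    def test_seven_fold_uses_t_critical_2447(self):
        loadings = [np.array([0.5])] * 6 + [np.array([0.6])]
        cv = CVResult(0.9, 0.1, np.zeros(7, int), loadings, np.zeros((7, 1)))
        [ci] = jackknife_ci(cv, ["a"], alpha=0.05)
        assert ci.se_cv == pytest.approx(0.0143, abs=5e-4)
        assert ci.half_width == pytest.approx(ci.se_cv * 2.447, rel=1e-3)
        assert ci.half_width == pytest.approx(0.0349, abs=5e-4)

    def test_sign_flip_across_folds_is_aligned_away(self):
        loadings = [np.array([0.5, 0.1]), -np.array([0.5, 0.1]),
                    np.array([0.5, 0.1])]
        cv = CVResult(0.9, 0.1, np.zeros(3, int), loadings, np.zeros((3, 1)))
        for ci in jackknife_ci(cv, ["a", "b"],
                               reference_loading=np.array([0.5, 0.1])):
            assert ci.half_width == 0.0

    def test_requires_two_folds(self):
        cv = CVResult(0.9, 0.1, np.zeros(1, int), [np.array([1.0])],
                      np.zeros((1, 1)))
        with pytest.raises(ValueError):
            jackknife_ci(cv, ["a"])


class TestPermutation:
    def test_row_count_and_valid_verdict_on_strong_signal(self, synth_table):
        sub = synth_table.subset_regions(("BJ", "SD"))
        res = permutation_test(sub.values, sub.region_labels, n_perm=30,
                               seed=1)
        assert len(res.rows) == 30
        assert res.valid and res.q2_intercept < 0
        assert res.model_q2y > max(r[2] for r in res.rows)

    def test_label_randomized_data_is_invalid(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 8))
        labels = ["A"] * 12 + ["B"] * 12
        res = permutation_test(X, labels, n_perm=30, seed=4)
        assert not res.valid

    def test_correlations_lie_in_unit_interval(self, synth_table):
        sub = synth_table.subset_regions(("HB", "SD"))
        res = permutation_test(sub.values, sub.region_labels, n_perm=10,
                               seed=2)
        assert all(0.0 <= r[0] <= 1.0 for r in res.rows)


class TestSUS:
    @staticmethod
    def _row(name, corr):
        return SPlotRow(name, 0.2, corr, 0.2, abs(corr) >= 0.5)

    @pytest.mark.parametrize("c1, c2, expected", [
        (0.9, 0.88, "shared"),
        (0.9, 0.05, "unique_model1"),
        (0.05, -0.9, "unique_model2"),
        (0.1, 0.1, "uninformative"),
        (0.9, 0.35, "uninformative"),  # between tau_low and tau_high
    ])
    def test_classification_rule(self, c1, c2, expected):
        [row] = sus_plot([self._row("x", c1)], [self._row("x", c2)])
        assert row.classification == expected

    def test_swap_symmetry(self):
        s1 = [self._row("x", 0.9), self._row("y", 0.1)]
        s2 = [self._row("x", 0.05), self._row("y", 0.8)]
        fwd = {r.compound: r.classification for r in sus_plot(s1, s2)}
        rev = {r.compound: r.classification for r in sus_plot(s2, s1)}
        swap = {"unique_model1": "unique_model2",
                "unique_model2": "unique_model1"}
        for name in fwd:
            assert rev[name] == swap.get(fwd[name], fwd[name])

    def test_mismatched_compound_sets_rejected(self):
        with pytest.raises(ValueError, match="compound"):
            sus_plot([self._row("x", 0.9)], [self._row("y", 0.9)])
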