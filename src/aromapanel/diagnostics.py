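"""Model diagnostics for pairwise OPLS-DA: S-plot, VIP, jack-knife CIs,
permutation validation and SUS plots.

The S-plot places each variable at (p(cov), p(corr)) — the covariance and
correlation between the predictive score t and that variable's scaled
column.  High |p(cov)| means a large contribution, high |p(corr)| a reliable
one; candidate markers sit in the high/high corners.  Because raw
covariances have a data-dependent scale, the covariance vector is normalized
to unit Euclidean norm before thresholding (raw values are kept for
plotting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .latent import CVResult, LatentModel, cross_validate, encode_classes
from .preprocess import ScaledMatrix, scale_matrix
from .latent import _fit_for_spec

__all__ = [
    "SPlotRow",
    "JackknifeCI",
    "PermutationResult",
    "SUSRow",
    "s_plot",
    "vip_scores",
    "jackknife_ci",
    "permutation_test",
    "sus_plot",
]


@dataclass(frozen=True)
class SPlotRow:
    compound: str
    p_cov: float          # unit-norm covariance used for thresholding
    p_corr: float         # correlation Corr(t, x_j) in [-1, 1]
    p_cov_raw: float      # raw Cov(t, x_j), kept for plotting
    selected: bool


@dataclass(frozen=True)
class JackknifeCI:
    """Loading uncertainty across CV folds: half_width = SE_CV * t(alpha, df)."""

    compound: str
    loading_estimate: float
    se_cv: float
    half_width: float
    df: int


@dataclass
class PermutationResult:
    """Label-permutation validation of a PLS/OPLS model.

    ``rows`` holds one (|corr with true y|, R²(Y), Q²(Y)) triple per
    permutation; the intercepts come from a least-squares line through the
    permuted points plus the original-label point (at correlation 1),
    evaluated at correlation 0.  ``valid`` requires the original R² and Q² to
    exceed every permuted value and the Q² intercept to be negative.
    """

    rows: list[tuple[float, float, float]]
    model_r2y: float
    model_q2y: float
    r2_intercept: float
    q2_intercept: float
    n_permutations: int
    valid: bool


@dataclass(frozen=True)
class SUSRow:
    compound: str
    p_corr_model1: float
    p_corr_model2: float
    classification: str  # shared | unique_model1 | unique_model2 | uninformative


def s_plot(
    model: LatentModel,
    X: ScaledMatrix | np.ndarray,
    compound_names: Sequence[str],
    cov_threshold: float = 0.1,
    corr_threshold: float = 0.5,
) -> list[SPlotRow]:
    """S-plot coordinates of every variable against the predictive score.

    ``p_cov_j = t'x_j/(N-1)``; ``p_corr_j = p_cov_j/(sigma_t sigma_xj)``
    (identical to the sample correlation since both t and the columns are
    centered).  Zero-variance columns get p_corr = NaN and are never
    selected.
    """
    Xv = X.values if isinstance(X, ScaledMatrix) else np.asarray(X, float)
    t = model.scores_pred[:, 0]
    n = len(t)
    cov = t @ Xv / (n - 1)
    sd_t = t.std(ddof=1)
    sd_x = Xv.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / (sd_t * sd_x)
    corr[sd_x == 0] = np.nan
    norm = np.linalg.norm(cov)
    cov_unit = cov / norm if norm > 0 else cov
    rows = []
    for j, name in enumerate(compound_names):
        ok = (np.isfinite(corr[j])
              and abs(cov_unit[j]) >= cov_threshold
              and abs(corr[j]) >= corr_threshold)
        rows.append(SPlotRow(name, float(cov_unit[j]), float(corr[j]),
                             float(cov[j]), bool(ok)))
    return rows


def vip_scores(model: LatentModel,
               compound_names: Sequence[str]) -> list[tuple[str, float]]:
    """Variable importance in projection over the predictive components.

    ``VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a )`` with unit-norm
    weights, where SSY_a is the Y sum of squares explained by component a and
    p the number of variables; hence ``sum_j VIP_j^2 = p``.  For OPLS only
    the predictive component enters, so VIP ranks variables by their
    class-discriminating contribution.
    """
    W = model.weights_pred
    if W is None:
        raise ValueError("VIP needs a supervised (PLS/OPLS) model")
    T = model.scores_pred
    C = model.y_loadings
    p = W.shape[0]
    ssy = np.array([
        float(T[:, a] @ T[:, a]) * float(C[a] @ C[a]) for a in range(W.shape[1])
    ])
    denom = ssy.sum()
    if denom <= 0:
        return [(name, 0.0) for name in compound_names]
    w_sq = W ** 2  # columns already unit norm
    vip = np.sqrt(p * (w_sq @ ssy) / denom)
    return [(name, float(v)) for name, v in zip(compound_names, vip)]


def jackknife_ci(cv: CVResult, compound_names: Sequence[str],
                 alpha: float = 0.05,
                 reference_loading: np.ndarray | None = None) -> list[JackknifeCI]:
    """Jack-knifed confidence half-widths of the predictive loadings.

    Each fold's loading vector is first sign-aligned to the reference (the
    full-model loading, or the first fold when absent) to undo the NIPALS
    sign indeterminacy, then ``SE_CV = SD(fold loadings)/sqrt(folds)`` and
    ``half_width = SE_CV * t(alpha/2, folds-1)`` (two-sided critical value).
    """
    folds = len(cv.per_fold_loadings)
    if folds < 2:
        raise ValueError("jack-knife needs >= 2 folds")
    ref = (np.asarray(reference_loading, float)
           if reference_loading is not None else cv.per_fold_loadings[0])
    aligned = []
    for pl in cv.per_fold_loadings:
        aligned.append(-pl if float(pl @ ref) < 0 else pl)
    L = np.vstack(aligned)  # folds x p
    est = L.mean(axis=0)
    se = L.std(axis=0, ddof=1) / np.sqrt(folds)
    se[np.ptp(L, axis=0) == 0] = 0.0  # identical folds: exactly zero width
    df = folds - 1
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    return [
        JackknifeCI(name, float(est[j]), float(se[j]),
                    float(se[j] * tcrit), df)
        for j, name in enumerate(compound_names)
    ]


def permutation_test(
    X_raw: np.ndarray,
    sample_labels: list[str],
    n_perm: int = 200,
    seed: int = 1,
    spec: dict | None = None,
    folds: int = 7,
    scaling: str = "pareto",
) -> PermutationResult:
    """Class-label permutation validation with full per-permutation refits.

    For every permutation the labels are shuffled, scaling + model + CV are
    recomputed from scratch, and (|corr(permuted y, y)|, R², Q²) recorded.
    The regression lines include the unpermuted point at correlation 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm >= 1 required")
    spec = spec or {"kind": "opls_da", "n_pred": 1, "n_orth": 1}
    rng = np.random.default_rng(seed)
    y_true = encode_classes(sample_labels).y_matrix[:, 0]

    def _evaluate(labels: list[str], cv_seed: int) -> tuple[float, float]:
        fitted = scale_matrix(X_raw, mode=scaling)
        model = _fit_for_spec(fitted, encode_classes(labels).y_matrix, spec)
        cv = cross_validate(spec, X_raw, labels, folds=folds, seed=cv_seed,
                            scaling=scaling)
        return model.r2y, cv.q2y

    model_r2, model_q2 = _evaluate(sample_labels, seed)
    rows: list[tuple[float, float, float]] = []
    n = len(sample_labels)
    for i in range(n_perm):
        perm = rng.permutation(n)
        labels_p = [sample_labels[j] for j in perm]
        y_p = encode_classes(labels_p).y_matrix[:, 0]
        with np.errstate(invalid="ignore"):
            corr = abs(float(np.corrcoef(y_p, y_true)[0, 1]))
        r2, q2 = _evaluate(labels_p, seed + 1 + i)
        rows.append((corr, r2, q2))

    xs = np.array([r[0] for r in rows] + [1.0])
    r2s = np.array([r[1] for r in rows] + [model_r2])
    q2s = np.array([r[2] for r in rows] + [model_q2])
    A = np.column_stack([xs, np.ones_like(xs)])
    r2_int = float(np.linalg.lstsq(A, r2s, rcond=None)[0][1])
    q2_int = float(np.linalg.lstsq(A, q2s, rcond=None)[0][1])
    perm_r2_max = max(r[1] for r in rows)
    perm_q2_max = max(r[2] for r in rows)
    valid = (model_r2 > perm_r2_max and model_q2 > perm_q2_max
             and q2_int < 0)
    return PermutationResult(rows, model_r2, model_q2, r2_int, q2_int,
                             n_perm, valid)


def sus_plot(
    splot1: Sequence[SPlotRow],
    splot2: Sequence[SPlotRow],
    tau_high: float = 0.5,
    tau_low: float = 0.2,
) -> list[SUSRow]:
    """Shared-and-unique-structures comparison of two OPLS models.

    Both models must share the reference class and the compound set; p(corr)
    is oriented so positive means elevated in the non-reference class.  A
    compound is ``shared`` when reliable in both models (|p(corr)| >=
    tau_high twice), ``unique_model1``/``unique_model2`` when reliable in one
    and near zero (|p(corr)| <= tau_low) in the other, else
    ``uninformative``.
    """
    names1 = [r.compound for r in splot1]
    names2 = [r.compound for r in splot2]
    if set(names1) != set(names2):
        raise ValueError("the two models cover different compound sets")
    by2 = {r.compound: r for r in splot2}
    rows = []
    for r1 in splot1:
        r2 = by2[r1.compound]
        a1, a2 = abs(r1.p_corr), abs(r2.p_corr)
        if np.isnan(a1) or np.isnan(a2):
            cls = "uninformative"
        elif a1 >= tau_high and a2 >= tau_high:
            cls = "shared"
        elif a1 >= tau_high and a2 <= tau_low:
            cls = "unique_model1"
        elif a2 >= tau_high and a1 <= tau_low:
            cls = "unique_model2"
        else:
            cls = "uninformative"
        rows.append(SUSRow(r1.compound, float(r1.p_corr), float(r2.p_corr), cls))
    return rows
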