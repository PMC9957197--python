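"""NIPALS latent-variable models: PCA, PLS-DA and OPLS-DA.

The X matrix (already centered/scaled, see :mod:`aromapanel.preprocess`) is
decomposed as

* PCA / PLS:   ``X = T P' + E``
* OPLS:        ``X = T_p P_p' + T_o P_o' + E``

where the OPLS orthogonal components ``T_o P_o'`` capture systematic X
variation uncorrelated with the class response Y (orthogonal signal
correction), leaving a single predictive component whose score separates the
two classes.  Model quality is summarized by R²p(X) (predictive X variance),
R²(X) (total explained X variance), R²(Y) (fit) and the cross-validated
Q²(Y) = 1 - PRESS/SS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import ScaledMatrix, apply_scaling, scale_matrix

__all__ = [
    "ClassCoding",
    "LatentModel",
    "CVResult",
    "encode_classes",
    "assign_folds",
    "fit_pca",
    "fit_pls",
    "fit_opls",
    "cross_validate",
    "model_summary",
]

_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class ClassCoding:
    """Dummy coding of class labels.

    Column order is deterministic (lexicographic).  Two-class problems use a
    single 0/1 column (1 = second label); K > 2 classes use one-hot columns.
    ``centering`` stores the column means removed before fitting.
    """

    labels: list[str]
    y_matrix: np.ndarray
    centering: np.ndarray
    sample_labels: list[str]

    @property
    def n_classes(self) -> int:
        return len(self.labels)


def encode_classes(sample_labels: list[str]) -> ClassCoding:
    """Build the dummy Y matrix for a list of per-sample class labels."""
    labels = sorted(set(sample_labels))
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    n = len(sample_labels)
    if len(labels) == 2:
        y = np.array([[1.0 if s == labels[1] else 0.0] for s in sample_labels])
    else:
        y = np.zeros((n, len(labels)))
        for i, s in enumerate(sample_labels):
            y[i, labels.index(s)] = 1.0
    return ClassCoding(labels, y, y.mean(axis=0), list(sample_labels))


@dataclass
class LatentModel:
    """A fitted PCA / PLS-DA / OPLS-DA decomposition."""

    kind: str
    scores_pred: np.ndarray          # T (or T_p), n x a
    loadings_pred: np.ndarray        # P (or P_p), p x a
    weights_pred: np.ndarray | None  # W, p x a (None for PCA)
    y_loadings: np.ndarray | None    # C, a x k
    residual: np.ndarray             # E, n x p
    r2x_pred: float
    r2x_total: float
    r2y: float | None
    n_pred_components: int
    n_orth_components: int = 0
    scores_orth: np.ndarray | None = None    # T_o, n x a_o
    loadings_orth: np.ndarray | None = None  # P_o, p x a_o
    weights_orth: np.ndarray | None = None   # W_o, p x a_o
    y_mean: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None  # PCA only

    # -- prediction -------------------------------------------------------

    def _filter_orthogonal(self, X: np.ndarray) -> np.ndarray:
        Xf = np.array(X, dtype=float, copy=True)
        for a in range(self.n_orth_components):
            t_o = Xf @ self.weights_orth[:, a]
            Xf -= np.outer(t_o, self.loadings_orth[:, a])
        return Xf

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores of new (already scaled) rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "pca":
            return X @ self.loadings_pred
        Xf = self._filter_orthogonal(X)
        if self.kind == "opls_da":
            return Xf @ self.weights_pred
        # PLS: oblique projection through W and P
        W, P = self.weights_pred, self.loadings_pred
        return Xf @ W @ np.linalg.inv(P.T @ W)

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        """Predicted (uncentered) Y for new scaled rows."""
        if self.kind == "pca":
            raise ValueError("PCA has no Y to predict")
        T = self.transform(X)
        return T @ self.y_loadings + self.y_mean


@dataclass
class CVResult:
    """Cross-validation output of a PLS/OPLS fit."""

    q2y: float
    press: float
    fold_assignments: np.ndarray
    per_fold_loadings: list[np.ndarray]
    per_fold_predictions: np.ndarray


def assign_folds(labels: list[str], folds: int, seed: int) -> np.ndarray:
    """Stratified fold ids: seeded within-class shuffle, global round-robin.

    Fold sizes differ by at most one overall and by at most one per class.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(labels):
        raise ValueError(
            f"cannot split {len(labels)} samples into {folds} folds"
        )
    rng = np.random.default_rng(seed)
    order: list[int] = []
    for cls in sorted(set(labels)):
        idx = np.array([i for i, s in enumerate(labels) if s == cls])
        rng.shuffle(idx)
        order.extend(int(i) for i in idx)
    assignment = np.empty(len(labels), dtype=int)
    for pos, i in enumerate(order):
        assignment[i] = pos % folds
    return assignment


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _as_matrix(X: np.ndarray | ScaledMatrix) -> np.ndarray:
    if isinstance(X, ScaledMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _as_y(y: np.ndarray | ClassCoding) -> np.ndarray:
    if isinstance(y, ClassCoding):
        return y.y_matrix
    y = np.asarray(y, dtype=float)
    return y[:, None] if y.ndim == 1 else y


def fit_pca(X: np.ndarray | ScaledMatrix, n_components: int) -> LatentModel:
    """NIPALS principal component analysis of a centered matrix.

    Components maximize residual variance successively; a rank-deficient
    request returns fewer components with a warning.
    """
    X = _as_matrix(X)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_max = min(n - 1, p)
    if n_components > n_max:
        raise ValueError(f"n_components must be <= min(rows-1, cols) = {n_max}")
    ssx0 = float(np.sum(X ** 2))
    E = X.copy()
    scores, loadings, evr = [], [], []
    for _ in range(n_components):
        col = int(np.argmax(np.sum(E ** 2, axis=0)))
        t = E[:, col].copy()
        if np.linalg.norm(t) < _TOL:
            warnings.warn("rank deficient: returning fewer PCA components")
            break
        for _ in range(_MAX_ITER):
            pvec = E.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = E @ pvec
            if np.linalg.norm(t_new - t) < _TOL * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        scores.append(t)
        loadings.append(pvec)
        evr.append(float(t @ t) / ssx0 if ssx0 > 0 else 0.0)
        E = E - np.outer(t, pvec)
    T = np.column_stack(scores)
    P = np.column_stack(loadings)
    r2x = float(sum(evr))
    return LatentModel(
        kind="pca", scores_pred=T, loadings_pred=P, weights_pred=None,
        y_loadings=None, residual=E, r2x_pred=r2x, r2x_total=r2x, r2y=None,
        n_pred_components=T.shape[1],
        explained_variance_ratio=np.array(evr),
    )


def _nipals_pls_component(E: np.ndarray, F: np.ndarray):
    """One NIPALS PLS component on current residuals (E, F).

    Returns (w, t, c, p) with ``w`` unit norm, or None when Y carries no
    X-correlated information left (the w = 0 guard).
    """
    if F.shape[1] == 1:
        w = E.T @ F[:, 0]
        nw = np.linalg.norm(w)
        if nw < _TOL:
            return None
        w = w / nw
        t = E @ w
    else:
        u = F[:, int(np.argmax(np.sum(F ** 2, axis=0)))].copy()
        t = np.zeros(E.shape[0])
        for _ in range(_MAX_ITER):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw < _TOL:
                return None
            w = w / nw
            t_new = E @ w
            c_tmp = F.T @ t_new / (t_new @ t_new)
            u = F @ c_tmp / (c_tmp @ c_tmp)
            if np.linalg.norm(t_new - t) < _TOL * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
    tt = float(t @ t)
    if tt < _TOL:
        return None
    c = F.T @ t / tt
    p = E.T @ t / tt
    return w, t, c, p


def fit_pls(X: np.ndarray | ScaledMatrix, y: np.ndarray | ClassCoding,
            n_components: int) -> LatentModel:
    """NIPALS PLS(-DA) regression of a dummy-coded Y on scaled X.

    Per component: ``w ∝ X'y`` (unit norm), ``t = Xw``, ``p = X't/(t't)``,
    then deflation of X (and Y).  If Y is orthogonal to every X column the
    component is skipped and R²(Y) contributions are zero.
    """
    X = _as_matrix(X)
    Y = _as_y(y)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("Y has zero variance")
    y_mean = Y.mean(axis=0)
    F = Y - y_mean
    ssy0 = float(np.sum(F ** 2))
    ssx0 = float(np.sum(X ** 2))
    E = X.copy()
    Ws, Ts, Cs, Ps = [], [], [], []
    for _ in range(n_components):
        comp = _nipals_pls_component(E, F)
        if comp is None:
            # w = 0 guard: no Y-correlated structure left; emit a null
            # component so the requested shape is preserved
            pvar = E.shape[1]
            Ws.append(np.zeros(pvar))
            Ts.append(np.zeros(E.shape[0]))
            Cs.append(np.zeros(F.shape[1]))
            Ps.append(np.zeros(pvar))
            continue
        w, t, c, p = comp
        Ws.append(w)
        Ts.append(t)
        Cs.append(c)
        Ps.append(p)
        E = E - np.outer(t, p)
        F = F - np.outer(t, c)
    T = np.column_stack(Ts)
    r2y = 1.0 - float(np.sum(F ** 2)) / ssy0
    r2x = 1.0 - float(np.sum(E ** 2)) / ssx0 if ssx0 > 0 else 0.0
    return LatentModel(
        kind="pls_da", scores_pred=T, loadings_pred=np.column_stack(Ps),
        weights_pred=np.column_stack(Ws), y_loadings=np.vstack(Cs),
        residual=E, r2x_pred=r2x, r2x_total=r2x, r2y=r2y,
        n_pred_components=T.shape[1], y_mean=y_mean,
    )


def fit_opls(X: np.ndarray | ScaledMatrix, y: np.ndarray | ClassCoding,
             n_pred: int = 1, n_orth: int = 1) -> LatentModel:
    """Two-class OPLS-DA: orthogonal signal correction + one predictive LV.

    The orthogonal weight is ``w_o ∝ p - (w'p) w`` (the part of the loading
    not aligned with the Y-predictive weight); each orthogonal component is
    removed from X before the predictive component is fitted on the filtered
    matrix.  The X variance splits exactly into predictive + orthogonal +
    residual parts.
    """
    X = _as_matrix(X)
    Y = _as_y(y)
    if Y.shape[1] != 1:
        raise ValueError("OPLS-DA here supports a single-column (two-class) Y")
    if n_pred != 1:
        raise ValueError("a single predictive component is required for "
                         "two-class OPLS-DA")
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("Y has zero variance")
    y_mean = Y.mean(axis=0)
    yc = (Y - y_mean)[:, 0]
    ssx0 = float(np.sum(X ** 2))
    ssy0 = float(yc @ yc)

    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw < _TOL:
        raise ValueError("Y is orthogonal to every X column")
    w = w / nw

    Xf = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-8:
            warnings.warn("no orthogonal variation left: fewer orthogonal "
                          "components returned")
            break
        w_o = w_o / n_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
        Xf = Xf - np.outer(t_o, p_o)

    t = Xf @ w
    tt = float(t @ t)
    p = Xf.T @ t / tt
    c = float(yc @ t) / tt
    if c < 0:  # orient the predictive score toward the class coded 1
        w, t, p, c = -w, -t, -p, -c
    E = Xf - np.outer(t, p)
    r2x_pred = tt * float(p @ p) / ssx0 if ssx0 > 0 else 0.0
    r2x_orth = sum(float(to @ to) * float(po @ po)
                   for to, po in zip(T_o, P_o)) / ssx0 if ssx0 > 0 else 0.0
    r2y = 1.0 - float(np.sum((yc - t * c) ** 2)) / ssy0
    n_o = len(W_o)
    return LatentModel(
        kind="opls_da",
        scores_pred=t[:, None], loadings_pred=p[:, None],
        weights_pred=w[:, None], y_loadings=np.array([[c]]),
        residual=E, r2x_pred=r2x_pred, r2x_total=r2x_pred + r2x_orth,
        r2y=r2y, n_pred_components=1, n_orth_components=n_o,
        scores_orth=np.column_stack(T_o) if n_o else np.zeros((X.shape[0], 0)),
        loadings_orth=np.column_stack(P_o) if n_o else np.zeros((X.shape[1], 0)),
        weights_orth=np.column_stack(W_o) if n_o else np.zeros((X.shape[1], 0)),
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _fit_for_spec(Xs, y, spec: dict) -> LatentModel:
    kind = spec.get("kind", "opls_da")
    if kind == "opls_da":
        return fit_opls(Xs, y, n_pred=spec.get("n_pred", 1),
                        n_orth=spec.get("n_orth", 1))
    if kind == "pls_da":
        return fit_pls(Xs, y, n_components=spec.get("n_components", 2))
    raise ValueError(f"unknown model kind {kind!r}")


def cross_validate(
    spec: dict,
    X_raw: np.ndarray,
    sample_labels: list[str],
    folds: int = 7,
    seed: int = 1,
    scaling: str = "pareto",
) -> CVResult:
    """Stratified k-fold CV with per-fold re-scaling and refitting.

    ``spec`` is e.g. ``{"kind": "opls_da", "n_pred": 1, "n_orth": 1}`` or
    ``{"kind": "pls_da", "n_components": 2}``.  Scaling is refit on every
    training fold (no leakage); Q²(Y) = 1 - PRESS / SS of the centered full
    Y.  Each training fold must contain every class.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    coding = encode_classes(sample_labels)
    Y = coding.y_matrix
    assignment = assign_folds(sample_labels, folds, seed)
    preds = np.zeros_like(Y)
    per_fold_loadings: list[np.ndarray] = []
    for k in range(folds):
        test = assignment == k
        train = ~test
        train_labels = {sample_labels[i] for i in np.flatnonzero(train)}
        if train_labels != set(coding.labels):
            raise ValueError(
                f"fold {k}: training set lacks class(es) "
                f"{sorted(set(coding.labels) - train_labels)}; use fewer folds"
            )
        fitted = scale_matrix(X_raw[train], mode=scaling)
        model = _fit_for_spec(fitted, Y[train], spec)
        per_fold_loadings.append(model.loadings_pred[:, 0].copy())
        if test.any():
            Xt = apply_scaling(X_raw[test], fitted)
            preds[test] = model.predict_y(Xt)
    F0 = Y - Y.mean(axis=0)
    press = float(np.sum((Y - preds) ** 2))
    q2 = 1.0 - press / float(np.sum(F0 ** 2))
    return CVResult(q2y=q2, press=press, fold_assignments=assignment,
                    per_fold_loadings=per_fold_loadings,
                    per_fold_predictions=preds)


def model_summary(model: LatentModel, cv: CVResult | None = None) -> dict:
    """Flat summary record: R²p(X), R²(X), R²(Y), Q²(Y) and component counts."""
    return {
        "r2x_pred": model.r2x_pred,
        "r2x_total": model.r2x_total,
        "r2y": model.r2y,
        "q2y": cv.q2y if cv is not None else None,
        "components": (
            f"{model.n_pred_components} predictive + "
            f"{model.n_orth_components} orthogonal"
            if model.kind == "opls_da" else str(model.n_pred_components)
        ),
    }
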