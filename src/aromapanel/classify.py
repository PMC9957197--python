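"""Multi-class PLS-DA on the marker panel: fit, predict, confusion matrix.

The classifier regresses a one-hot class matrix on the scaled marker
concentrations with a small number of latent variables (default 2) and
assigns each sample to the class with the largest predicted Y column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import FeatureTable
from .latent import (CVResult, LatentModel, cross_validate, encode_classes,
                     fit_pls)
from .preprocess import ScaledMatrix, apply_scaling, scale_matrix

logger = logging.getLogger(__name__)

__all__ = ["ClassifierModel", "ConfusionMatrix", "fit_classifier", "predict",
           "evaluate"]


@dataclass
class ClassifierModel:
    """A fitted multi-class PLS-DA origin classifier."""

    latent: LatentModel
    scaler: ScaledMatrix
    class_order: list[str]
    compound_names: list[str]
    n_latent_variables: int
    cv: CVResult | None = None

    @property
    def training_summary(self) -> dict:
        return {
            "r2y": self.latent.r2y,
            "q2y": self.cv.q2y if self.cv is not None else None,
            "r2x_total": self.latent.r2x_total,
            "n_latent_variables": self.n_latent_variables,
        }


@dataclass
class ConfusionMatrix:
    """K x K count matrix (rows = true class, columns = predicted)."""

    counts: np.ndarray
    class_order: list[str]

    @property
    def accuracy(self) -> float:
        """Percent of samples on the main diagonal."""
        total = self.counts.sum()
        return 100.0 * float(np.trace(self.counts)) / float(total)

    def off_diagonal(self) -> list[tuple[str, str, int]]:
        out = []
        for i, true in enumerate(self.class_order):
            for j, pred in enumerate(self.class_order):
                if i != j and self.counts[i, j]:
                    out.append((true, pred, int(self.counts[i, j])))
        return out


def fit_classifier(
    table: FeatureTable,
    n_lv: int = 2,
    folds: int = 7,
    seed: int = 1,
    scaling: str = "pareto",
    auto_select_lv: bool = False,
    max_lv: int = 5,
) -> ClassifierModel:
    """Fit a PLS-DA classifier on a (panel-restricted) feature table.

    ``auto_select_lv`` replaces the fixed component count with the first
    minimum of cross-validated PRESS over 1..``max_lv`` components.
    """
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    coding = encode_classes(table.region_labels)
    if coding.n_classes < 2:
        raise ValueError("need at least two classes")
    rank = min(table.n_samples - 1, len(table.compounds))
    if auto_select_lv:
        press_by_lv = []
        for a in range(1, min(max_lv, rank) + 1):
            cv_a = cross_validate({"kind": "pls_da", "n_components": a},
                                  table.values, table.region_labels,
                                  folds=folds, seed=seed, scaling=scaling)
            press_by_lv.append(cv_a.press)
            if len(press_by_lv) > 1 and press_by_lv[-1] > press_by_lv[-2]:
                break
        n_lv = int(np.argmin(press_by_lv)) + 1
    if n_lv > rank:
        warnings.warn(f"n_lv={n_lv} exceeds rank {rank}; truncating")
        n_lv = rank
    scaler = scale_matrix(table.values, mode=scaling)
    latent = fit_pls(scaler, coding, n_components=n_lv)
    cv = cross_validate({"kind": "pls_da", "n_components": n_lv},
                        table.values, table.region_labels,
                        folds=folds, seed=seed, scaling=scaling)
    return ClassifierModel(latent=latent, scaler=scaler,
                           class_order=coding.labels,
                           compound_names=table.compound_names,
                           n_latent_variables=n_lv, cv=cv)


def predict(model: ClassifierModel, X: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Predicted labels and Y-score rows for raw concentration rows.

    The label is the argmax of the predicted (uncentered) Y columns; exact
    ties are broken toward the earliest class in ``class_order`` with a
    logged warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.compound_names):
        raise ValueError(
            f"expected {len(model.compound_names)} columns "
            f"(panel {model.compound_names}), got {X.shape[1]}"
        )
    Xs = apply_scaling(X, model.scaler)
    Y = model.latent.predict_y(Xs)
    if Y.shape[1] == 1:  # two-class single-column coding
        Y = np.column_stack([1.0 - Y[:, 0], Y[:, 0]])
    labels = []
    for row in Y:
        best = np.flatnonzero(row == row.max())
        if len(best) > 1:
            logger.warning("tie between classes %s; choosing %s",
                           [model.class_order[i] for i in best],
                           model.class_order[best[0]])
        labels.append(model.class_order[int(best[0])])
    return labels, Y


def evaluate(model: ClassifierModel, table: FeatureTable) -> ConfusionMatrix:
    """Confusion matrix of the model on a labeled feature table."""
    if table.n_samples == 0:
        raise ValueError("evaluation set is empty")
    sub = table.restrict_compounds(model.compound_names)
    predicted, _ = predict(model, sub.values)
    k = len(model.class_order)
    counts = np.zeros((k, k), dtype=int)
    for true, pred in zip(table.region_labels, predicted):
        if true not in model.class_order:
            raise ValueError(f"unknown true label {true!r}")
        counts[model.class_order.index(true), model.class_order.index(pred)] += 1
    return ConfusionMatrix(counts, list(model.class_order))
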