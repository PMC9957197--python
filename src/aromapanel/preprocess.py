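"""Column-wise centering and scaling ahead of latent-variable modeling.

Pareto scaling (the default) centers each column and divides by the square
root of its sample standard deviation — a compromise between unit-variance
scaling (which inflates noisy low-abundance variables) and bare centering
(which lets high-abundance variables dominate).  Inside cross-validation the
scaling must be refit on each training fold and applied, frozen, to the held
out rows; :func:`apply_scaling` exists for exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScaledMatrix", "scale_matrix", "apply_scaling", "inverse_scaling"]

_MODES = ("pareto", "unit_variance", "center_only")


@dataclass
class ScaledMatrix:
    """A centered/scaled matrix together with its fitted transform.

    ``values[:, j] = (X[:, j] - column_means[j]) / column_scales[j]``.
    Constant columns get scale 1, all-zero output and their index recorded in
    ``constant_columns``.
    """

    values: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    mode: str
    constant_columns: tuple[int, ...]


def scale_matrix(X: np.ndarray, mode: str = "pareto") -> ScaledMatrix:
    """Center each column and divide by a mode-dependent scale.

    * ``pareto``: divide by sqrt(SD) (sample SD, ddof=1);
    * ``unit_variance``: divide by SD;
    * ``center_only``: divide by 1.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown scaling mode {mode!r}; expected {_MODES}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] < 2:
        raise ValueError("scaling needs at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = tuple(int(j) for j in np.flatnonzero(sds == 0))
    if mode == "pareto":
        scales = np.sqrt(sds)
    elif mode == "unit_variance":
        scales = sds.copy()
    else:
        scales = np.ones_like(sds)
    scales[list(constant)] = 1.0
    values = (X - means) / scales
    values[:, list(constant)] = 0.0
    return ScaledMatrix(values, means, scales, mode, constant)


def apply_scaling(new_X: np.ndarray, fitted: ScaledMatrix) -> np.ndarray:
    """Scale new rows with a previously fitted transform.

    Uses the training means and scales only — never re-estimates on the new
    rows — so held-out folds see exactly the training-set geometry.
    """
    new_X = np.atleast_2d(np.asarray(new_X, dtype=float))
    if new_X.shape[1] != fitted.column_means.shape[0]:
        raise ValueError(
            f"column count {new_X.shape[1]} does not match fitted transform "
            f"({fitted.column_means.shape[0]} columns)"
        )
    return (new_X - fitted.column_means) / fitted.column_scales


def inverse_scaling(scaled_values: np.ndarray, fitted: ScaledMatrix) -> np.ndarray:
    """Map scaled rows back to the original units.

    Exact for non-constant columns; constant columns recover their (single)
    training value.
    """
    scaled_values = np.atleast_2d(np.asarray(scaled_values, dtype=float))
    out = scaled_values * fitted.column_scales + fitted.column_means
    # constant columns were forced to zero, so the round trip restores means
    for j in fitted.constant_columns:
        out[:, j] = fitted.column_means[j]
    return out
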