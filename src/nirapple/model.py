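"""NIPALS partial least squares regression and its discriminant variant.

The regression core is PLS1 (single response) fitted by NIPALS with
mean-centering of X and y and X-deflation per component; X is not
variance-scaled because all spectral channels share units (absorbance).
Regression coefficients are composed as b = W (P'W)^-1 q so prediction is
the affine map y_mean + (x - x_mean) b.

For a univariate response the NIPALS inner loop converges in one pass, so a
component costs a handful of matrix-vector products; cross-validated
latent-variable (LV) selection exploits this by fitting ``max_lv``
components once per fold and evaluating every truncation of the component
sequence.

PLS-DA encodes the storage week (1..7) as a single ordinal response fitted
with the identical machinery; the continuous prediction is rounded to the
nearest class with half-points rounded up (the midpoint decision boundary)
and clamped to the class range.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import SpectraMatrix
from .partition import FoldAssignment, make_folds

logger = logging.getLogger(__name__)


@dataclass
class PlsModel:
    """Fitted latent-variable model (weights, loadings, scores, coefficients)."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x A
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A
    scores: np.ndarray       # n x A (training scores)
    coefficients: np.ndarray  # p
    trained_on: np.ndarray | None = None  # variable indices, None = all
    class_range: tuple[int, int] | None = None  # set by plsda_fit

    def predict(self, X: SpectraMatrix | np.ndarray) -> np.ndarray:
        X = X.values if isinstance(X, SpectraMatrix) else np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coefficients.size:
            raise ValueError(
                f"model expects {self.coefficients.size} variables, got {X.shape[1]}"
            )
        return self.y_mean + (X - self.x_mean) @ self.coefficients

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "trained_on": None if self.trained_on is None else self.trained_on.tolist(),
            "class_range": self.class_range,
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")


def _nipals_components(
    Xc: np.ndarray, yc: np.ndarray, n_lv: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run NIPALS on centered data; returns (W, P, q, T), possibly short."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd = Xc.copy()
    yd = yc
    a_done = 0
    for a in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            warnings.warn(
                f"PLS component {a + 1}: weight norm below 1e-12, stopping "
                f"with {a} components",
                stacklevel=3,
            )
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            warnings.warn(
                f"PLS component {a + 1}: degenerate score vector, stopping",
                stacklevel=3,
            )
            break
        pvec = Xd.T @ t / tt
        W[:, a] = w
        P[:, a] = pvec
        q[a] = float(yd @ t) / tt
        T[:, a] = t
        Xd = Xd - np.outer(t, pvec)
        a_done = a + 1
    return W[:, :a_done], P[:, :a_done], q[:a_done], T[:, :a_done]


def _coefficients_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression coefficient vector for every truncation 1..A; p x A matrix."""
    A = W.shape[1]
    R = np.zeros((W.shape[0], A))
    M = P.T @ W  # upper triangular with unit-ish diagonal
    coefs = np.zeros((W.shape[0], A))
    b = np.zeros(W.shape[0])
    # solve incrementally: R = W (P'W)^-1, b_A = R[:, :A] q[:A]
    for a in range(A):
        r = W[:, a] - R[:, :a] @ M[:a, a]
        R[:, a] = r / M[a, a]
        b = b + R[:, a] * q[a]
        coefs[:, a] = b
    return coefs


def pls_fit(
    X: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    n_lv: int,
    trained_on: np.ndarray | None = None,
) -> PlsModel:
    """Fit a PLS1 model with ``n_lv`` latent variables by NIPALS."""
    Xv = X.values if isinstance(X, SpectraMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n < 3:
        raise ValueError("PLS needs at least 3 samples")
    if y.size != n:
        raise ValueError("y length must match the number of spectra")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")
    x_mean = Xv.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_components(Xv - x_mean, y - y_mean, n_lv)
    if W.shape[1] == 0:
        raise ValueError("no PLS component could be extracted (X'y is zero)")
    coefs = _coefficients_path(W, P, q)
    return PlsModel(
        n_lv=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=coefs[:, -1],
        trained_on=None if trained_on is None else np.asarray(trained_on, int),
    )


def pls_predict(model: PlsModel, X: SpectraMatrix | np.ndarray) -> np.ndarray:
    """Predict the trait for spectra restricted to the model's variables."""
    return model.predict(X)


def rmsecv_curve(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: FoldAssignment,
) -> np.ndarray:
    """10-fold (or k-fold) RMSECV for every LV count 1..max_lv.

    One NIPALS fit of ``max_lv`` components per fold; every truncation of
    the component sequence is evaluated on the held-out fold.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    max_lv = int(min(max_lv, p))
    sse = None
    for fold in range(folds.k):
        val = folds.fold_of_sample == fold
        train = ~val
        n_train = int(train.sum())
        cap = min(max_lv, n_train - 1)
        x_mean = X[train].mean(axis=0)
        y_mean = y[train].mean()
        W, P, q, _ = _nipals_components(X[train] - x_mean, y[train] - y_mean, cap)
        coefs = _coefficients_path(W, P, q)  # p x A_fold
        preds = y_mean + (X[val] - x_mean) @ coefs  # n_val x A_fold
        err = preds - y[val][:, None]
        fold_sse = np.square(err).sum(axis=0)
        if fold_sse.size < max_lv:  # short fit: pad with its last value
            fold_sse = np.concatenate(
                [fold_sse, np.full(max_lv - fold_sse.size, fold_sse[-1])]
            )
        sse = fold_sse if sse is None else sse + fold_sse
    return np.sqrt(sse / n)


def select_lv(
    X: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    max_lv: int = 20,
    folds: FoldAssignment | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Pick the LV count minimizing k-fold RMSECV over 1..max_lv.

    Ties go to the smaller LV count.  ``max_lv`` is silently capped at
    min(n_train - 1, p) with a log message.
    """
    Xv = X.values if isinstance(X, SpectraMatrix) else np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = Xv.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if folds is None:
        folds = make_folds(n, min(cv_folds, n), seed)
    smallest_train = n - int(np.bincount(folds.fold_of_sample).max())
    cap = min(max_lv, smallest_train - 1, p)
    if cap < max_lv:
        logger.info("max_lv capped from %d to %d (n_train/p limit)", max_lv, cap)
    curve = rmsecv_curve(Xv, y, cap, folds)
    n_lv = int(np.argmin(curve)) + 1  # argmin takes the smallest index on ties
    return n_lv, curve


# -- discriminant variant ----------------------------------------------------

def plsda_fit(
    X: SpectraMatrix | np.ndarray,
    weeks: np.ndarray,
    n_lv: int,
    class_range: tuple[int, int] = (1, 7),
) -> PlsModel:
    """PLS-DA on the ordinal storage-week label (identical PLS machinery)."""
    weeks = np.asarray(weeks)
    if not np.allclose(weeks, np.round(weeks)):
        raise ValueError("week labels must be integers")
    if np.unique(weeks).size < 2:
        raise ValueError("PLS-DA needs at least 2 distinct classes")
    lo, hi = class_range
    if weeks.min() < lo or weeks.max() > hi:
        raise ValueError(f"week labels must lie in [{lo}, {hi}]")
    model = pls_fit(X, weeks.astype(float), n_lv)
    model.class_range = (int(lo), int(hi))
    return model


def plsda_classify(model: PlsModel, X: SpectraMatrix | np.ndarray) -> np.ndarray:
    """Round the continuous prediction to the nearest class.

    The boundary between adjacent classes is their midpoint; exact
    half-points round up.  Results are clamped to the class range.
    """
    if model.class_range is None:
        raise ValueError("model was not fitted by plsda_fit")
    lo, hi = model.class_range
    cont = model.predict(X)
    cls = np.floor(cont + 0.5).astype(int)  # round half up
    return np.clip(cls, lo, hi)
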