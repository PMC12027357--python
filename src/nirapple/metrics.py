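"""Model evaluation metrics and the optional reference-value outlier filter.

RMSEC/RMSEP are root mean square errors on the calibration/prediction sets,
in trait units (°Brix for SSC, N for firmness).  Rc/Rp are Pearson
correlations between predicted and measured values, so they live in
[-1, 1] (they are not coefficients of determination).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpectraMatrix
from .model import PlsModel


@dataclass
class RegressionMetrics:
    rmsec: float
    rmsep: float
    rc: float | None
    rp: float | None
    n_lv: int


@dataclass
class DiscriminantResult:
    true_week: np.ndarray
    predicted_week: np.ndarray
    misclassification_rate_calibration: float
    misclassification_rate_prediction: float


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def pearson(actual: np.ndarray, predicted: np.ndarray) -> float | None:
    """Pearson correlation; None (with a warning) when either side is constant."""
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    if np.std(actual) == 0 or np.std(predicted) == 0:
        warnings.warn("correlation undefined: zero variance", stacklevel=2)
        return None
    return float(np.corrcoef(actual, predicted)[0, 1])


def evaluate_regression(
    model: PlsModel,
    X_cal: SpectraMatrix | np.ndarray,
    y_cal: np.ndarray,
    X_pred: SpectraMatrix | np.ndarray,
    y_pred: np.ndarray,
) -> RegressionMetrics:
    """RMSEC/RMSEP and Rc/Rp of a fitted model on both sets."""
    y_cal = np.asarray(y_cal, float)
    y_pred = np.asarray(y_pred, float)
    if y_cal.size == 0 or y_pred.size == 0:
        raise ValueError("calibration and prediction sets must be non-empty")
    yhat_cal = model.predict(X_cal)
    yhat_pred = model.predict(X_pred)
    return RegressionMetrics(
        rmsec=rmse(y_cal, yhat_cal),
        rmsep=rmse(y_pred, yhat_pred),
        rc=pearson(y_cal, yhat_cal),
        rp=pearson(y_pred, yhat_pred),
        n_lv=model.n_lv,
    )


def misclassification_rate(true_weeks: np.ndarray, predicted_weeks: np.ndarray) -> float:
    """Fraction of mismatched class labels."""
    true_weeks = np.asarray(true_weeks)
    predicted_weeks = np.asarray(predicted_weeks)
    if true_weeks.size == 0:
        raise ValueError("empty label sequence")
    if true_weeks.size != predicted_weeks.size:
        raise ValueError("label sequences differ in length")
    return float(np.mean(true_weeks != predicted_weeks))


def outlier_filter(
    references: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    max_removal_fraction: float = 0.05,
) -> pd.DataFrame:
    """Iterative Shapiro-Wilk screening of anomalous reference values.

    While a Shapiro-Wilk test rejects normality of the trait at ``alpha``,
    remove the sample with the largest studentized distance from the trait
    mean; removals are capped at ``max_removal_fraction`` of the samples.
    Off by default in every pipeline; returns the input unchanged when
    normality already holds.
    """
    if len(references) < 8:
        raise ValueError("outlier filter needs at least 8 samples")
    kept = references.reset_index(drop=True)
    max_removals = int(np.floor(max_removal_fraction * len(kept)))
    removed = 0
    while removed < max_removals:
        x = kept[trait].to_numpy(dtype=float)
        if np.std(x, ddof=1) == 0:
            break
        _, p = stats.shapiro(x)
        if p >= alpha:
            break
        z = np.abs(x - x.mean()) / np.std(x, ddof=1)
        kept = kept.drop(index=int(np.argmax(z))).reset_index(drop=True)
        removed += 1
    return kept
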