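"""Calibration/prediction splitting and cross-validation fold assignment.

The calibration set is chosen by the Kennard-Stone algorithm: a
deterministic greedy maximin rule that picks a space-filling subset of the
spectra, so the calibration set spans the spectral variation and the
prediction set interpolates it.  A seeded uniform random split is available
as an alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import SpectraMatrix


@dataclass
class SplitResult:
    """Disjoint calibration/prediction index partition (ascending order)."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        self.calibration_idx = np.asarray(self.calibration_idx, dtype=int)
        self.prediction_idx = np.asarray(self.prediction_idx, dtype=int)
        if np.intersect1d(self.calibration_idx, self.prediction_idx).size:
            raise ValueError("calibration and prediction sets overlap")

    def to_json(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        doc = {
            "calibration": self.calibration_idx.tolist(),
            "prediction": self.prediction_idx.tolist(),
            "ratio": self.ratio,
        }
        if sample_ids is not None:
            doc["calibration_ids"] = [sample_ids[i] for i in self.calibration_idx]
            doc["prediction_ids"] = [sample_ids[i] for i in self.prediction_idx]
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            np.asarray(doc["calibration"], int),
            np.asarray(doc["prediction"], int),
            float(doc.get("ratio", float("nan"))),
        )


@dataclass
class FoldAssignment:
    """Cross-validation fold label per sample (values 0..k-1)."""

    fold_of_sample: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_of_sample = np.asarray(self.fold_of_sample, dtype=int)
        sizes = np.bincount(self.fold_of_sample, minlength=self.k)
        if sizes.min() == 0:
            raise ValueError("every fold must be non-empty")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")


def calibration_size(n: int, ratio: float = 3.0) -> int:
    """Calibration count for a ratio:1 split; round-half-up on n*ratio/(ratio+1)."""
    return int(np.floor(n * ratio / (ratio + 1.0) + 0.5))


def kennard_stone(
    spectra: SpectraMatrix | np.ndarray, n_calibration: int
) -> SplitResult:
    """Greedy maximin (Kennard-Stone) selection of the calibration set.

    Start from the two mutually farthest samples (Euclidean distance over
    wavelengths), then repeatedly add the sample whose minimum distance to
    the selected set is largest, until ``n_calibration`` samples are chosen.
    Ties are broken by lowest sample index, so the split is deterministic
    and platform-independent.
    """
    X = spectra.values if isinstance(spectra, SpectraMatrix) else np.asarray(spectra, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n_calibration < 2:
        raise ValueError("Kennard-Stone needs n_calibration >= 2")
    if n_calibration > n:
        raise ValueError("n_calibration exceeds the number of samples")

    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    # farthest pair; argmax of the flattened matrix lands on the lowest
    # (row, col) pair under ties
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    first, second = min(i, j), max(i, j)
    np.fill_diagonal(d2, 0.0)

    selected = np.zeros(n, dtype=bool)
    selected[[first, second]] = True
    min_d2 = np.minimum(d2[first], d2[second])
    min_d2[[first, second]] = -np.inf
    for _ in range(n_calibration - 2):
        nxt = int(np.argmax(min_d2))  # argmax takes the lowest index on ties
        selected[nxt] = True
        min_d2 = np.minimum(min_d2, d2[nxt])
        min_d2[nxt] = -np.inf

    cal = np.flatnonzero(selected)
    pred = np.flatnonzero(~selected)
    ratio = n_calibration / max(n - n_calibration, 1)
    return SplitResult(cal, pred, ratio)


def random_split(n: int, n_calibration: int, seed: int) -> SplitResult:
    """Seeded uniform random alternative to Kennard-Stone."""
    if n_calibration < 1 or n_calibration > n:
        raise ValueError("invalid calibration size")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = np.sort(perm[:n_calibration])
    pred = np.sort(perm[n_calibration:])
    return SplitResult(cal, pred, n_calibration / max(n - n_calibration, 1))


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Seeded uniform permutation dealt round-robin into k folds."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of_sample = np.empty(n, dtype=int)
    fold_of_sample[perm] = np.arange(n) % k
    return FoldAssignment(fold_of_sample, k, seed)
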