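"""Wavelength selection: uninformative variable elimination (UVE) and
competitive adaptive reweighted sampling (CARS).

UVE appends artificial noise variables to the spectral matrix, measures the
stability of every variable's PLS regression coefficient across
leave-one-out submodels (mean over SD), and eliminates real variables whose
absolute stability does not exceed the largest absolute stability observed
among the noise variables — variables no more reliable than noise carry no
information about the trait.

CARS runs a Monte-Carlo elimination loop: at each iteration a PLS model is
fitted on a random subset of the calibration samples restricted to the
currently retained wavelengths; an exponentially decreasing function (EDF)
forces the retained count down from all p variables at the first iteration
to 2 at the last, keeping the wavelengths with the largest absolute
regression coefficients; adaptive reweighted sampling (ARS) then draws the
retained set with probability proportional to coefficient magnitude
(with replacement, de-duplicated).  The subset minimizing k-fold RMSECV
over the loop is returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import SpectraMatrix
from .model import pls_fit, rmsecv_curve
from .partition import make_folds


@dataclass
class UveResult:
    """Stability diagnostics and retained wavelength indices from UVE."""

    stability: np.ndarray          # real variables then appended noise variables
    threshold: float
    selected_idx: np.ndarray       # subset of 0..p-1 (real variables only)
    n_noise: int
    n_real: int

    def to_json(self, path: str | Path, wavelengths_nm: np.ndarray | None = None) -> None:
        doc = {
            "stability": self.stability.tolist(),
            "threshold": self.threshold,
            "selected_idx": self.selected_idx.tolist(),
            "n_noise": self.n_noise,
            "n_real": self.n_real,
        }
        if wavelengths_nm is not None:
            doc["selected_wavelengths_nm"] = np.asarray(wavelengths_nm)[
                self.selected_idx
            ].tolist()
        Path(path).write_text(json.dumps(doc), encoding="utf-8")


@dataclass
class CarsResult:
    """Per-iteration trace and the RMSECV-optimal wavelength subset."""

    rmsecv_trace: np.ndarray
    subset_sizes: np.ndarray
    best_iteration: int            # 0-based position in the trace
    selected_idx: np.ndarray
    n_runs: int
    edf_a: float
    edf_k: float
    best_n_lv: int = 0
    subsets: list[np.ndarray] = field(default_factory=list, repr=False)

    def to_json(self, path: str | Path, wavelengths_nm: np.ndarray | None = None) -> None:
        doc = {
            "rmsecv_trace": self.rmsecv_trace.tolist(),
            "subset_sizes": self.subset_sizes.tolist(),
            "best_iteration": self.best_iteration,
            "selected_idx": self.selected_idx.tolist(),
            "n_runs": self.n_runs,
            "edf_a": self.edf_a,
            "edf_k": self.edf_k,
            "best_n_lv": self.best_n_lv,
        }
        if wavelengths_nm is not None:
            doc["selected_wavelengths_nm"] = np.asarray(wavelengths_nm)[
                self.selected_idx
            ].tolist()
        Path(path).write_text(json.dumps(doc), encoding="utf-8")


def _as_matrix(X: SpectraMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, SpectraMatrix) else np.asarray(X, float)


def uve_select(
    X: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    n_lv: int,
    n_noise: int | None = None,
    noise_scale: float = 1e-10,
    cutoff_factor: float = 1.0,
    seed: int = 0,
    n_submodels: int | None = None,
    submodel_fraction: float = 0.8,
) -> UveResult:
    """Uninformative variable elimination with leave-one-out submodels.

    ``n_noise`` defaults to the number of real spectral variables.  The
    appended noise columns are uniform random values scaled to
    ``noise_scale`` times the mean absolute absorbance — small enough not
    to perturb the fit, but yielding nonzero coefficients whose stability
    calibrates the elimination threshold
    (``cutoff_factor * max_noise |stability|``).

    By default one submodel is fitted per leave-one-out sample deletion
    (deterministic); pass ``n_submodels`` to use seeded Monte-Carlo
    resampling instead (each submodel on a ``submodel_fraction`` subset).
    """
    Xv = _as_matrix(X)
    y = np.asarray(y, float)
    n, p = Xv.shape
    if n < 3:
        raise ValueError("UVE needs at least 3 samples")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_noise is None:
        n_noise = p
    if n_noise < 1:
        raise ValueError("n_noise must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = noise_scale * np.mean(np.abs(Xv))
    noise = rng.uniform(0.0, 1.0, size=(n, n_noise)) * scale
    Xa = np.hstack([Xv, noise])

    if n_submodels is None:
        submodel_rows = [np.delete(np.arange(n), j) for j in range(n)]
    else:
        size = max(3, int(round(submodel_fraction * n)))
        submodel_rows = [
            np.sort(rng.choice(n, size=size, replace=False))
            for _ in range(n_submodels)
        ]

    coefs = np.empty((len(submodel_rows), p + n_noise))
    for j, rows in enumerate(submodel_rows):
        lv = min(n_lv, rows.size - 1, p + n_noise)
        model = pls_fit(Xa[rows], y[rows], lv)
        coefs[j] = model.coefficients

    mean_b = coefs.mean(axis=0)
    sd_b = coefs.std(axis=0, ddof=1)
    zero_sd = sd_b == 0
    if np.any(zero_sd):
        warnings.warn(
            f"{int(zero_sd.sum())} variables have zero coefficient SD across "
            "submodels; their stability is set to signed infinity",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        # sd == 0: signed infinity (perfectly stable), or 0 when the
        # coefficient itself is identically zero
        stability = np.where(
            zero_sd,
            np.where(mean_b == 0, 0.0, np.sign(mean_b) * np.inf),
            mean_b / np.where(zero_sd, 1.0, sd_b),
        )
    noise_stab = np.abs(stability[p:])
    finite_noise = noise_stab[np.isfinite(noise_stab)]
    threshold = cutoff_factor * float(
        finite_noise.max() if finite_noise.size else noise_stab.max()
    )
    selected = np.flatnonzero(np.abs(stability[:p]) > threshold)
    return UveResult(
        stability=stability,
        threshold=threshold,
        selected_idx=selected,
        n_noise=n_noise,
        n_real=p,
    )


def cars_edf_constants(p: int, n_runs: int) -> tuple[float, float]:
    """EDF constants a, k with r_1 = 1 and r_{n_runs} = 2/p for r_i = a e^{-k i}."""
    if p < 2 or n_runs < 2:
        raise ValueError("EDF needs p >= 2 and n_runs >= 2")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = float(np.exp(k))
    return a, float(k)


def cars_select(
    X: SpectraMatrix | np.ndarray,
    y: np.ndarray,
    n_runs: int = 100,
    cv_folds: int = 10,
    max_lv: int = 20,
    mc_fraction: float = 0.8,
    seed: int = 0,
    cv_repeats: int = 3,
) -> CarsResult:
    """Competitive adaptive reweighted sampling over ``n_runs`` iterations.

    Each iteration records the k-fold RMSECV of the current retained subset
    (LV count re-selected up to ``max_lv`` by the inner CV minimum), fits a
    PLS model on a random ``mc_fraction`` of the samples, and shrinks the
    subset by EDF forced retention followed by ARS weighted resampling.
    Ties on the minimum RMSECV go to the earliest iteration.

    The RMSECV is averaged over ``cv_repeats`` independent fold assignments
    (repeated k-fold CV): the trace minimum picks one subset out of
    ``n_runs``, and a single fold assignment is noisy enough to favor
    spuriously small subsets.
    """
    Xv = _as_matrix(X)
    y = np.asarray(y, float)
    n, p = Xv.shape
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0.0 < mc_fraction < 1.0:
        raise ValueError("mc_fraction must be in (0, 1)")
    if p < 2:
        raise ValueError("need at least 2 variables")

    ss = np.random.SeedSequence(seed).spawn(1 + cv_repeats)
    rng = np.random.default_rng(ss[0])
    fold_sets = [
        make_folds(n, min(cv_folds, n), int(s.generate_state(1)[0] % (2**31)))
        for s in ss[1:]
    ]
    smallest_train = n - max(
        int(np.bincount(f.fold_of_sample).max()) for f in fold_sets
    )

    edf_a, edf_k = cars_edf_constants(p, n_runs)
    retained = np.arange(p)
    trace: list[float] = []
    sizes: list[int] = []
    subsets: list[np.ndarray] = []
    best_lvs: list[int] = []
    mc_size = max(3, int(round(mc_fraction * n)))

    for i in range(1, n_runs + 1):
        cap = min(max_lv, smallest_train - 1, retained.size)
        curve = np.mean(
            [rmsecv_curve(Xv[:, retained], y, cap, f) for f in fold_sets], axis=0
        )
        best_lv = int(np.argmin(curve)) + 1
        trace.append(float(curve.min()))
        sizes.append(retained.size)
        subsets.append(retained.copy())
        best_lvs.append(best_lv)
        if i == n_runs:
            break

        mc_rows = np.sort(rng.choice(n, size=mc_size, replace=False))
        lv = min(best_lv, mc_size - 1, retained.size)
        model = pls_fit(Xv[mc_rows][:, retained], y[mc_rows], lv)
        weight = np.abs(model.coefficients)

        # EDF retention count for the next iteration (number of draws below;
        # NOT capped at the current subset size, so de-duplication stays mild)
        n_edf = max(2, int(round(edf_a * np.exp(-edf_k * (i + 1)) * p)))
        # forced retention: keep the top-|b| wavelengths (stable order breaks
        # ties by lowest index)
        order = np.argsort(-weight, kind="stable")[: min(n_edf, retained.size)]
        edf_set = retained[order]
        edf_w = weight[order]
        # ARS: n_edf weighted draws with replacement, then de-duplicate
        if edf_w.sum() > 0:
            probs = edf_w / edf_w.sum()
        else:
            probs = np.full(edf_set.size, 1.0 / edf_set.size)
        draw = rng.choice(edf_set, size=n_edf, replace=True, p=probs)
        retained = np.unique(draw)
        if retained.size < 2:
            warnings.warn(
                f"CARS retained set collapsed below 2 variables at iteration "
                f"{i}; stopping early",
                stacklevel=2,
            )
            break

    trace_arr = np.asarray(trace)
    best = int(np.argmin(trace_arr))  # argmin -> earliest iteration on ties
    return CarsResult(
        rmsecv_trace=trace_arr,
        subset_sizes=np.asarray(sizes, int),
        best_iteration=best,
        selected_idx=subsets[best],
        n_runs=n_runs,
        edf_a=edf_a,
        edf_k=edf_k,
        best_n_lv=best_lvs[best],
        subsets=subsets,
    )
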