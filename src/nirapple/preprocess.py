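"""Spectral preprocessing: SNV, MSC and per-spectrum normalization.

All three transforms are row-wise corrections for path-length and scatter
differences between fruit.  MSC is the only one with fit/apply separation:
its reference spectrum is the calibration-set mean, and prediction spectra
are always corrected against that stored reference (never their own mean),
so no information leaks from the prediction set into the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import SpectraMatrix

METHODS = ("none", "normalization", "vector_norm", "msc", "snv")


@dataclass
class PreprocessState:
    """Fitted preprocessing configuration.

    ``reference_spectrum`` is present iff ``method == "msc"``.
    """

    method: str = "none"
    reference_spectrum: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if (self.method == "msc") != (self.reference_spectrum is not None):
            raise ValueError("reference_spectrum present iff method is msc")
        if self.reference_spectrum is not None:
            self.reference_spectrum = np.asarray(self.reference_spectrum, dtype=float)

    def to_json(self, path: str | Path) -> None:
        doc = {"method": self.method}
        if self.reference_spectrum is not None:
            doc["reference_spectrum"] = self.reference_spectrum.tolist()
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessState":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        ref = doc.get("reference_spectrum")
        return cls(
            method=doc["method"],
            reference_spectrum=None if ref is None else np.asarray(ref, float),
        )


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: center and scale each spectrum.

    Every row is transformed to mean 0 and sample standard deviation 1
    (n-1 denominator).  Constant rows have no scale and are an error.
    """
    X = spectra.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"constant spectrum (zero variance): sample "
            f"{spectra.sample_ids[bad[0]]!r}"
        )
    return spectra.with_values((X - mean) / sd)


def msc_fit(calibration: SpectraMatrix) -> PreprocessState:
    """Fit MSC: the reference is the mean calibration spectrum."""
    if calibration.n_samples < 1:
        raise ValueError("MSC needs at least one calibration spectrum")
    return PreprocessState(
        method="msc", reference_spectrum=calibration.values.mean(axis=0)
    )


def msc_apply(spectra: SpectraMatrix, state: PreprocessState) -> SpectraMatrix:
    """Multiplicative scatter correction against a fitted reference.

    Each spectrum x is OLS-regressed on the reference r (x = a + b*r over
    wavelengths); the corrected spectrum is (x - a) / b.
    """
    if state.method != "msc" or state.reference_spectrum is None:
        raise ValueError("state must come from msc_fit")
    r = state.reference_spectrum
    if r.size != spectra.n_wavelengths:
        raise ValueError("reference spectrum length does not match wavelength grid")
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    X = spectra.values
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    small = np.flatnonzero(np.abs(b) < 1e-12)
    if small.size:
        raise ValueError(
            f"MSC slope ~0 (spectrum uncorrelated with reference): sample "
            f"{spectra.sample_ids[small[0]]!r}"
        )
    a = X.mean(axis=1) - b * r.mean()
    return spectra.with_values((X - a[:, None]) / b[:, None])


def normalize(spectra: SpectraMatrix) -> SpectraMatrix:
    """Per-spectrum min-max scaling to [0, 1]."""
    X = spectra.values
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    bad = np.flatnonzero((hi - lo).ravel() == 0)
    if bad.size:
        raise ValueError(
            f"constant spectrum (min == max): sample "
            f"{spectra.sample_ids[bad[0]]!r}"
        )
    return spectra.with_values((X - lo) / (hi - lo))


def vector_norm(spectra: SpectraMatrix) -> SpectraMatrix:
    """Scale each spectrum to unit Euclidean norm (alternative normalization)."""
    X = spectra.values
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if bad.size:
        raise ValueError(
            f"all-zero spectrum: sample {spectra.sample_ids[bad[0]]!r}"
        )
    return spectra.with_values(X / norms)


def fit(method: str, calibration: SpectraMatrix) -> PreprocessState:
    """Fit the named method on calibration spectra."""
    if method == "msc":
        return msc_fit(calibration)
    if method not in METHODS:
        raise ValueError(f"unknown preprocessing method {method!r}")
    return PreprocessState(method=method)


def apply(spectra: SpectraMatrix, state: PreprocessState) -> SpectraMatrix:
    """Apply a fitted preprocessing state to any spectra set."""
    if state.method == "none":
        return spectra
    if state.method == "normalization":
        return normalize(spectra)
    if state.method == "vector_norm":
        return vector_norm(spectra)
    if state.method == "snv":
        return snv(spectra)
    return msc_apply(spectra, state)
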