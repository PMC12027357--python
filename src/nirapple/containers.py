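"""Shared in-memory containers for spectral data and their CSV dialects.

The package moves two tables around:

* ``spectra.csv`` — one sample per row; first column ``sample_id``, remaining
  column headers are wavelengths in nm printed with two decimals.
* ``references.csv`` — columns ``sample_id, variety, temperature_c, week,
  ssc_brix, firmness_n``.

Both are UTF-8, comma-delimited, with ``.`` as the decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REFERENCE_COLUMNS = [
    "sample_id",
    "variety",
    "temperature_c",
    "week",
    "ssc_brix",
    "firmness_n",
]


@dataclass
class SpectraMatrix:
    """Absorbance block (samples x wavelengths) with an explicit nm grid.

    Parameters
    ----------
    values
        Real matrix, one spectrum per row (absorbance, unitless).
    wavelengths_nm
        Strictly increasing wavelength grid, one entry per column.
    sample_ids
        Unique sample labels, one per row.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectra values must be a 2-D matrix")
        if self.values.shape[1] != self.wavelengths_nm.size:
            raise ValueError(
                f"{self.values.shape[1]} spectral columns but "
                f"{self.wavelengths_nm.size} wavelengths"
            )
        if self.wavelengths_nm.size >= 2 and not np.all(
            np.diff(self.wavelengths_nm) > 0
        ):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite entries")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("one sample_id required per spectrum row")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def take(self, idx) -> "SpectraMatrix":
        """Row subset (new object, copied values)."""
        idx = np.asarray(idx)
        return SpectraMatrix(
            self.values[idx].copy(),
            self.wavelengths_nm,
            [self.sample_ids[i] for i in idx],
        )

    def select_wavelengths(self, idx) -> "SpectraMatrix":
        """Column subset in ascending wavelength order."""
        idx = np.sort(np.asarray(idx, dtype=int))
        return SpectraMatrix(
            self.values[:, idx].copy(),
            self.wavelengths_nm[idx],
            list(self.sample_ids),
        )

    def with_values(self, values: np.ndarray) -> "SpectraMatrix":
        """Same grid and ids, new absorbance block (used by transforms)."""
        return SpectraMatrix(values, self.wavelengths_nm, list(self.sample_ids))


def write_spectra_csv(spectra: SpectraMatrix, path: str | Path) -> None:
    cols = [f"{w:.2f}" for w in spectra.wavelengths_nm]
    df = pd.DataFrame(spectra.values, columns=cols)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError("first column of spectra.csv must be sample_id")
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    return SpectraMatrix(
        df.iloc[:, 1:].to_numpy(dtype=float),
        wavelengths,
        df["sample_id"].astype(str).tolist(),
    )


def validate_references(references: pd.DataFrame) -> pd.DataFrame:
    """Check the reference-table schema and return the frame unchanged."""
    missing = [c for c in REFERENCE_COLUMNS if c not in references.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    if references["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in reference table")
    for col in ("ssc_brix", "firmness_n"):
        if not np.all(np.isfinite(references[col].to_numpy(dtype=float))):
            raise ValueError(f"non-finite values in {col}")
    return references


def write_references_csv(references: pd.DataFrame, path: str | Path) -> None:
    validate_references(references)
    references.loc[:, REFERENCE_COLUMNS].to_csv(path, index=False)


def read_references_csv(path: str | Path) -> pd.DataFrame:
    return validate_references(pd.read_csv(path))
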