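"""Full-study orchestration: preprocessing x selection x model grids.

Regression models are fitted per (trait, storage temperature) with the
varieties pooled; storage-week discrimination is fitted per
(variety, temperature) group.  Every grid cell runs the same recipe:
Kennard-Stone 3:1 split on the raw spectra, preprocessing fitted on the
calibration set only, optional wavelength selection on the calibration set,
latent-variable count chosen by k-fold RMSECV, final fit and evaluation on
the held-out prediction set.  A (config, seed) pair fully determines every
output file.
"""

from __future__ import annotations

import logging
import traceback
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .containers import SpectraMatrix
from .datasets import SyntheticDataset
from .metrics import evaluate_regression, misclassification_rate
from .model import plsda_classify, plsda_fit, pls_fit, select_lv
from .partition import calibration_size, kennard_stone, make_folds
from .selection import cars_select, uve_select

logger = logging.getLogger(__name__)

TRAIT_LABELS = {"ssc_brix": "SSC", "firmness_n": "Firmness"}

REGRESSION_COLUMNS = [
    "quality_parameter",
    "temperature",
    "treatment",
    "latent_variables",
    "rmsec",
    "rc",
    "rmsep",
    "rp",
    "n_variables",
    "error",
]

DISCRIMINANT_COLUMNS = [
    "variety",
    "temperature",
    "latent_variables",
    "misclassification_rate_calibration",
    "misclassification_rate_prediction",
    "n_calibration",
    "n_prediction",
    "error",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a grid run."""

    seed: int = 0
    traits: list[str] = field(default_factory=lambda: ["ssc_brix", "firmness_n"])
    temperatures: list[float] | None = None
    preprocessing: list[str] = field(
        default_factory=lambda: ["normalization", "msc", "snv"]
    )
    selections: list[str] = field(default_factory=lambda: ["cars", "uve"])
    split_ratio: float = 3.0
    max_lv: int = 20
    cv_folds: int = 10
    cars_runs: int = 100
    cars_mc_fraction: float = 0.8
    uve_noise_scale: float = 1e-10
    uve_cutoff_factor: float = 1.0
    uve_n_submodels: int | None = None  # None = leave-one-out
    # storage-week discrimination models spectra after scatter correction
    discriminant_preprocessing: str = "snv"
    out_dir: str = "results"
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _cell_seed(base_seed: int, *key: object) -> int:
    """Deterministic per-cell child seed (stable across processes and runs)."""
    digest = zlib.crc32("|".join(map(str, key)).encode("utf-8"))
    h = np.random.SeedSequence([base_seed, digest])
    return int(h.generate_state(1)[0] % (2**31))


def fit_treatment(
    spectra: SpectraMatrix,
    y: np.ndarray,
    split,
    method: str,
    selection: str | None,
    config: RunConfig,
    seed: int,
) -> dict:
    """One grid cell: preprocess, optionally select wavelengths, fit, evaluate."""
    cal = spectra.take(split.calibration_idx)
    pred = spectra.take(split.prediction_idx)
    y_cal = y[split.calibration_idx]
    y_pred = y[split.prediction_idx]

    state = preprocess.fit(method, cal)
    cal_p = preprocess.apply(cal, state)
    pred_p = preprocess.apply(pred, state)

    selected_idx = None
    if selection == "cars":
        result = cars_select(
            cal_p,
            y_cal,
            n_runs=config.cars_runs,
            cv_folds=config.cv_folds,
            max_lv=config.max_lv,
            mc_fraction=config.cars_mc_fraction,
            seed=seed,
        )
        selected_idx = result.selected_idx
    elif selection == "uve":
        lv0, _ = select_lv(
            cal_p, y_cal, max_lv=config.max_lv, cv_folds=config.cv_folds, seed=seed
        )
        result = uve_select(
            cal_p,
            y_cal,
            n_lv=lv0,
            noise_scale=config.uve_noise_scale,
            cutoff_factor=config.uve_cutoff_factor,
            seed=seed,
            n_submodels=config.uve_n_submodels,
        )
        selected_idx = result.selected_idx
        if selected_idx.size < 2:
            raise RuntimeError("UVE retained fewer than 2 wavelengths")
    elif selection is not None:
        raise ValueError(f"unknown selection method {selection!r}")

    if selected_idx is not None:
        cal_p = cal_p.select_wavelengths(selected_idx)
        pred_p = pred_p.select_wavelengths(selected_idx)

    folds = make_folds(cal_p.n_samples, min(config.cv_folds, cal_p.n_samples), seed)
    n_lv, _ = select_lv(cal_p, y_cal, max_lv=config.max_lv, folds=folds)
    model = pls_fit(cal_p, y_cal, n_lv, trained_on=selected_idx)
    metrics = evaluate_regression(model, cal_p, y_cal, pred_p, y_pred)
    return {
        "latent_variables": model.n_lv,
        "rmsec": metrics.rmsec,
        "rc": metrics.rc,
        "rmsep": metrics.rmsep,
        "rp": metrics.rp,
        "n_variables": cal_p.n_wavelengths,
    }


def _treatments(config: RunConfig) -> list[tuple[str, str | None, str]]:
    """(preprocess, selection, label) rows: raw, each preprocess, each combo."""
    rows: list[tuple[str, str | None, str]] = [("none", None, "Raw spectra")]
    for method in config.preprocessing:
        rows.append((method, None, method.capitalize()))
    for method in config.preprocessing:
        for sel in config.selections:
            rows.append((method, sel, f"{method.capitalize()}-{sel}"))
    return rows


def run_regression_grid(
    config: RunConfig, dataset: SyntheticDataset
) -> pd.DataFrame:
    """Fit every preprocessing x selection treatment per (trait, temperature).

    Varieties are pooled within a temperature.  A failing cell is recorded
    in the ``error`` column and does not abort the grid.
    """
    references = dataset.references
    temps = config.temperatures or sorted(references["temperature_c"].unique())
    rows = []
    for trait in config.traits:
        for temperature in temps:
            mask = references["temperature_c"].to_numpy() == float(temperature)
            idx = np.flatnonzero(mask)
            spectra = dataset.spectra.take(idx)
            y = references.loc[mask, trait].to_numpy(dtype=float)
            split = kennard_stone(
                spectra, calibration_size(spectra.n_samples, config.split_ratio)
            )
            for method, sel, label in _treatments(config):
                seed = _cell_seed(config.seed, trait, temperature, label)
                row = {
                    "quality_parameter": TRAIT_LABELS.get(trait, trait),
                    "temperature": float(temperature),
                    "treatment": label,
                    "error": "",
                }
                try:
                    row.update(
                        fit_treatment(spectra, y, split, method, sel, config, seed)
                    )
                    logger.info(
                        "%s %s°C %s: LV=%s RMSEP=%.3f Rp=%.3f",
                        row["quality_parameter"],
                        temperature,
                        label,
                        row["latent_variables"],
                        row["rmsep"],
                        row["rp"] if row["rp"] is not None else float("nan"),
                    )
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    logger.warning("cell failed (%s, %s, %s): %s", trait, temperature, label, exc)
                    logger.debug(traceback.format_exc())
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows, columns=REGRESSION_COLUMNS)


def run_discriminant_grid(
    config: RunConfig, dataset: SyntheticDataset
) -> pd.DataFrame:
    """PLS-DA storage-week discrimination per (variety, temperature) group.

    Misclassification rates are reported to 3 decimals.
    """
    references = dataset.references
    groups = (
        references[["variety", "temperature_c"]]
        .drop_duplicates()
        .sort_values(["temperature_c", "variety"])
        .itertuples(index=False)
    )
    rows = []
    for variety, temperature in groups:
        mask = (
            (references["variety"] == variety)
            & (references["temperature_c"] == temperature)
        ).to_numpy()
        idx = np.flatnonzero(mask)
        spectra = dataset.spectra.take(idx)
        weeks = references.loc[mask, "week"].to_numpy(dtype=int)
        seed = _cell_seed(config.seed, "plsda", variety, temperature)
        row = {
            "variety": variety,
            "temperature": float(temperature),
            "error": "",
        }
        try:
            split = kennard_stone(
                spectra, calibration_size(spectra.n_samples, config.split_ratio)
            )
            cal = spectra.take(split.calibration_idx)
            pred = spectra.take(split.prediction_idx)
            state = preprocess.fit(config.discriminant_preprocessing, cal)
            cal = preprocess.apply(cal, state)
            pred = preprocess.apply(pred, state)
            w_cal = weeks[split.calibration_idx]
            w_pred = weeks[split.prediction_idx]
            n_lv, _ = select_lv(
                cal, w_cal.astype(float), max_lv=config.max_lv,
                cv_folds=config.cv_folds, seed=seed,
            )
            week_range = (int(weeks.min()), int(weeks.max()))
            model = plsda_fit(cal, w_cal, n_lv, class_range=week_range)
            rate_cal = misclassification_rate(w_cal, plsda_classify(model, cal))
            rate_pred = misclassification_rate(w_pred, plsda_classify(model, pred))
            row.update(
                {
                    "latent_variables": model.n_lv,
                    "misclassification_rate_calibration": round(rate_cal, 3),
                    "misclassification_rate_prediction": round(rate_pred, 3),
                    "n_calibration": int(split.calibration_idx.size),
                    "n_prediction": int(split.prediction_idx.size),
                }
            )
            logger.info(
                "PLS-DA %s %s°C: LV=%d cal=%.3f pred=%.3f",
                variety, temperature, model.n_lv, rate_cal, rate_pred,
            )
        except Exception as exc:  # noqa: BLE001 - cell isolation
            logger.warning("PLS-DA cell failed (%s, %s): %s", variety, temperature, exc)
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=DISCRIMINANT_COLUMNS)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    report.to_csv(path, index=False, float_format="%.3f")


# -- optional figures --------------------------------------------------------

def plot_mean_spectra_by_week(dataset: SyntheticDataset, temperature: float, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    refs = dataset.references
    mask = refs["temperature_c"] == temperature
    fig, ax = plt.subplots(figsize=(7, 4))
    for week, grp in refs[mask].groupby("week"):
        rows = refs.index.get_indexer(grp.index)
        ax.plot(
            dataset.spectra.wavelengths_nm,
            dataset.spectra.values[rows].mean(axis=0),
            label=f"week {week}",
        )
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("absorbance")
    ax.set_title(f"Mean spectra by storage week at {temperature} °C")
    ax.legend(fontsize=7)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selection_trace(result, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    axes[0].plot(result.subset_sizes)
    axes[0].set_ylabel("retained wavelengths")
    axes[1].plot(result.rmsecv_trace)
    axes[1].axvline(result.best_iteration, color="red", ls="--", lw=1)
    axes[1].set_ylabel("RMSECV")
    axes[1].set_xlabel("iteration")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_predicted_vs_actual(y_true, y_pred, label: str, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(y_true, y_pred, s=10, alpha=0.6)
    lo = min(np.min(y_true), np.min(y_pred))
    hi = max(np.max(y_true), np.max(y_pred))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel(f"measured {label}")
    ax.set_ylabel(f"predicted {label}")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
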