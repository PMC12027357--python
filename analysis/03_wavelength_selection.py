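"""Wavelength selection on one variety's SSC calibration set.

Runs CARS and UVE on normalization-corrected Akesu spectra after a
Kennard-Stone 3:1 split; writes the selection diagnostics (JSON) under
results/selection/ and the trace figure to scratch/figures/.
"""

from pathlib import Path

import numpy as np

from nirapple import (
    calibration_size,
    cars_select,
    generate_dataset,
    kennard_stone,
    select_lv,
    uve_select,
)
from nirapple import preprocess as pp
from nirapple.pipeline import plot_selection_trace

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    dataset = generate_dataset(seed=SEED)
    refs = dataset.references
    mask = (refs["variety"] == "Akesu").to_numpy()
    spectra = dataset.spectra.take(np.flatnonzero(mask))
    y = refs.loc[mask, "ssc_brix"].to_numpy(dtype=float)

    split = kennard_stone(spectra, calibration_size(spectra.n_samples, 3.0))
    cal = spectra.take(split.calibration_idx)
    y_cal = y[split.calibration_idx]
    state = pp.fit("normalization", cal)
    cal_n = pp.apply(cal, state)

    out = ROOT / "results" / "selection"
    out.mkdir(parents=True, exist_ok=True)

    cars = cars_select(cal_n, y_cal, n_runs=100, cv_folds=10, max_lv=20, seed=SEED)
    cars.to_json(out / "cars_akesu_ssc.json", wavelengths_nm=cal_n.wavelengths_nm)
    kept = cal_n.wavelengths_nm[cars.selected_idx]
    print(f"CARS: {cars.selected_idx.size} wavelengths at iteration "
          f"{cars.best_iteration} (RMSECV {cars.rmsecv_trace[cars.best_iteration]:.3f} "
          f"vs full-spectrum {cars.rmsecv_trace[0]:.3f})")
    print(f"  retained span: {kept.min():.0f}-{kept.max():.0f} nm; the noisy "
          "grid edges are discarded first")
    plot_selection_trace(cars, ROOT / "scratch" / "figures" / "cars_trace.png")

    n_lv, _ = select_lv(cal_n, y_cal, max_lv=20, seed=SEED)
    uve = uve_select(cal_n, y_cal, n_lv=n_lv, seed=SEED, n_submodels=40)
    uve.to_json(out / "uve_akesu_ssc.json", wavelengths_nm=cal_n.wavelengths_nm)
    print(f"UVE: {uve.selected_idx.size} of {uve.n_real} wavelengths kept "
          f"({uve.n_noise} artificial noise variables set the threshold "
          f"{uve.threshold:.2f})")


if __name__ == "__main__":
    main()
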