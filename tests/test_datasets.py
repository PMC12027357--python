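"""Synthetic-data generator: design bookkeeping, seeding, and the
statistical structure the downstream chemometrics relies on."""

import numpy as np
import pytest

from nirapple import (
    QualityTrendParams,
    SpectralForwardModel,
    StudyDesign,
    generate_dataset,
    generate_references,
    generate_spectra,
    read_spectra_csv,
    snv,
)
from nirapple.containers import read_references_csv
from nirapple.datasets import (
    ConfigurationError,
    GroupTrend,
    dump_generator_config,
    load_generator_config,
    write_dataset,
)


def noise_free_forward(**overrides) -> SpectralForwardModel:
    """Forward model with every stochastic term switched off."""
    params = dict(
        ssc_reference_error_brix=0.0,
        firmness_reference_error_n=0.0,
        moisture_noise_sd=0.0,
        pigment_sample_sd=0.0,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        baseline_drift_sd=0.0,
        noise_sd=0.0,
    )
    params.update(overrides)
    return SpectralForwardModel(**params)


class TestDesign:
    def test_default_design_counts(self, default_dataset):
        refs = default_dataset.references
        assert refs.groupby("variety").size().eq(384).all()
        assert default_dataset.spectra.n_wavelengths == 1044
        wl = default_dataset.spectra.wavelengths_nm
        assert wl[0] == 350.0 and wl[-1] == 1150.0
        assert np.allclose(np.diff(wl), np.diff(wl)[0])

    def test_soft_variety_absent_at_room_temperature(self, default_dataset):
        refs = default_dataset.references
        soft_warm = refs[
            (refs["variety"] == "Huangyuanshuai") & (refs["temperature_c"] == 25.0)
        ]
        assert soft_warm.empty

    def test_eleven_variety_temperature_groups(self, default_dataset):
        groups = default_dataset.references[["variety", "temperature_c"]].drop_duplicates()
        assert len(groups) == 11

    def test_invalid_designs_rejected(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(n_wavelengths=1)
        with pytest.raises(ConfigurationError):
            StudyDesign(wavelength_start_nm=900, wavelength_end_nm=400)

    def test_unknown_group_in_trends_is_config_error(self):
        design = StudyDesign(varieties=["Nonesuch"], temperatures=[1])
        with pytest.raises(ConfigurationError):
            generate_references(design, QualityTrendParams.default(), seed=0)


class TestReferences:
    def test_noise_free_group_equals_mean(self):
        design = StudyDesign(
            varieties=["Akesu"], temperatures=[1], samples_per_variety=70,
            excluded_groups=[],
        )
        trends = QualityTrendParams(
            groups={
                ("Akesu", 1.0): GroupTrend(
                    ssc_mean=14.0, ssc_sd=0.0, firmness_mean=9.0, firmness_sd=0.0,
                    ssc_amplitude=0.0, firmness_amplitude=0.0,
                )
            }
        )
        refs = generate_references(design, trends, seed=5)
        assert np.allclose(refs["ssc_brix"], 14.0)
        assert np.allclose(refs["firmness_n"], 9.0)

    def test_group_mean_recovered_at_large_n(self):
        # Monte-Carlo check against the configured group mean (14.874 degBrix)
        design = StudyDesign(
            varieties=["Akesu"], temperatures=[1], samples_per_variety=10_000,
            excluded_groups=[],
        )
        refs = generate_references(design, QualityTrendParams.default(), seed=11)
        ssc = refs["ssc_brix"].to_numpy()
        se = ssc.std(ddof=1) / np.sqrt(ssc.size)
        assert abs(ssc.mean() - 14.874) < 3 * se

    def test_week_profile_peaks_under_refrigeration(self):
        # large noiseless-amplitude design: weekly means peak near week 4 at
        # 1 degC and trough there at 25 degC (SSC)
        design = StudyDesign(
            varieties=["Akesu"], temperatures=[1, 25], samples_per_variety=14_000,
            excluded_groups=[],
        )
        refs = generate_references(design, QualityTrendParams.default(), seed=3)
        for temp, kind in ((1.0, "peak"), (25.0, "trough")):
            weekly = (
                refs[refs["temperature_c"] == temp]
                .groupby("week")["ssc_brix"]
                .mean()
            )
            extremum_week = weekly.idxmax() if kind == "peak" else weekly.idxmin()
            assert 3 <= extremum_week <= 5

    def test_firmness_declines_at_room_temperature(self):
        design = StudyDesign(
            varieties=["Akesu"], temperatures=[25], samples_per_variety=14_000,
            excluded_groups=[],
        )
        refs = generate_references(design, QualityTrendParams.default(), seed=3)
        weekly = refs.groupby("week")["firmness_n"].mean().to_numpy()
        assert np.all(np.diff(weekly) < 0)


class TestSpectra:
    def test_identical_reference_rows_give_identical_spectra(self):
        design = StudyDesign(varieties=["Akesu"], temperatures=[1], n_wavelengths=200)
        import pandas as pd

        refs = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "variety": ["Akesu", "Akesu"],
                "temperature_c": [1.0, 1.0],
                "week": [2, 2],
                "ssc_brix": [14.0, 14.0],
                "firmness_n": [9.0, 9.0],
            }
        )
        spectra = generate_spectra(refs, noise_free_forward(), design, seed=9)
        assert np.array_equal(spectra.values[0], spectra.values[1])

    def test_moisture_drives_720nm_down_faster_when_warm(self):
        design = StudyDesign(
            varieties=["Akesu"], temperatures=[1, 25], samples_per_variety=14_000,
            excluded_groups=[], n_wavelengths=300,
        )
        ds = generate_dataset(design=design, seed=4)
        j720 = int(np.argmin(np.abs(ds.spectra.wavelengths_nm - 720.0)))
        refs = ds.references
        week7 = refs["week"] == 7
        cold = ds.spectra.values[np.flatnonzero(week7 & (refs["temperature_c"] == 1.0)), j720]
        warm = ds.spectra.values[np.flatnonzero(week7 & (refs["temperature_c"] == 25.0)), j720]
        assert warm.mean() < cold.mean()

    def test_720nm_weekly_means_non_increasing_at_room_temperature(self):
        design = StudyDesign(
            varieties=["Akesu"], temperatures=[25], samples_per_variety=7_000,
            excluded_groups=[], n_wavelengths=300,
        )
        ds = generate_dataset(design=design, seed=4)
        j720 = int(np.argmin(np.abs(ds.spectra.wavelengths_nm - 720.0)))
        refs = ds.references
        weekly = np.array(
            [
                ds.spectra.values[np.flatnonzero(refs["week"] == w), j720].mean()
                for w in range(1, 8)
            ]
        )
        assert np.all(np.diff(weekly) <= 0)

    def test_ssc_visible_in_sugar_band_after_scatter_correction(self, default_dataset):
        j910 = int(
            np.argmin(np.abs(default_dataset.spectra.wavelengths_nm - 910.0))
        )
        corrected = snv(default_dataset.spectra)
        r = np.corrcoef(
            default_dataset.references["ssc_brix"], corrected.values[:, j910]
        )[0, 1]
        assert r > 0.5

    def test_band_widths_validated(self):
        fm = SpectralForwardModel()
        fm.pigment_band.width_nm = -1.0
        with pytest.raises(ConfigurationError):
            fm.validate()


class TestDatasetPlumbing:
    def test_seeded_determinism_bit_identical(self):
        design = StudyDesign(samples_per_variety=42, n_wavelengths=120)
        a = generate_dataset(design=design, seed=7)
        b = generate_dataset(design=design, seed=7)
        assert np.array_equal(a.spectra.values, b.spectra.values)
        assert a.references.equals(b.references)

    def test_different_seeds_differ(self):
        design = StudyDesign(samples_per_variety=42, n_wavelengths=120)
        a = generate_dataset(design=design, seed=1)
        b = generate_dataset(design=design, seed=2)
        assert not np.array_equal(a.spectra.values, b.spectra.values)

    def test_csv_round_trip(self, tmp_path):
        design = StudyDesign(samples_per_variety=21, n_wavelengths=50)
        ds = generate_dataset(design=design, seed=3)
        spectra_path, refs_path = write_dataset(ds, tmp_path)
        spectra = read_spectra_csv(spectra_path)
        refs = read_references_csv(refs_path)
        assert np.allclose(spectra.values, ds.spectra.values)
        assert spectra.sample_ids == ds.spectra.sample_ids
        assert len(refs) == len(ds.references)
        # header carries the nm grid at 2 decimals
        assert np.allclose(spectra.wavelengths_nm, ds.spectra.wavelengths_nm, atol=0.005)

    def test_generator_config_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        design = StudyDesign(samples_per_variety=16, n_wavelengths=64)
        trends = QualityTrendParams.default()
        forward = SpectralForwardModel(noise_sd=0.001)
        dump_generator_config(design, trends, forward, path)
        design2, trends2, forward2 = load_generator_config(path)
        assert design2 == design
        assert forward2 == forward
        assert trends2.groups == trends.groups
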