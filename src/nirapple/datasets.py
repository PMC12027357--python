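"""Seeded synthetic apple NIR datasets.

The study the package supports measured diffuse-transmission absorbance of
four apple varieties (Akesu, Huangyuanshuai, Shandong Fuji, Luochuan Fuji)
stored at 1/10/25 °C and sampled weekly for seven weeks, with soluble solids
content (SSC, °Brix) and flesh firmness (N) as reference traits.  The raw
spectra are not publicly deposited, so this module generates datasets with
the same statistical structure:

* per-(variety, temperature) SSC/firmness means and SDs matching the study's
  summary statistics;
* a quadratic storage-week trend peaking between weeks 3 and 5 under
  refrigeration, inverted (SSC) or monotone-declining (firmness) at 25 °C;
* spectra built from Gaussian absorption bands (water ~720/970 nm,
  sugar-correlated C-H bands ~840/910 nm, a skin-pigment band ~650 nm) on a
  smooth baseline, with per-sample multiplicative scatter and white noise;
* a moisture latent variable that declines with storage week, faster at
  higher temperature, driving the 720 nm water band down over time;
* firmness entering the multiplicative scatter slope (firmer, crisper flesh
  scatters more).

All randomness flows from one integer seed through ``numpy.random
.SeedSequence`` children (one stream per generation stage), so a dataset is
bit-reproducible from ``(design, trends, forward, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    SpectraMatrix,
    validate_references,
    write_references_csv,
    write_spectra_csv,
)

VARIETIES = ["Akesu", "Huangyuanshuai", "Shandong Fuji", "Luochuan Fuji"]
TEMPERATURES_C = [1, 10, 25]

#: (variety, temperature) groups absent from the study: Huangyuanshuai's soft
#: flesh rotted early at room temperature, so it has no 25 °C group.
EXCLUDED_GROUPS = [("Huangyuanshuai", 25)]

#: Storage temperatures at or above this are treated as "room temperature"
#: (no respiration suppression): the weekly quality profile inverts there.
ROOM_TEMPERATURE_C = 20.0


class ConfigurationError(ValueError):
    """Raised when a design/trend/forward-model configuration is invalid."""


@dataclass
class StudyDesign:
    """Sampling layout of the storage experiment."""

    varieties: list[str] = field(default_factory=lambda: list(VARIETIES))
    temperatures: list[float] = field(default_factory=lambda: list(TEMPERATURES_C))
    weeks: int = 7
    samples_per_variety: int = 384
    samples_per_batch: int | None = None
    excluded_groups: list[tuple[str, float]] = field(
        default_factory=lambda: [tuple(g) for g in EXCLUDED_GROUPS]
    )
    wavelength_start_nm: float = 350.0
    wavelength_end_nm: float = 1150.0
    n_wavelengths: int = 1044

    def __post_init__(self) -> None:
        if self.n_wavelengths < 2:
            raise ConfigurationError("need at least 2 wavelengths")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ConfigurationError("wavelength range must be increasing")
        if self.weeks < 1:
            raise ConfigurationError("need at least one storage week")
        if not self.varieties or not self.temperatures:
            raise ConfigurationError("need at least one variety and temperature")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(
            self.wavelength_start_nm, self.wavelength_end_nm, self.n_wavelengths
        )

    def groups(self) -> list[tuple[str, float]]:
        """Available (variety, temperature) groups, exclusions removed."""
        excluded = {(v, float(t)) for v, t in self.excluded_groups}
        return [
            (v, float(t))
            for v in self.varieties
            for t in self.temperatures
            if (v, float(t)) not in excluded
        ]

    def cell_counts(self) -> dict[tuple[str, float, int], int]:
        """Sample count per (variety, temperature, week) cell.

        If ``samples_per_batch`` is set, every cell gets exactly that count.
        Otherwise each variety's ``samples_per_variety`` total is divided
        evenly over its available (temperature, week) cells, with the
        remainder assigned to the earliest weeks.
        """
        counts: dict[tuple[str, float, int], int] = {}
        for variety in self.varieties:
            cells = [
                (t, w)
                for w in range(1, self.weeks + 1)
                for (v, t) in self.groups()
                if v == variety
            ]
            # order by week first so remainders land in the earliest weeks
            cells.sort(key=lambda tw: (tw[1], tw[0]))
            if not cells:
                continue
            if self.samples_per_batch is not None:
                per_cell = [self.samples_per_batch] * len(cells)
            else:
                base, rem = divmod(self.samples_per_variety, len(cells))
                per_cell = [base + (1 if i < rem else 0) for i in range(len(cells))]
            for (t, w), n in zip(cells, per_cell):
                counts[(variety, t, w)] = n
        return counts


@dataclass
class GroupTrend:
    """Quality-trait parameters of one (variety, temperature) group.

    ``ssc_mean``/``ssc_sd`` are in °Brix, ``firmness_mean``/``firmness_sd``
    in N.  ``peak_week`` locates the interior quality peak under
    refrigeration (the profile troughs instead at room temperature), and the
    two amplitudes set the size of the weekly swing in trait units.
    """

    ssc_mean: float
    ssc_sd: float
    firmness_mean: float
    firmness_sd: float
    peak_week: float = 4.0
    ssc_amplitude: float = 0.6
    firmness_amplitude: float = 0.8


# Per-group SSC/firmness summary statistics of the storage study
# (mean, SD) by storage temperature and variety.
_STUDY_GROUP_STATS: dict[tuple[str, float], tuple[float, float, float, float]] = {
    # (variety, temp): (ssc_mean, ssc_sd, firmness_mean, firmness_sd)
    ("Akesu", 1.0): (14.874, 0.676, 8.970, 0.660),
    ("Huangyuanshuai", 1.0): (13.499, 0.333, 4.119, 0.396),
    ("Shandong Fuji", 1.0): (13.055, 0.524, 8.434, 0.805),
    ("Luochuan Fuji", 1.0): (12.338, 1.345, 9.781, 0.681),
    ("Akesu", 10.0): (15.078, 0.698, 8.933, 0.550),
    ("Huangyuanshuai", 10.0): (14.100, 0.878, 4.815, 0.426),
    ("Shandong Fuji", 10.0): (13.263, 0.653, 9.178, 0.532),
    ("Luochuan Fuji", 10.0): (13.020, 0.591, 10.731, 0.694),
    ("Akesu", 25.0): (14.188, 1.027, 9.130, 0.886),
    ("Shandong Fuji", 25.0): (13.474, 0.884, 9.676, 0.324),
    ("Luochuan Fuji", 25.0): (13.116, 0.873, 10.493, 0.873),
}


@dataclass
class QualityTrendParams:
    """Per-(variety, temperature) trait distributions and week profiles."""

    groups: dict[tuple[str, float], GroupTrend]

    @classmethod
    def default(cls) -> "QualityTrendParams":
        return cls(
            groups={
                key: GroupTrend(ssc_mean=sm, ssc_sd=ss, firmness_mean=fm, firmness_sd=fs)
                for key, (sm, ss, fm, fs) in _STUDY_GROUP_STATS.items()
            }
        )

    def for_group(self, variety: str, temperature: float) -> GroupTrend:
        key = (variety, float(temperature))
        if key not in self.groups:
            raise ConfigurationError(
                f"no trend parameters configured for group {key}"
            )
        trend = self.groups[key]
        if trend.ssc_sd < 0 or trend.firmness_sd < 0:
            raise ConfigurationError(f"negative SD configured for group {key}")
        return trend


@dataclass
class GaussianBand:
    center_nm: float
    width_nm: float
    amplitude: float

    def profile(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        if self.width_nm <= 0:
            raise ConfigurationError("band width must be positive")
        return np.exp(-(((wavelengths_nm - self.center_nm) / self.width_nm) ** 2))


@dataclass
class SpectralForwardModel:
    """Latent-trait -> absorbance forward model.

    Bands are Gaussian in wavelength.  Sensitivities are relative amplitude
    change per standardized latent unit: SSC drives the sugar-correlated C-H
    bands positively, moisture drives the water bands positively, and
    firmness enters the per-sample multiplicative scatter slope.
    """

    water_bands: list[GaussianBand] = field(
        default_factory=lambda: [
            GaussianBand(720.0, 35.0, 0.45),
            GaussianBand(970.0, 45.0, 0.35),
        ]
    )
    sugar_bands: list[GaussianBand] = field(
        default_factory=lambda: [
            GaussianBand(840.0, 28.0, 0.22),
            GaussianBand(910.0, 30.0, 0.26),
        ]
    )
    pigment_band: GaussianBand = field(
        default_factory=lambda: GaussianBand(650.0, 22.0, 0.30)
    )
    ssc_sensitivity: float = 0.4
    moisture_sensitivity: float = 0.12
    firmness_scatter_gain: float = 0.2
    # cell-wall material also absorbs in the 970 nm region: a small direct
    # band signature so firmness is not carried by scatter alone
    firmness_band_sensitivity: float = 0.12
    pigment_variety_step: float = 0.06
    pigment_week_slope: float = -0.015
    # fruit-to-fruit skin color variability (relative SD of the pigment band
    # amplitude, unrelated to the internal traits)
    pigment_sample_sd: float = 0.05
    # trait-spectrum decoupling: the refractometer/texture-analyzer reference
    # is a noisy, localized measurement of what the whole-fruit spectrum sees,
    # so the spectral latent is the reference value plus this error
    ssc_reference_error_brix: float = 0.15
    firmness_reference_error_n: float = 0.3
    # standardization constants for the latent traits (fixed, not data-driven,
    # so each spectrum depends only on its own reference row)
    ssc_center: float = 13.5
    ssc_scale: float = 1.0
    firmness_center: float = 8.5
    firmness_scale: float = 1.0
    # moisture declines with storage week even when refrigerated, and faster
    # when warm
    moisture_decline_per_week_base: float = 0.0
    moisture_decline_per_week_per_degc: float = 0.002
    moisture_noise_sd: float = 0.03
    # baseline + instrumental terms
    baseline_offset: float = 0.25
    baseline_slope: float = 0.15
    scatter_slope_sd: float = 0.20
    scatter_offset_sd: float = 0.08
    noise_sd: float = 0.005
    # per-sample smooth baseline drift (random quadratic, absorbance units)
    baseline_drift_sd: float = 0.01
    # measurement-session (batch) effect: each weekly batch of a storage
    # group is measured in one session, leaving a shared smooth spectral
    # deviation (instrument state, ambient conditions); absorbance units
    batch_effect_sd: float = 0.0
    # per-session wavelength-calibration drift of the spectrometer (nm SD);
    # applied as a first-order shift of each batch's spectra
    batch_wavelength_shift_nm: float = 0.0
    # detector sensitivity collapses toward the grid edges (UV end and the
    # silicon cutoff near 1100 nm), inflating noise there
    edge_noise_factor: float = 50.0
    edge_width_nm: float = 110.0

    def all_bands(self) -> list[GaussianBand]:
        return [*self.water_bands, *self.sugar_bands, self.pigment_band]

    def validate(self) -> None:
        for band in self.all_bands():
            if band.width_nm <= 0:
                raise ConfigurationError("all band widths must be positive")
        if self.noise_sd < 0 or self.scatter_slope_sd < 0 or self.scatter_offset_sd < 0:
            raise ConfigurationError("noise/scatter SDs must be non-negative")


@dataclass
class SyntheticDataset:
    spectra: SpectraMatrix
    references: pd.DataFrame
    seed: int
    design: StudyDesign


def _week_profile(weeks: int, peak_week: float) -> np.ndarray:
    """Mean-centered quadratic week profile peaking (value max) at peak_week."""
    w = np.arange(1, weeks + 1, dtype=float)
    half_span = max(peak_week - 1.0, weeks - peak_week, 1.0)
    quad = 1.0 - ((w - peak_week) / half_span) ** 2
    return quad - quad.mean()


def _declining_profile(weeks: int) -> np.ndarray:
    """Mean-centered linear decline over weeks (amplitude-1 half-range)."""
    w = np.arange(1, weeks + 1, dtype=float)
    if weeks == 1:
        return np.zeros(1)
    lin = (w.mean() - w) / ((weeks - 1) / 2.0)
    return lin


def generate_references(
    design: StudyDesign, trends: QualityTrendParams, seed: int
) -> pd.DataFrame:
    """Draw the per-sample reference table (SSC, firmness, group labels).

    Each trait is group mean + mean-centered week profile + Gaussian noise
    with the group SD.  Under refrigeration the profile is a quadratic peak
    at ``peak_week``; at room temperature SSC troughs instead and firmness
    declines monotonically.  Values are floored at 10% of the group mean.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    counts = design.cell_counts()
    rows = []
    for variety in design.varieties:
        for temperature in map(float, design.temperatures):
            if (variety, temperature) not in [
                (v, t) for v, t in design.groups() if v == variety
            ]:
                continue
            trend = trends.for_group(variety, temperature)
            peak = _week_profile(design.weeks, trend.peak_week)
            warm = temperature >= ROOM_TEMPERATURE_C
            ssc_profile = -peak if warm else peak
            firm_profile = _declining_profile(design.weeks) if warm else peak
            for week in range(1, design.weeks + 1):
                n = counts.get((variety, temperature, week), 0)
                if n == 0:
                    continue
                ssc = (
                    trend.ssc_mean
                    + trend.ssc_amplitude * ssc_profile[week - 1]
                    + rng.normal(0.0, trend.ssc_sd, size=n)
                )
                firm = (
                    trend.firmness_mean
                    + trend.firmness_amplitude * firm_profile[week - 1]
                    + rng.normal(0.0, trend.firmness_sd, size=n)
                )
                ssc = np.maximum(ssc, 0.1 * trend.ssc_mean)
                firm = np.maximum(firm, 0.1 * trend.firmness_mean)
                for i in range(n):
                    rows.append(
                        {
                            "variety": variety,
                            "temperature_c": temperature,
                            "week": week,
                            "ssc_brix": ssc[i],
                            "firmness_n": firm[i],
                        }
                    )
    references = pd.DataFrame(rows)
    if references.empty:
        raise ConfigurationError("design produced no samples")
    references.insert(
        0,
        "sample_id",
        [
            f"{r.variety.replace(' ', '')}_T{int(r.temperature_c):02d}"
            f"_W{int(r.week)}_{i:04d}"
            for i, r in enumerate(references.itertuples())
        ],
    )
    return validate_references(references)


def generate_spectra(
    references: pd.DataFrame,
    forward: SpectralForwardModel,
    design: StudyDesign,
    seed: int,
) -> SpectraMatrix:
    """Render one absorbance spectrum per reference row.

    Spectrum = baseline + Gaussian bands scaled by standardized latent
    traits, then per-sample multiplicative scatter (slope carries the
    firmness signal) and additive white noise.
    """
    validate_references(references)
    forward.validate()
    if references.empty:
        raise ConfigurationError("reference table is empty")
    wavelengths = design.wavelengths_nm
    if wavelengths.size < 2:
        raise ConfigurationError("wavelength grid needs at least 2 points")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    n = len(references)
    ssc_latent = references["ssc_brix"].to_numpy() + rng.normal(
        0.0, forward.ssc_reference_error_brix, size=n
    )
    firm_latent = references["firmness_n"].to_numpy() + rng.normal(
        0.0, forward.firmness_reference_error_n, size=n
    )
    ssc_z = (ssc_latent - forward.ssc_center) / forward.ssc_scale
    firm_z = (firm_latent - forward.firmness_center) / forward.firmness_scale
    week = references["week"].to_numpy(dtype=float)
    temp = references["temperature_c"].to_numpy(dtype=float)
    variety_idx = np.array(
        [design.varieties.index(v) if v in design.varieties else 0
         for v in references["variety"]],
        dtype=float,
    )

    # moisture latent: 1 at week 0, declining faster when warm
    moisture = (
        1.0
        - (
            forward.moisture_decline_per_week_base
            + forward.moisture_decline_per_week_per_degc * temp
        )
        * week
        + rng.normal(0.0, forward.moisture_noise_sd, size=n)
    )
    moisture_z = (moisture - 1.0) / 0.1  # fixed scale: 0.1 moisture units

    baseline = forward.baseline_offset + forward.baseline_slope * (
        (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0])
    )

    clean = np.tile(baseline, (n, 1))
    for i, band in enumerate(forward.water_bands):
        amp = band.amplitude * (1.0 + forward.moisture_sensitivity * moisture_z)
        if i == 1:  # the ~970 nm band also sees cell-wall material
            amp = amp * (1.0 + forward.firmness_band_sensitivity * firm_z)
        clean += np.outer(np.maximum(amp, 0.0), band.profile(wavelengths))
    for band in forward.sugar_bands:
        amp = band.amplitude * (1.0 + forward.ssc_sensitivity * ssc_z)
        clean += np.outer(np.maximum(amp, 0.0), band.profile(wavelengths))
    pig = forward.pigment_band
    pig_amp = pig.amplitude * (
        1.0
        + forward.pigment_variety_step * variety_idx
        + forward.pigment_week_slope * (week - 1.0)
        + rng.normal(0.0, forward.pigment_sample_sd, size=n)
    )
    clean += np.outer(np.maximum(pig_amp, 0.0), pig.profile(wavelengths))

    # log-normal multiplicative scatter keeps the slope positive; firmer
    # (crisper) flesh scatters more, so firmness enters the log-slope
    slope = np.exp(
        forward.firmness_scatter_gain * firm_z
        + rng.normal(0.0, forward.scatter_slope_sd, size=n)
    )
    offset = rng.normal(0.0, forward.scatter_offset_sd, size=n)
    values = clean * slope[:, None] + offset[:, None]
    if forward.batch_effect_sd > 0 or forward.batch_wavelength_shift_nm > 0:
        u = (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0])
        basis = np.vstack(
            [np.ones_like(u), u, u**2]
            + [b.profile(wavelengths) for b in forward.all_bands()]
        )
        gradient = np.gradient(values, wavelengths, axis=1)
        batch_keys = references[["variety", "temperature_c", "week"]].apply(tuple, axis=1)
        for key in sorted(batch_keys.unique()):
            coef = rng.normal(0.0, forward.batch_effect_sd, size=basis.shape[0])
            shift = rng.normal(0.0, forward.batch_wavelength_shift_nm)
            rows = np.flatnonzero((batch_keys == key).to_numpy())
            values[rows] += coef @ basis + shift * gradient[rows]
    if forward.baseline_drift_sd > 0:
        u = (wavelengths - wavelengths[0]) / (wavelengths[-1] - wavelengths[0])
        drift_coef = rng.normal(0.0, forward.baseline_drift_sd, size=(n, 3))
        values = values + drift_coef @ np.vstack([np.ones_like(u), u, u**2])
    if forward.noise_sd > 0:
        edge = np.exp(-(((wavelengths - wavelengths[0]) / forward.edge_width_nm) ** 2))
        edge += np.exp(-(((wavelengths - wavelengths[-1]) / forward.edge_width_nm) ** 2))
        sd_profile = forward.noise_sd * (1.0 + forward.edge_noise_factor * edge)
        values = values + rng.normal(0.0, 1.0, size=values.shape) * sd_profile
    return SpectraMatrix(values, wavelengths, references["sample_id"].tolist())


def generate_dataset(
    design: StudyDesign | None = None,
    trends: QualityTrendParams | None = None,
    forward: SpectralForwardModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a full (spectra, references) dataset; bit-reproducible per seed."""
    design = design or StudyDesign()
    trends = trends or QualityTrendParams.default()
    forward = forward or SpectralForwardModel()
    references = generate_references(design, trends, seed)
    spectra = generate_spectra(references, forward, design, seed)
    return SyntheticDataset(spectra=spectra, references=references, seed=seed, design=design)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spectra_path = out / "spectra.csv"
    references_path = out / "references.csv"
    write_spectra_csv(dataset.spectra, spectra_path)
    write_references_csv(dataset.references, references_path)
    return spectra_path, references_path


# -- configuration I/O -------------------------------------------------------

def design_from_dict(doc: dict) -> StudyDesign:
    doc = dict(doc)
    if "excluded_groups" in doc:
        doc["excluded_groups"] = [tuple(g) for g in doc["excluded_groups"]]
    return StudyDesign(**doc)


def trends_from_dict(doc: dict) -> QualityTrendParams:
    groups = {}
    for entry in doc["groups"]:
        entry = dict(entry)
        key = (entry.pop("variety"), float(entry.pop("temperature_c")))
        groups[key] = GroupTrend(**entry)
    return QualityTrendParams(groups=groups)


def forward_from_dict(doc: dict) -> SpectralForwardModel:
    doc = dict(doc)
    for key in ("water_bands", "sugar_bands"):
        if key in doc:
            doc[key] = [GaussianBand(**b) for b in doc[key]]
    if "pigment_band" in doc:
        doc["pigment_band"] = GaussianBand(**doc["pigment_band"])
    return SpectralForwardModel(**doc)


def load_generator_config(path: str | Path) -> tuple[
    StudyDesign, QualityTrendParams, SpectralForwardModel
]:
    """Read a YAML/JSON document mirroring the three generator dataclasses."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    design = design_from_dict(doc.get("design", {}))
    if "trends" in doc:
        trends = trends_from_dict(doc["trends"])
    else:
        trends = QualityTrendParams.default()
    forward = forward_from_dict(doc.get("forward", {}))
    return design, trends, forward


def dump_generator_config(
    design: StudyDesign,
    trends: QualityTrendParams,
    forward: SpectralForwardModel,
    path: str | Path,
) -> None:
    doc = {
        "design": asdict(design),
        "trends": {
            "groups": [
                {"variety": v, "temperature_c": t, **asdict(g)}
                for (v, t), g in trends.groups.items()
            ]
        },
        "forward": asdict(forward),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
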