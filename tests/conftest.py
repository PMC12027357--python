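import numpy as np
import pytest

from nirapple import SpectraMatrix, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full default synthetic study (4 varieties x 3 temperatures, seed 2)."""
    return generate_dataset(seed=2)


@pytest.fixture(scope="session")
def akesu_ssc(default_dataset):
    """One variety's 384 spectra with the paired SSC vector."""
    refs = default_dataset.references
    mask = (refs["variety"] == "Akesu").to_numpy()
    spectra = default_dataset.spectra.take(np.flatnonzero(mask))
    y = refs.loc[mask, "ssc_brix"].to_numpy(dtype=float)
    return spectra, y


def random_spectra(n, p, seed=0, smooth=False):
    """Random positive absorbance matrix on an arbitrary nm grid."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.2, 1.0, size=(n, p))
    if smooth:
        kernel = np.ones(5) / 5
        values = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, values
        )
    wavelengths = np.linspace(400.0, 1000.0, p)
    return SpectraMatrix(values, wavelengths)
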