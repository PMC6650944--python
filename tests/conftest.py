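import numpy as np
import pandas as pd
import pytest

from lncspec import SimConfig, Spectrum, SpectrumSet, make_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared by read-only tests."""
    return make_dataset(SimConfig(seed=11))


@pytest.fixture()
def toy_csv(tmp_path):
    """3-sample spectra CSV on a 400-900 nm 1 nm grid, plus an LNC CSV."""
    wl = np.arange(400, 901)
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"wavelength": wl})
    for sid in ("a", "b", "c"):
        df[sid] = 0.2 + 0.1 * np.sin(wl / 90.0) + rng.normal(0, 0.002, wl.size)
    spath = tmp_path / "spectra.csv"
    df.to_csv(spath, index=False)
    lpath = tmp_path / "lnc.csv"
    pd.DataFrame({"sample_id": ["a", "b", "c"], "lnc": [1.2, 1.9, 2.5]}).to_csv(
        lpath, index=False)
    return spath, lpath


def make_flat_spectrum(value=0.4, lo=350, hi=2500):
    wl = np.arange(lo, hi + 1, dtype=float)
    return Spectrum(wl, np.full(wl.size, float(value)), "flat")


@pytest.fixture()
def flat_spectrum():
    return make_flat_spectrum()
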