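import numpy as np
import pandas as pd
import pytest

import sproutspec as sp


def make_spectra(matrix, wavelengths=None, **meta_overrides):
    """Small helper building a SpectraSet around a plain matrix."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = matrix.shape
    wl = np.arange(p, dtype=float) * 2.0 + 1300.0 if wavelengths is None else wavelengths
    meta = {
        "sample_id": [f"s{i}" for i in range(n)],
        "germination_h": [0] * n,
        "replicate": [1] * n,
        "scan": list(range(1, n + 1)),
        "mode": ["transmission"] * n,
    }
    meta.update(meta_overrides)
    return sp.SpectraSet(np.asarray(wl, dtype=float), matrix, pd.DataFrame(meta))


@pytest.fixture(scope="session")
def extract_fixture():
    """Default synthetic extract dataset, seed 1 (315 rows, 401 wl)."""
    return sp.simulate_extract_spectra(sp.SpectraSimConfig(seed=1))


@pytest.fixture(scope="session")
def extract_preprocessed(extract_fixture):
    spectra, truth = extract_fixture
    cfg = sp.PreprocessConfig(window=sp.WavelengthWindow(1300.0, 1600.0))
    return sp.preprocess_pipeline(spectra, cfg), truth


@pytest.fixture(scope="session")
def standard_fixture():
    """Default synthetic ascorbic standard series, seed 1 (54 rows)."""
    return sp.simulate_standard_curve(sp.SpectraSimConfig(seed=1))


@pytest.fixture(scope="session")
def standard_preprocessed(standard_fixture):
    cfg = sp.PreprocessConfig(window=sp.WavelengthWindow(1300.0, 1600.0))
    return sp.preprocess_pipeline(standard_fixture, cfg)
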