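import dataclasses

import numpy as np
import pytest

import sersmix as sm


@pytest.fixture(scope="session")
def default_dataset() -> sm.LabeledSpectrumSet:
    """The default 78-spectrum synthetic dataset (seed 0)."""
    return sm.generate_dataset()


@pytest.fixture(scope="session")
def processed(default_dataset) -> sm.LabeledSpectrumSet:
    return sm.preprocess_set(default_dataset)


@pytest.fixture(scope="session")
def feature_matrix(processed) -> sm.FeatureMatrix:
    return sm.select_peak_windows(processed)


@pytest.fixture(scope="session")
def default_split(feature_matrix) -> sm.SplitIndices:
    return sm.kennard_stone_split(feature_matrix, 50)


@pytest.fixture(scope="session")
def noiseless_config() -> sm.GeneratorConfig:
    return dataclasses.replace(sm.GeneratorConfig(), noise_sd=0.0,
                               gain_jitter_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def linear_spectrum(intensities, start=0.0, step=1.0) -> sm.Spectrum:
    """Helper: spectrum on a uniform synthetic grid."""
    y = np.asarray(intensities, dtype=float)
    x = start + step * np.arange(y.size)
    return sm.Spectrum(x, y)
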