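"""Synthetic SERS spectrum generator: peak placement, concentration
response, mixture additivity and dataset structure."""

import dataclasses

import numpy as np
import pytest

import sersmix as sm
from sersmix.errors import ConfigurationError
from sersmix.simulate import (analyte_signal, baseline_signal,
                              generate_dataset, generate_mixture_spectrum,
                              generate_pure_spectrum, solvent_signal)

CHL_PEAKS = (609, 675, 1092, 1166, 1567)
PYR_PEAKS = (558, 608, 990, 1294, 1600)


def chemical_part(spectrum, config):
    """Baseline-subtracted signal (analyte + solvent bands only)."""
    return spectrum.intensities - baseline_signal(config)


@pytest.mark.parametrize("model,peaks", [
    (sm.CHLORPYRIFOS, CHL_PEAKS),
    (sm.PYRIMETHANIL, PYR_PEAKS),
])
def test_pure_spectrum_has_local_maxima_at_characteristic_bands(
        model, peaks, noiseless_config):
    spec = generate_pure_spectrum(model, 1e-3, noiseless_config)
    signal = chemical_part(spec, noiseless_config)
    grid = spec.wavenumbers
    for center in peaks:
        idx = np.argmin(np.abs(grid - center))
        window = slice(max(idx - 3, 0), idx + 4)
        top = np.argmax(signal[window]) + window.start
        assert abs(grid[top] - center) <= noiseless_config.grid_step
        assert signal[top] > 0  # band rises above the baseline


def test_zero_amplitude_leaves_baseline_plus_solvent(noiseless_config):
    # response law max(0, 8 + log10 c) vanishes exactly at c = 1e-8
    model = dataclasses.replace(sm.CHLORPYRIFOS, response_slope=1.0,
                                response_intercept=8.0)
    spec = generate_pure_spectrum(model, 1e-8, noiseless_config)
    expected = baseline_signal(noiseless_config) + solvent_signal(noiseless_config)
    np.testing.assert_allclose(spec.intensities, expected, rtol=0, atol=0)


def test_log_linear_response_height_ratio(noiseless_config):
    # slope 1, intercept 8: amplitude 5 at 1e-3 M and 3 at 1e-5 M
    model = sm.AnalyteModel("probe", (sm.PeakSpec(800.0, 6.0, 1.0),),
                            response_slope=1.0, response_intercept=8.0)
    grid = noiseless_config.wavenumbers
    idx = np.argmin(np.abs(grid - 800.0))
    heights = {}
    for conc in (1e-3, 1e-5):
        spec = generate_pure_spectrum(model, conc, noiseless_config)
        clean = spec.intensities - baseline_signal(noiseless_config) \
            - solvent_signal(noiseless_config)
        heights[conc] = clean[idx]
    assert heights[1e-3] == pytest.approx(5.0, rel=1e-12)
    assert heights[1e-5] == pytest.approx(3.0, rel=1e-12)
    assert heights[1e-3] / heights[1e-5] == pytest.approx(5.0 / 3.0, rel=1e-12)


def test_pyrimethanil_band_grows_with_its_volume_fraction(noiseless_config):
    grid = noiseless_config.wavenumbers
    idx = np.argmin(np.abs(grid - 558.0))
    heights = []
    for ratio in [(1, 4), (1, 1), (4, 1)]:  # pyrimethanil:chlorpyrifos
        spec = generate_mixture_spectrum(sm.PYRIMETHANIL, sm.CHLORPYRIFOS,
                                         1e-4, 1e-4, ratio, noiseless_config)
        heights.append(chemical_part(spec, noiseless_config)[idx])
    assert heights[0] < heights[1] < heights[2]


def test_mixture_is_sum_of_component_signals_with_single_background(
        noiseless_config):
    ca, cb, ratio = 1e-3, 1e-4, (2, 1)
    fa, fb = 2 / 3, 1 / 3
    mix = generate_mixture_spectrum(sm.PYRIMETHANIL, sm.CHLORPYRIFOS,
                                    ca, cb, ratio, noiseless_config)
    expected = (analyte_signal(sm.PYRIMETHANIL, ca * fa, noiseless_config)
                + analyte_signal(sm.CHLORPYRIFOS, cb * fb, noiseless_config)
                + solvent_signal(noiseless_config)
                + baseline_signal(noiseless_config))
    np.testing.assert_allclose(mix.intensities, expected, rtol=1e-10)
    # equivalently: sum of the two pure spectra minus the duplicated
    # solvent + baseline contribution
    pure_sum = (
        generate_pure_spectrum(sm.PYRIMETHANIL, ca * fa, noiseless_config).intensities
        + generate_pure_spectrum(sm.CHLORPYRIFOS, cb * fb, noiseless_config).intensities
        - solvent_signal(noiseless_config) - baseline_signal(noiseless_config))
    np.testing.assert_allclose(mix.intensities, pure_sum, rtol=1e-10)


def test_vanishing_second_component_degenerates_to_pure_spectrum(
        noiseless_config):
    mix = generate_mixture_spectrum(sm.PYRIMETHANIL, sm.CHLORPYRIFOS,
                                    2e-3, 1e-300, (1, 1), noiseless_config)
    pure = generate_pure_spectrum(sm.PYRIMETHANIL, 1e-3, noiseless_config)
    np.testing.assert_allclose(mix.intensities, pure.intensities, rtol=1e-12)


def test_band_height_monotone_in_concentration(noiseless_config):
    grid = noiseless_config.wavenumbers
    for model, center in [(sm.CHLORPYRIFOS, 675.0), (sm.PYRIMETHANIL, 558.0)]:
        idx = np.argmin(np.abs(grid - center))
        heights = [
            chemical_part(generate_pure_spectrum(model, c, noiseless_config),
                          noiseless_config)[idx]
            for c in sorted(noiseless_config.concentration_levels)
        ]
        assert np.all(np.diff(heights) >= 0)


def test_default_dataset_counts(default_dataset):
    assert len(default_dataset) == 78
    labels = default_dataset.labels
    assert np.sum(labels == 1) == 38   # mixtures
    assert np.sum(labels == 2) == 20   # pyrimethanil
    assert np.sum(labels == 3) == 20   # chlorpyrifos


def test_same_seed_gives_identical_dataset(default_dataset):
    again = generate_dataset()
    np.testing.assert_array_equal(default_dataset.intensities,
                                  again.intensities)
    other = generate_dataset(dataclasses.replace(sm.GeneratorConfig(), seed=99))
    assert not np.array_equal(default_dataset.intensities, other.intensities)


def test_custom_composition_counts():
    config = dataclasses.replace(sm.GeneratorConfig(),
                                 class_composition={1: 10, 2: 10, 3: 10})
    ds = generate_dataset(config, size=30)
    assert len(ds) == 30
    assert all(np.sum(ds.labels == c) == 10 for c in (1, 2, 3))


def test_class_mean_spectra_distinct_at_exclusive_bands():
    """Low-noise class separability at 558 (pyrimethanil) vs 675
    (chlorpyrifos) underwrites the classification targets."""
    config = dataclasses.replace(sm.GeneratorConfig(), noise_sd=0.01,
                                 gain_jitter_sd=0.0)
    ds = generate_dataset(config)
    grid = ds.wavenumbers
    i558 = np.argmin(np.abs(grid - 558.0))
    i675 = np.argmin(np.abs(grid - 675.0))
    means = {c: ds.intensities[ds.labels == c].mean(axis=0) for c in (1, 2, 3)}
    base = baseline_signal(config)
    # pyrimethanil band present for classes 1 and 2, absent for 3
    assert means[2][i558] - base[i558] > 5 * (means[3][i558] - base[i558])
    assert means[1][i558] > base[i558] + 0.1
    # chlorpyrifos band present for classes 1 and 3, absent for 2
    assert means[3][i675] - base[i675] > 5 * (means[2][i675] - base[i675])
    assert means[1][i675] > base[i675] + 0.1


def test_error_contracts(noiseless_config):
    with pytest.raises(ValueError):
        generate_pure_spectrum(sm.CHLORPYRIFOS, -1e-3, noiseless_config)
    with pytest.raises(ValueError):
        generate_pure_spectrum(sm.CHLORPYRIFOS, 1.0, noiseless_config)  # range
    with pytest.raises(ConfigurationError):
        generate_dataset(sm.GeneratorConfig(), size=77)
    bad = sm.AnalyteModel("bad", (sm.PeakSpec(5000.0, 6.0, 1.0),))
    with pytest.raises(ConfigurationError, match="5000"):
        generate_pure_spectrum(bad, 1e-3, noiseless_config)
    with pytest.raises(ValueError):
        generate_mixture_spectrum(sm.PYRIMETHANIL, sm.CHLORPYRIFOS,
                                  1e-3, 1e-3, (0, 1), noiseless_config)
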