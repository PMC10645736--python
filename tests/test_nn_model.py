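"""MC-CNN-GRU model contracts: channel assembly, determinism, schedule,
early stopping, prediction and embedding."""

import dataclasses

import numpy as np
import pytest

import sersmix as sm
from sersmix.errors import ConfigurationError
from sersmix.nn.model import (MCCNNGRUConfig, build_channels, build_model,
                              embed, learning_rate_at, predict, train)

FAST = dict(max_epochs=5)


@pytest.fixture(scope="module")
def small_channels(noiseless_config):
    """A small labeled dataset with channels, for fast training runs."""
    config = dataclasses.replace(noiseless_config, noise_sd=0.05,
                                 class_composition={1: 8, 2: 8, 3: 8}, seed=3)
    ds = sm.generate_dataset(config)
    return ds, build_channels(ds)


# conftest fixtures are function-scoped; redefine at module scope for reuse
@pytest.fixture(scope="module")
def noiseless_config():
    return dataclasses.replace(sm.GeneratorConfig(), noise_sd=0.0,
                               gain_jitter_sd=0.0)


class TestConfig:
    def test_invalid_fields_are_listed(self):
        with pytest.raises(ConfigurationError, match="conv_kernel"):
            MCCNNGRUConfig(conv_kernel=4)
        with pytest.raises(ConfigurationError, match="decay_factor"):
            MCCNNGRUConfig(decay_factor=1.5)

    def test_learning_rate_schedule_is_exact_step(self):
        cfg = MCCNNGRUConfig()
        assert learning_rate_at(1, cfg) == 1e-3
        assert learning_rate_at(cfg.decay_epoch, cfg) == 1e-3
        assert learning_rate_at(cfg.decay_epoch + 1, cfg) == pytest.approx(1e-4)


class TestBuild:
    def test_same_seed_same_initial_parameters(self):
        a = build_model(MCCNNGRUConfig(seed=7), 200)
        b = build_model(MCCNNGRUConfig(seed=7), 200)
        assert a.parameter_checksum() == b.parameter_checksum()
        c = build_model(MCCNNGRUConfig(seed=8), 200)
        assert a.parameter_checksum() != c.parameter_checksum()

    def test_parameter_count_independent_of_input_length(self):
        cfg = MCCNNGRUConfig()
        assert build_model(cfg, 200).parameter_count() == \
            build_model(cfg, 751).parameter_count()

    def test_input_shape_validated(self):
        model = build_model(MCCNNGRUConfig(), 100)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 3, 99)))
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 2, 100)))


class TestChannels:
    def test_shapes(self, small_channels):
        ds, channels = small_channels
        assert channels.shape == (len(ds), 3, ds.wavenumbers.size)

    def test_constant_spectra_give_identical_channels(self):
        grid = 200.0 + 2.0 * np.arange(400)
        const = sm.LabeledSpectrumSet(
            [sm.Spectrum(grid, np.full(400, 5.0), label=1)])
        cfg = sm.PreprocessConfig(normalize_mode="none")
        channels = build_channels(const, cfg)
        np.testing.assert_allclose(channels[0, 0], channels[0, 1], atol=1e-9)
        np.testing.assert_allclose(channels[0, 0], channels[0, 2], atol=1e-9)

    def test_smooth_input_sg_channel_close_to_raw_off_band(self, noiseless_config):
        ds = sm.generate_dataset(noiseless_config)
        channels = build_channels(ds)
        raw, smoothed = channels[0, 0], channels[0, 1]
        grid = ds.wavenumbers
        centers = [p.center for p in sm.CHLORPYRIFOS.peaks] + \
                  [p.center for p in noiseless_config.solvent_peaks]
        off_band = np.all(
            np.abs(grid[:, None] - np.array(centers)) > 25.0, axis=1)
        assert np.abs(raw[off_band] - smoothed[off_band]).max() < 5e-3

    def test_grid_mismatch_rejected(self):
        a = sm.Spectrum(np.arange(10.0), np.ones(10))
        b = sm.Spectrum(1.0 + np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            sm.LabeledSpectrumSet([a, b])


class TestTraining:
    def test_history_contract_and_determinism(self, small_channels):
        ds, channels = small_channels
        cfg = MCCNNGRUConfig(seed=11, **FAST)
        model = build_model(cfg, channels.shape[2])
        hist = train(model, channels, ds.labels, None, cfg)
        assert hist.stop_epoch <= cfg.max_epochs
        assert len(hist.loss) == hist.stop_epoch == len(hist.accuracy)
        assert all(np.isfinite(hist.loss))
        model2 = build_model(cfg, channels.shape[2])
        hist2 = train(model2, channels, ds.labels, None, cfg)
        assert hist.loss == hist2.loss
        assert hist.accuracy == hist2.accuracy

    def test_tiny_early_stop_threshold_runs_all_epochs(self, small_channels):
        ds, channels = small_channels
        cfg = MCCNNGRUConfig(seed=11, max_epochs=3, early_stop_loss=1e-12)
        model = build_model(cfg, channels.shape[2])
        hist = train(model, channels, ds.labels, None, cfg)
        assert hist.stop_epoch == 3
        assert hist.stop_reason == "max_epochs"

    def test_trains_only_on_training_split(self, small_channels):
        ds, channels = small_channels
        split = sm.SplitIndices(np.arange(12), np.arange(12, 24))
        cfg = MCCNNGRUConfig(seed=11, **FAST)
        model = build_model(cfg, channels.shape[2])
        train(model, channels, ds.labels, split, cfg)
        bad = sm.SplitIndices(np.array([0, 100]), np.array([1]))
        model2 = build_model(cfg, channels.shape[2])
        with pytest.raises(ValueError):
            train(model2, channels, ds.labels, bad, cfg)


@pytest.fixture(scope="module")
def trained(small_channels):
    ds, channels = small_channels
    cfg = MCCNNGRUConfig(seed=21, max_epochs=60)
    model = build_model(cfg, channels.shape[2])
    history = train(model, channels, ds.labels, None, cfg)
    return ds, channels, model, history


class TestPredictEmbed:
    def test_probabilities_form_simplex(self, trained):
        _, channels, model, _ = trained
        codes, proba = predict(model, channels)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(
            codes, np.array([model.class_labels[i] for i in proba.argmax(1)]))

    def test_inference_deterministic(self, trained):
        _, channels, model, _ = trained
        a = model.predict_proba(channels)
        b = model.predict_proba(channels)
        np.testing.assert_array_equal(a, b)

    def test_learns_the_small_dataset(self, trained):
        ds, channels, model, history = trained
        accuracy = (model.predict(channels) == ds.labels).mean()
        assert accuracy >= 0.9
        assert history.loss[-1] < history.loss[0]

    def test_embedding_contract(self, trained):
        ds, channels, model, _ = trained
        result = embed(model, channels, ds.labels, perplexity=5.0)
        assert result.tsne_coords.shape == (len(ds), 2)
        assert result.penultimate_features.shape[0] == len(ds)

    def test_duplicated_samples_embed_nearby(self, trained):
        ds, channels, model, _ = trained
        dup = np.concatenate([channels, channels[:1]])
        labels = np.append(ds.labels, ds.labels[0])
        result = embed(model, dup, labels, perplexity=5.0)
        d = np.linalg.norm(result.tsne_coords[0] - result.tsne_coords[-1])
        spread = np.linalg.norm(
            result.tsne_coords - result.tsne_coords.mean(0), axis=1).mean()
        assert d < 0.1 * spread

    def test_perplexity_must_be_below_sample_count(self, trained):
        ds, channels, model, _ = trained
        with pytest.raises(ValueError):
            embed(model, channels[:5], ds.labels[:5], perplexity=10.0)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        ds, channels, model, _ = trained
        path = tmp_path / "model.npz"
        model.save(path)
        from sersmix.nn.model import MCCNNGRU
        back = MCCNNGRU.load(path)
        assert back.config == model.config
        np.testing.assert_array_equal(back.predict_proba(channels),
                                      model.predict_proba(channels))
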