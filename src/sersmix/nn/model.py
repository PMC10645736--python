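"""The multi-channel CNN-GRU spectral classifier.

Three preprocessed views of each spectrum (baseline-corrected "raw",
Savitzky-Golay-smoothed, FFT-low-pass-filtered) feed three parallel 1-D
convolution stacks (8/16/32 filters; the first two convolutions followed by
batch normalization and Swish, the third by Swish).  The channel feature
maps are concatenated along the feature axis at matched spectral positions,
giving a sequence that two GRU layers (16 then 32 hidden units) read; the
hidden sequence is globally average-pooled and a fully connected layer
produces softmax class probabilities.  Spectral resolution is reduced by
average pooling after the first convolution block (``conv_pool``) and again
after channel fusion (``seq_pool``).

Convolution features are translation-equivariant, so after global pooling
the absolute band positions -- the class-discriminative information in
these spectra -- survive only through the GRU's sequential dynamics.  Two
numerical choices make that pathway trainable: the conv feature maps are
segment-averaged before the recurrence (shorter sequences, stronger
per-step evidence) and the GRU update-gate biases are initialized positive
(``gru_update_bias``), starting the recurrence in a long-memory,
integrator-like regime in which band positions are linearly encoded in the
time-pooled hidden state.

Training uses Adam on the cross-entropy loss with the learning rate stepped
from 1e-3 to 1e-4 after 50 epochs, and stops early once the epoch training
loss falls below 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.manifold import TSNE

from ..errors import ConfigurationError, TrainingError
from ..features import SplitIndices
from ..preprocess import (PreprocessConfig, baseline_correct, fft_lowpass,
                          normalize, sg_smooth)
from ..simulate import LabeledSpectrumSet
from .layers import (AvgPool1d, BatchNorm1d, Conv1d, Dense, GRU, Swish,
                     softmax, softmax_cross_entropy)

__all__ = [
    "MCCNNGRUConfig",
    "TrainingHistory",
    "EmbeddingResult",
    "MCCNNGRU",
    "build_channels",
    "build_model",
    "train",
    "predict",
    "embed",
    "learning_rate_at",
]


@dataclass(frozen=True)
class MCCNNGRUConfig:
    """Architecture and training hyperparameters (defaults documented)."""

    conv_filters: tuple[int, int, int] = (8, 16, 32)
    conv_kernel: int = 3
    gru_units: tuple[int, int] = (16, 32)
    n_channels: int = 3
    n_classes: int = 3
    conv_pool: int = 4
    seq_pool: int = 4
    gru_update_bias: float = 2.0
    learning_rate: float = 1e-3
    decay_epoch: int = 50
    decay_factor: float = 0.1
    early_stop_loss: float = 0.01
    max_epochs: int = 300
    batch_size: int = 8
    tsne_perplexity: float = 15.0
    seed: int = 0

    def __post_init__(self):
        bad = []
        if len(self.conv_filters) != 3 or any(f < 1 for f in self.conv_filters):
            bad.append("conv_filters")
        if self.conv_kernel < 1 or self.conv_kernel % 2 == 0:
            bad.append("conv_kernel")
        if len(self.gru_units) != 2 or any(u < 1 for u in self.gru_units):
            bad.append("gru_units")
        if self.n_classes < 2:
            bad.append("n_classes")
        if self.learning_rate <= 0:
            bad.append("learning_rate")
        if not (0 < self.decay_factor < 1):
            bad.append("decay_factor")
        if self.early_stop_loss <= 0:
            bad.append("early_stop_loss")
        if self.max_epochs < 1 or self.batch_size < 1:
            bad.append("max_epochs/batch_size")
        if self.seq_pool < 1 or self.conv_pool < 1:
            bad.append("seq_pool/conv_pool")
        if bad:
            raise ConfigurationError(f"invalid MCCNNGRUConfig fields: {', '.join(bad)}")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = "max_epochs"


@dataclass
class EmbeddingResult:
    penultimate_features: np.ndarray
    tsne_coords: np.ndarray
    labels: np.ndarray


def learning_rate_at(epoch: int, config: MCCNNGRUConfig) -> float:
    """Step schedule: lr0 through decay_epoch, lr0 * decay_factor after."""
    if epoch <= config.decay_epoch:
        return config.learning_rate
    return config.learning_rate * config.decay_factor


class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, layers, lr: float):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for li, layer in enumerate(layers):
            for name, g in layer.grads.items():
                key = (li, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(g)
                    self.v[key] = np.zeros_like(g)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                mhat = self.m[key] / b1t
                vhat = self.v[key] / b2t
                layer.params[name] -= lr * mhat / (np.sqrt(vhat) + self.eps)


class MCCNNGRU:
    """Multi-channel 1-D CNN + GRU classifier (see module docstring).

    Input is a float array of shape (n_samples, n_channels, n_points);
    class labels are the study codes, index ``i`` of the softmax mapping to
    ``class_labels[i]`` (default (1, 2, 3)).
    """

    class_labels = (1, 2, 3)

    def __init__(self, config: MCCNNGRUConfig, input_length: int):
        if input_length < config.conv_kernel:
            raise ConfigurationError(
                f"input_length {input_length} shorter than conv_kernel "
                f"{config.conv_kernel}"
            )
        self.config = config
        self.input_length = input_length
        rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.conv_filters
        k = config.conv_kernel
        self.channel_stacks = []
        for _ in range(config.n_channels):
            stack = [
                Conv1d(1, f1, k, rng), BatchNorm1d(f1), Swish(),
                AvgPool1d(config.conv_pool),
                Conv1d(f1, f2, k, rng), BatchNorm1d(f2), Swish(),
                Conv1d(f2, f3, k, rng), Swish(),
            ]
            self.channel_stacks.append(stack)
        g1, g2 = config.gru_units
        self.gru1 = GRU(config.n_channels * f3, g1, rng)
        self.gru2 = GRU(g1, g2, rng)
        # long-memory initialization: bias the update gates toward
        # "remember" so band positions reach the pooled readout (see module
        # docstring)
        for gru in (self.gru1, self.gru2):
            gru.params["b"][:gru.hidden_size] = config.gru_update_bias
        self.head = Dense(g2, config.n_classes, rng)

    # -- plumbing -----------------------------------------------------------

    @property
    def layers(self):
        out = []
        for stack in self.channel_stacks:
            out.extend(stack)
        out.extend([self.gru1, self.gru2, self.head])
        return out

    def parameter_count(self) -> int:
        return sum(layer.parameter_count() for layer in self.layers)

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for layer in self.layers
                         for p in layer.params.values()))

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if x.ndim != 3 or x.shape[1] != self.config.n_channels \
                or x.shape[2] != self.input_length:
            raise ValueError(
                f"expected input of shape (n, {self.config.n_channels}, "
                f"{self.input_length}), got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Logits of shape (n, n_classes); caches activations when training."""
        x = self._check_input(x)
        maps = []
        for c, stack in enumerate(self.channel_stacks):
            h = x[:, c:c + 1, :]
            for layer in stack:
                h = layer.forward(h, training)
            maps.append(h)
        feat = np.concatenate(maps, axis=1)          # (n, 3*f3, L)
        # segment-average along the wavenumber axis (the last segment may be
        # shorter than seq_pool)
        length = feat.shape[2]
        starts = np.arange(0, length, self.config.seq_pool)
        counts = np.diff(np.append(starts, length))
        pooled_seq = np.add.reduceat(feat, starts, axis=2) / counts
        self._seg_counts = counts
        seq = np.ascontiguousarray(pooled_seq.transpose(0, 2, 1))
        h1 = self.gru1.forward(seq, training)
        h2 = self.gru2.forward(h1, training)
        pooled = h2.mean(axis=1)                     # global average pooling
        self._pooled = pooled
        self._seq_len = h2.shape[1]
        return self.head.forward(pooled, training)

    def backward(self, dlogits: np.ndarray):
        dpooled = self.head.backward(dlogits)
        dh2 = np.repeat(dpooled[:, None, :], self._seq_len, axis=1) / self._seq_len
        dh1 = self.gru2.backward(dh2)
        dseq = self.gru1.backward(dh1)
        dpool = np.ascontiguousarray(dseq.transpose(0, 2, 1)) / self._seg_counts
        dfeat = np.repeat(dpool, self._seg_counts, axis=2)
        f3 = self.config.conv_filters[2]
        for c, stack in enumerate(self.channel_stacks):
            g = dfeat[:, c * f3:(c + 1) * f3, :]
            for layer in reversed(stack):
                g = layer.backward(g)

    # -- inference ----------------------------------------------------------

    def save(self, path):
        """Self-describing checkpoint: config JSON + weights + BN statistics
        in one npz archive."""
        import dataclasses as _dc
        import json as _json
        arrays = {"__config__": np.frombuffer(
            _json.dumps({**_dc.asdict(self.config),
                         "input_length": self.input_length}).encode(),
            dtype=np.uint8)}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                arrays[f"layer{i}/{name}"] = p
            if isinstance(layer, BatchNorm1d):
                arrays[f"layer{i}/running_mean"] = layer.running_mean
                arrays[f"layer{i}/running_var"] = layer.running_var
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MCCNNGRU":
        import json as _json
        with np.load(path) as archive:
            meta = _json.loads(bytes(archive["__config__"]).decode())
            input_length = meta.pop("input_length")
            for key in ("conv_filters", "gru_units"):
                meta[key] = tuple(meta[key])
            model = cls(MCCNNGRUConfig(**meta), input_length)
            for i, layer in enumerate(model.layers):
                for name in layer.params:
                    layer.params[name] = archive[f"layer{i}/{name}"]
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean = archive[f"layer{i}/running_mean"]
                    layer.running_var = archive[f"layer{i}/running_var"]
        return model

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba(x)
        return np.array([self.class_labels[i] for i in p.argmax(axis=1)])

    def penultimate(self, x: np.ndarray) -> np.ndarray:
        """Features of the layer before the output head (pooled GRU state)."""
        self.forward(x, training=False)
        return self._pooled.copy()


def build_model(config: MCCNNGRUConfig, input_length: int) -> MCCNNGRU:
    return MCCNNGRU(config, input_length)


def build_channels(spectra: LabeledSpectrumSet,
                   preprocess: PreprocessConfig | None = None) -> np.ndarray:
    """Assemble the three aligned input channels, shape (n, 3, n_points).

    Channel 1 is the normalized, baseline-corrected spectrum; channels 2 and
    3 are its Savitzky-Golay-smoothed and FFT-low-pass-filtered versions.
    """
    preprocess = preprocess or PreprocessConfig()
    rows = []
    for s in spectra:
        base = baseline_correct(normalize(s, preprocess.normalize_mode), preprocess)
        rows.append(np.stack([
            base.intensities,
            sg_smooth(base, preprocess).intensities,
            fft_lowpass(base, preprocess).intensities,
        ]))
    return np.stack(rows)


def _labels_to_targets(labels: np.ndarray, class_labels=MCCNNGRU.class_labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(class_labels)}
    return np.array([index[lab] for lab in labels])


def train(model: MCCNNGRU, channels: np.ndarray, labels: np.ndarray,
          split: SplitIndices | None = None,
          config: MCCNNGRUConfig | None = None) -> TrainingHistory:
    """Train in place on ``split.train`` (or all samples when no split).

    Fully seeded: the shuffling rng derives from ``config.seed`` so repeated
    runs produce identical histories.
    """
    config = config or model.config
    labels = np.asarray(labels)
    if split is not None:
        idx = np.asarray(split.train)
        if idx.max() >= channels.shape[0]:
            raise ValueError("split indices exceed the dataset size")
        x_train, y_train = channels[idx], labels[idx]
    else:
        x_train, y_train = channels, labels
    targets = _labels_to_targets(y_train)
    n = x_train.shape[0]
    optimizer = _Adam()
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory()
    for epoch in range(1, config.max_epochs + 1):
        lr = learning_rate_at(epoch, config)
        order = shuffle_rng.permutation(n)
        batch_losses = []
        n_correct = 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = model.forward(x_train[sel], training=True)
            loss, dlogits = softmax_cross_entropy(logits, targets[sel])
            if not np.isfinite(loss):
                raise TrainingError("training diverged: non-finite loss", epoch)
            model.backward(dlogits)
            optimizer.step(model.layers, lr)
            batch_losses.append(loss)
            n_correct += int((logits.argmax(axis=1) == targets[sel]).sum())
        epoch_loss = float(np.mean(batch_losses))
        train_acc = n_correct / n
        history.loss.append(epoch_loss)
        history.accuracy.append(train_acc)
        history.learning_rate.append(lr)
        history.stop_epoch = epoch
        if epoch_loss < config.early_stop_loss:
            history.stop_reason = "early_stop"
            break
    else:
        history.stop_reason = "max_epochs"
    return history


def predict(model: MCCNNGRU, channels: np.ndarray):
    """(class codes, probabilities) for a channel tensor."""
    proba = model.predict_proba(channels)
    codes = np.array([model.class_labels[i] for i in proba.argmax(axis=1)])
    return codes, proba


def embed(model: MCCNNGRU, channels: np.ndarray, labels: np.ndarray,
          perplexity: float | None = None, seed: int | None = None) -> EmbeddingResult:
    """t-SNE embedding of the penultimate-layer features."""
    feats = model.penultimate(channels)
    n = feats.shape[0]
    perplexity = model.config.tsne_perplexity if perplexity is None else perplexity
    if n <= perplexity:
        raise ValueError(
            f"t-SNE needs more samples ({n}) than the perplexity ({perplexity})"
        )
    seed = model.config.seed if seed is None else seed
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed)
    coords = tsne.fit_transform(feats)
    return EmbeddingResult(penultimate_features=feats, tsne_coords=coords,
                           labels=np.asarray(labels))
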