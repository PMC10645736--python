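"""Seeded replicates of the classification study.

One replicate = generate the default 78-spectrum dataset with the given
seed, preprocess, extract the 55-wavenumber feature matrix, Kennard-Stone
split 50/28, then fit and score a classifier:

* :func:`svm_replicate` — integer log2 grid search of the RBF SVM on the
  training split (5-fold stratified CV objective), refit at the optimum,
  report train/test accuracy;
* :func:`cnn_replicate` — train the MC-CNN-GRU with its documented
  defaults on the training split, report train/test accuracy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .classical import evaluate, svm_grid_search, svm_train
from .features import FeatureMatrix, SplitIndices, kennard_stone_split, select_peak_windows
from .nn.model import MCCNNGRU, MCCNNGRUConfig, TrainingHistory, build_channels, build_model, train
from .preprocess import PreprocessConfig, preprocess_set
from .simulate import GeneratorConfig, LabeledSpectrumSet, generate_dataset

__all__ = ["StudyData", "SVMReplicate", "CNNReplicate",
           "prepare_study_data", "svm_replicate", "cnn_replicate"]


@dataclass
class StudyData:
    dataset: LabeledSpectrumSet
    features: FeatureMatrix
    split: SplitIndices


@dataclass
class SVMReplicate:
    seed: int
    log2C: int
    log2g: int
    cv_accuracy: float
    train_accuracy: float
    test_accuracy: float


@dataclass
class CNNReplicate:
    seed: int
    train_accuracy: float
    test_accuracy: float
    history: TrainingHistory
    model: MCCNNGRU
    channels: np.ndarray
    data: StudyData


def prepare_study_data(seed: int, n_train: int = 50) -> StudyData:
    config = dataclasses.replace(GeneratorConfig(), seed=seed)
    dataset = generate_dataset(config)
    processed = preprocess_set(dataset, PreprocessConfig())
    features = select_peak_windows(processed)
    split = kennard_stone_split(features, n_train)
    return StudyData(dataset, features, split)


def svm_replicate(seed: int) -> SVMReplicate:
    data = prepare_study_data(seed)
    X, y = data.features.values, data.features.labels
    tr, te = data.split.train, data.split.test
    grid = svm_grid_search(X[tr], y[tr])
    model = svm_train(X[tr], y[tr], grid.C, grid.g)
    return SVMReplicate(
        seed=seed, log2C=grid.log2C, log2g=grid.log2g,
        cv_accuracy=grid.best_objective,
        train_accuracy=evaluate(model, X[tr], y[tr]).accuracy,
        test_accuracy=evaluate(model, X[te], y[te]).accuracy,
    )


def cnn_replicate(seed: int, config: MCCNNGRUConfig | None = None) -> CNNReplicate:
    data = prepare_study_data(seed)
    labels = data.features.labels
    channels = build_channels(data.dataset)
    config = config or MCCNNGRUConfig(seed=seed)
    model = build_model(config, channels.shape[2])
    history = train(model, channels, labels, data.split, config)
    tr, te = data.split.train, data.split.test
    return CNNReplicate(
        seed=seed,
        train_accuracy=evaluate(model, channels[tr], labels[tr]).accuracy,
        test_accuracy=evaluate(model, channels[te], labels[te]).accuracy,
        history=history, model=model, channels=channels, data=data,
    )
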