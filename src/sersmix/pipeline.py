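"""End-to-end pipeline: simulate -> preprocess -> features -> split ->
SVM grid search -> MC-CNN-GRU -> evaluate -> embed, with a reproducibility
manifest of config hash, seed and per-stage artifact checksums."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .classical import evaluate, svm_grid_search, svm_train
from .errors import StageError
from .features import (DEFAULT_PEAK_CENTERS, kennard_stone_split,
                       select_peak_windows)
from .nn.model import (MCCNNGRUConfig, build_channels, build_model, embed,
                       train)
from .preprocess import PreprocessConfig, preprocess_set
from .simulate import GeneratorConfig, generate_dataset

__all__ = ["SVMSettings", "RunConfig", "run_pipeline", "PIPELINE_STAGES"]

PIPELINE_STAGES = ("simulate", "preprocess", "features", "split",
                   "svm", "cnn", "evaluate", "embed")


@dataclass(frozen=True)
class SVMSettings:
    log2_min: int = -10
    log2_max: int = 10
    folds: int = 5
    n_train: int = 50
    peak_centers: tuple[float, ...] = DEFAULT_PEAK_CENTERS
    half_points: int = 5


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: MCCNNGRUConfig = field(default_factory=MCCNNGRUConfig)
    svm: SVMSettings = field(default_factory=SVMSettings)
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one seed to every seeded component."""
        return dataclasses.replace(
            self,
            seed=seed,
            generator=dataclasses.replace(self.generator, seed=seed),
            model=dataclasses.replace(self.model, seed=seed),
        )


def _config_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _config_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _config_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_dict(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages, write artifacts under ``out_dir`` and return the
    manifest (also written as ``manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()).hexdigest(),
        "stages": {},
    }

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {
            "artifacts": {p.name: _sha256(p) for p in paths}}

    stage = "simulate"
    try:
        dataset = generate_dataset(config.generator)
        p1, p2 = out / "spectra.csv", out / "labels.csv"
        sio.write_wide_csv(dataset, p1, p2)
        record(stage, p1, p2)

        stage = "preprocess"
        processed = preprocess_set(dataset, config.preprocess)
        p = out / "preprocessed.csv"
        sio.write_wide_csv(processed, p)
        record(stage, p)

        stage = "features"
        features = select_peak_windows(processed, config.svm.peak_centers,
                                       config.svm.half_points)
        p = out / "features.csv"
        sio.write_feature_matrix(features, p)
        record(stage, p)

        stage = "split"
        split = kennard_stone_split(features, config.svm.n_train)
        p = out / "split.csv"
        sio.write_split(split, p)
        record(stage, p)

        stage = "svm"
        X, y = features.values, features.labels
        Xtr, ytr = X[split.train], y[split.train]
        Xte, yte = X[split.test], y[split.test]
        grid = svm_grid_search(Xtr, ytr,
                               (config.svm.log2_min, config.svm.log2_max),
                               config.svm.folds)
        svm = svm_train(Xtr, ytr, grid.C, grid.g)
        p = out / "svm_grid.json"
        sio.write_json({"log2C": grid.log2C, "log2g": grid.log2g,
                        "best_objective": grid.best_objective,
                        "objective_surface": grid.objective_surface.tolist()}, p)
        record(stage, p)

        stage = "cnn"
        channels = build_channels(dataset, config.preprocess)
        model = build_model(config.model, channels.shape[2])
        history = train(model, channels, y, split, config.model)
        p = out / "training_history.json"
        sio.write_json({"loss": history.loss, "accuracy": history.accuracy,
                        "stop_epoch": history.stop_epoch,
                        "stop_reason": history.stop_reason}, p)
        record(stage, p)

        stage = "evaluate"
        reports = {
            "svm_train": evaluate(svm, Xtr, ytr,
                                  hyperparameters={"log2C": grid.log2C,
                                                   "log2g": grid.log2g}).to_dict(),
            "svm_test": evaluate(svm, Xte, yte).to_dict(),
            "cnn_train": evaluate(model, channels[split.train], ytr).to_dict(),
            "cnn_test": evaluate(model, channels[split.test], yte).to_dict(),
        }
        p = out / "reports.json"
        sio.write_json(reports, p)
        record(stage, p)

        stage = "embed"
        emb = embed(model, channels, y)
        p = out / "embedding.csv"
        np.savetxt(p, np.column_stack([emb.tsne_coords, y]),
                   header="tsne1 tsne2 label", fmt="%.17g")
        record(stage, p)
    except Exception as e:  # keep partial artifacts, name the stage
        sio.write_json(manifest, out / "manifest.json")
        raise StageError(stage, e) from e

    sio.write_json(manifest, out / "manifest.json")
    return manifest
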