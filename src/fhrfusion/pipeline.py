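"""End-to-end orchestration: records -> segments -> features + images -> model.

Convenience layer tying the stage modules together for scripts, the CLI and
the examples.  Every function is deterministic given its seed arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, imaging, model, nn
from .features import FEATURE_NAMES, MinMaxNormalizer, extract_features
from .imaging import DEFAULT_STACK
from .preprocessing import FHRSegment, RawCTGRecord, preprocess_record
from .synthetic import LabeledDataset, SyntheticConfig, generate_dataset

__all__ = [
    "PreparedInputs",
    "segments_from_records",
    "features_table",
    "image_array",
    "prepare_inputs",
    "train_model",
    "combined_builder",
    "save_model",
    "load_model",
    "features_to_csv",
]


@dataclass
class PreparedInputs:
    """Aligned per-segment model inputs."""

    features_raw: np.ndarray  # (n, 15), unnormalized
    images: np.ndarray  # (n, 64, 64, c)
    labels: np.ndarray  # (n,)
    segment_ids: list[str]
    encoders: tuple[str, ...]


def segments_from_records(
    records: list[RawCTGRecord],
    max_interp_s: float = 15.0,
    quality_cap: float = 0.10,
) -> list[FHRSegment]:
    segments: list[FHRSegment] = []
    for rec in records:
        segments.extend(preprocess_record(rec, max_interp_s=max_interp_s, quality_cap=quality_cap))
    return segments


def features_table(segments: list[FHRSegment]) -> pd.DataFrame:
    """Raw (unnormalized) 15-feature table, one row per segment."""
    rows = []
    for seg in segments:
        fv = extract_features(seg)
        row = dict(zip(FEATURE_NAMES, fv.to_array()))
        row["segment_id"] = seg.segment_id
        row["record_id"] = seg.record_id
        row["label"] = seg.label
        rows.append(row)
    return pd.DataFrame(rows, columns=["segment_id", "record_id", "label", *FEATURE_NAMES])


def image_array(segments: list[FHRSegment], encoders: tuple[str, ...] = DEFAULT_STACK) -> np.ndarray:
    """Encode every segment; shape (n, 64, 64, len(encoders))."""
    return np.stack([imaging.stack(seg, encoders).to_array() for seg in segments])


def prepare_inputs(
    dataset: LabeledDataset,
    encoders: tuple[str, ...] = DEFAULT_STACK,
) -> PreparedInputs:
    segments = segments_from_records(dataset.records)
    table = features_table(segments)
    images = image_array(segments, encoders)
    return PreparedInputs(
        features_raw=table[FEATURE_NAMES].to_numpy(dtype=float),
        images=images,
        labels=table["label"].to_numpy(dtype=int),
        segment_ids=list(table["segment_id"]),
        encoders=encoders,
    )


def train_model(
    kind: str,
    features_norm: np.ndarray | None,
    images: np.ndarray | None,
    labels: np.ndarray,
    cfg: model.TrainingConfig,
    fusion: str = "softmax",
):
    """Build and train an 'mlp', 'cnn' or 'combined' model; returns (net, history)."""
    if kind == "mlp":
        net = model.build(model.MLPSpec(), seed=cfg.seed)
        x = features_norm
    elif kind == "cnn":
        net = model.build(model.CNNSpec(n_images=images.shape[-1]), seed=cfg.seed)
        x = images
    elif kind == "combined":
        spec = model.CombinedSpec(cnn=model.CNNSpec(n_images=images.shape[-1]), fusion=fusion)
        net = model.build(spec, seed=cfg.seed)
        x = (features_norm, images)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    history = model.train(net, x, labels, cfg)
    return net, history


def combined_builder(cfg_template: model.TrainingConfig, kind: str = "combined", fusion: str = "softmax"):
    """A builder closure for :func:`fhrfusion.evaluation.repeated_protocol`.

    Normalization statistics are learned inside the builder on each run's
    training rows only, so no test information leaks into scaling.
    """

    def builder(x_train, y_train, run_seed: int):
        cfg = model.TrainingConfig(
            learning_rate=cfg_template.learning_rate,
            decay=cfg_template.decay,
            batch_size=cfg_template.batch_size,
            max_epochs=cfg_template.max_epochs,
            patience=cfg_template.patience,
            train_fraction=cfg_template.train_fraction,
            val_fraction=cfg_template.val_fraction,
            restore_best=cfg_template.restore_best,
            seed=run_seed,
        )
        if kind == "combined":
            feats_raw, images = x_train
            normalizer = MinMaxNormalizer().fit(feats_raw)
            net, _ = train_model(kind, normalizer.transform(feats_raw), images, y_train, cfg, fusion)
            return _NormalizingModel(net, normalizer, kind)
        if kind == "mlp":
            normalizer = MinMaxNormalizer().fit(x_train)
            net, _ = train_model(kind, normalizer.transform(x_train), None, y_train, cfg)
            return _NormalizingModel(net, normalizer, kind)
        net, _ = train_model(kind, None, x_train, y_train, cfg)
        return _NormalizingModel(net, None, kind)

    return builder


class _NormalizingModel:
    """Wraps a trained net with the training-partition feature scaling."""

    def __init__(self, net, normalizer: MinMaxNormalizer | None, kind: str):
        self.net, self.normalizer, self.kind = net, normalizer, kind

    def predict(self, x):
        if self.kind == "combined":
            feats_raw, images = x
            return self.net.predict((self.normalizer.transform(feats_raw), images))
        if self.kind == "mlp":
            return self.net.predict(self.normalizer.transform(x))
        return self.net.predict(x)


# ---------------------------------------------------------------------------
# Checkpoints: parameter arrays in an .npz plus a JSON spec sidecar.
# ---------------------------------------------------------------------------

def save_model(net, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for key, layer in nn._unique_layers(net):
        for name, value in layer.params.items():
            arrays[f"{key}:{name}"] = value
        if isinstance(layer, nn.BatchNorm):
            arrays[f"{key}:running_mean"] = layer.running_mean
            arrays[f"{key}:running_var"] = layer.running_var
    np.savez(path, **arrays)
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_model(net, path: str | Path):
    """Load saved parameters into a freshly built net of the same topology."""
    data = np.load(Path(path) if str(path).endswith(".npz") else Path(str(path) + ".npz"))
    for key, layer in nn._unique_layers(net):
        for name in layer.params:
            layer.params[name][...] = data[f"{key}:{name}"]
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean[...] = data[f"{key}:running_mean"]
            layer.running_var[...] = data[f"{key}:running_var"]
    return net


def features_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
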