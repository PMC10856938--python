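"""The two classifiers: a dense network over the 240 FIBF statistics and a
1-D convolutional network over the 1495-value spectrogram image.

Architectures (swish activations throughout; a 3-way softmax head is
appended — the feature-table descriptions end at the last hidden layer):

* ``mlp``:  dense 128 -> dropout 0.3 -> dense 80 -> dropout 0.2 -> softmax(3)
* ``cnn``:  reshape to 23 time steps x 65 channels -> conv1d(128, k=5, same)
  -> avgpool(2) -> dropout 0.4 -> conv1d(64, k=5, same) -> avgpool(2)
  -> dropout 0.3 -> flatten -> dense 60 -> dropout 0.3 -> dense 30
  -> dropout 0.2 -> dense 20 -> softmax(3)

Training uses Adam with categorical cross-entropy, batch size 32 and a
stratified validation split; defaults are lr 8e-4 / 250 epochs for the
dense model and lr 4e-4 / 400 epochs for the convolutional one.  An
8-bit affine quantization of weights and activations can be emulated
in-place for deployment studies.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .core import CLASS_LABELS, UNCERTAIN
from . import nn

logger = logging.getLogger(__name__)

DEFAULT_UNCERTAIN_THRESHOLD = 0.6


@dataclass
class ModelSpec:
    kind: str  # "mlp" | "cnn"
    input_len: int
    n_classes: int = 3
    reshape_rows: int = 23  # cnn only

    def __post_init__(self):
        if self.kind not in ("mlp", "cnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "cnn" and self.input_len % self.reshape_rows:
            raise ValueError(
                f"cnn input length {self.input_len} not divisible by {self.reshape_rows} reshape rows"
            )


@dataclass
class TrainConfig:
    learning_rate: float = 8e-4
    epochs: int = 250
    validation_fraction: float = 0.2
    batch_size: int = 32
    seed: int = 0
    quantized: bool = False

    @classmethod
    def method1_defaults(cls, **kw) -> "TrainConfig":
        return cls(**{"learning_rate": 8e-4, "epochs": 250, **kw})

    @classmethod
    def method2_defaults(cls, **kw) -> "TrainConfig":
        return cls(**{"learning_rate": 4e-4, "epochs": 400, **kw})


@dataclass
class Prediction:
    probabilities: np.ndarray  # over CLASS_LABELS, sums to 1
    label: str  # CLASS_LABELS entry or "uncertain"
    threshold: float


@dataclass
class TrainedModel:
    net: nn.Sequential
    spec: ModelSpec
    classes: tuple = CLASS_LABELS

    @property
    def quantized(self) -> bool:
        return self.net.quantized


def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Instantiate an untrained network for ``spec`` (init seeded)."""
    rng = np.random.default_rng(seed)
    if spec.kind == "mlp":
        layers = [
            nn.Dense(spec.input_len, 128, rng), nn.Swish(), nn.Dropout(0.3),
            nn.Dense(128, 80, rng), nn.Swish(), nn.Dropout(0.2),
            nn.Dense(80, spec.n_classes, rng),
        ]
    else:
        channels = spec.input_len // spec.reshape_rows
        t = spec.reshape_rows
        t1 = -(-t // 2)  # after first pool
        t2 = -(-t1 // 2)
        layers = [
            nn.Reshape(spec.reshape_rows),
            nn.Conv1D(channels, 128, 5, rng), nn.Swish(), nn.AvgPool1D(2), nn.Dropout(0.4),
            nn.Conv1D(128, 64, 5, rng), nn.Swish(), nn.AvgPool1D(2), nn.Dropout(0.3),
            nn.Flatten(),
            nn.Dense(t2 * 64, 60, rng), nn.Swish(), nn.Dropout(0.3),
            nn.Dense(60, 30, rng), nn.Swish(), nn.Dropout(0.2),
            nn.Dense(30, 20, rng), nn.Swish(),
            nn.Dense(20, spec.n_classes, rng),
        ]
    return TrainedModel(net=nn.Sequential(layers), spec=spec)


def _encode_labels(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[lab] for lab in labels])
    except KeyError as e:
        raise ValueError(f"unknown label {e.args[0]!r}") from None


def train(model: TrainedModel, features: np.ndarray, labels, config: TrainConfig) -> dict:
    """Train in place; returns the per-epoch history.

    Deterministic given ``config.seed`` (weights are re-initialized from
    it so identical calls converge to identical parameters).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.spec.input_len:
        raise ValueError(f"features must be (n, {model.spec.input_len})")
    y = _encode_labels(labels, model.classes)
    if np.unique(y).size < 2:
        raise ValueError("training needs at least two classes present")

    fresh = build_model(model.spec, seed=config.seed)
    model.net = fresh.net
    net = model.net

    xt, xv, yt, yv = train_test_split(
        x, y, test_size=config.validation_fraction, stratify=y, random_state=config.seed
    )
    onehot = np.eye(len(model.classes))

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(net, lr=config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    for epoch in range(config.epochs):
        order = rng.permutation(xt.shape[0])
        losses = []
        for lo in range(0, xt.shape[0], config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits = net.forward(xt[idx], train=True, rng=rng)
            loss, grad = nn.cross_entropy(logits, onehot[yt[idx]])
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf loss at epoch {epoch}; lower the learning rate")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        pt = net.predict_proba(xt)
        pv = net.predict_proba(xv)
        vloss = float(-np.log(np.clip(pv[np.arange(yv.size), yv], 1e-12, None)).mean())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float((pt.argmax(1) == yt).mean()))
        history["val_loss"].append(vloss)
        history["val_accuracy"].append(float((pv.argmax(1) == yv).mean()))
    if config.quantized:
        quantize_emulate(model, xt)
    return history


def predict(model: TrainedModel, features: np.ndarray,
            uncertain_threshold: float = DEFAULT_UNCERTAIN_THRESHOLD) -> Prediction:
    """Classify one feature vector, abstaining below the confidence threshold."""
    f = np.asarray(features, dtype=float).reshape(-1)
    if f.size != model.spec.input_len:
        raise ValueError(f"expected {model.spec.input_len} features, got {f.size}")
    probs = model.net.predict_proba(f)[0]
    best = int(probs.argmax())  # argmax returns the lowest index on ties
    if probs[best] >= uncertain_threshold:
        label = model.classes[best]
    else:
        label = UNCERTAIN
    return Prediction(probabilities=probs, label=label, threshold=uncertain_threshold)


def predict_batch(model: TrainedModel, features: np.ndarray,
                  uncertain_threshold: float = DEFAULT_UNCERTAIN_THRESHOLD) -> list:
    x = np.asarray(features, dtype=float)
    probs = model.net.predict_proba(x)
    out = []
    for p in probs:
        best = int(p.argmax())
        lab = model.classes[best] if p[best] >= uncertain_threshold else UNCERTAIN
        out.append(Prediction(probabilities=p, label=lab, threshold=uncertain_threshold))
    return out


def quantize_emulate(model: TrainedModel, calibration: np.ndarray) -> TrainedModel:
    """Emulate 8-bit affine quantization of weights and activations in place.

    Weight tensors are snapped to a per-tensor uint8 grid; activation
    ranges are calibrated on ``calibration`` and applied at inference.
    Quantizing an already-quantized model is a no-op (the weights are
    already on their grids and the recorded activation ranges stand).
    """
    cal = np.asarray(calibration, dtype=float)
    if cal.size == 0:
        raise ValueError("calibration set must be non-empty")
    if model.net.quantized:
        return model
    net = model.net
    for layer in net.layers:
        for p in layer.params:
            if p.ndim >= 2:  # weight matrices; biases stay float (32-bit accumulators)
                scale, zp = nn.quant_params(float(p.min()), float(p.max()))
                p[...] = nn.fake_quant(p, scale, zp)
    # calibrate activation ranges layer by layer
    x = np.atleast_2d(cal)
    meta = []
    for layer in net.layers:
        x = layer.forward(x, False, None)
        if isinstance(layer, (nn.Dense, nn.Conv1D, nn.Swish)):
            scale, zp = nn.quant_params(float(x.min()), float(x.max()))
            meta.append((scale, zp))
            x = nn.fake_quant(x, scale, zp)
        else:
            meta.append(None)
    net.quant_meta = meta
    net.quantized = True
    return model


# ---------------------------------------------------------------------------
# Serialization: a directory with spec.json + weights.npz


def save_model(model: TrainedModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = {
        "kind": model.spec.kind,
        "input_len": model.spec.input_len,
        "n_classes": model.spec.n_classes,
        "reshape_rows": model.spec.reshape_rows,
        "classes": list(model.classes),
        "quantized": model.net.quantized,
        "quant_meta": model.net.quant_meta,
    }
    (out / "spec.json").write_text(json.dumps(spec, indent=1))
    arrays = {}
    for i, layer in enumerate(model.net.layers):
        for j, p in enumerate(layer.params):
            arrays[f"layer{i}_p{j}"] = p
    np.savez(out / "weights.npz", **arrays)
    return out


def load_model(model_dir: str | Path) -> TrainedModel:
    d = Path(model_dir)
    spec = json.loads((d / "spec.json").read_text())
    model = build_model(ModelSpec(spec["kind"], spec["input_len"], spec["n_classes"],
                                  spec["reshape_rows"]))
    model.classes = tuple(spec["classes"])
    with np.load(d / "weights.npz") as z:
        for i, layer in enumerate(model.net.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = z[f"layer{i}_p{j}"]
    if spec["quantized"]:
        model.net.quantized = True
        model.net.quant_meta = [tuple(m) if m is not None else None for m in spec["quant_meta"]]
    return model
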