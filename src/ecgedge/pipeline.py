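"""End-to-end helpers tying the modules into the two detection pipelines.

These are the batch-mode counterparts of the streaming loop: extract the
per-window features for a whole corpus, train a classifier, and score it
on the held-out split.  Used by the CLI, the examples and the acceptance
checks alike.
"""

from __future__ import annotations

import numpy as np

from .core import EcgSignal
from .evaluation import ConfusionReport, confusion
from .features_m1 import method1_window_features
from .fdm import BandSpec, default_band_edges
from .models import (ModelSpec, TrainConfig, TrainedModel, build_model,
                     predict_batch, train)
from .spectrogram import SpectrogramParams, compute_spectrogram


def extract_features(signals, method: int, band_spec: BandSpec | None = None,
                     norm_mode: str = "maxabs",
                     spectrogram_params: SpectrogramParams | None = None) -> tuple:
    """One feature row per (signal, split) pair; returns (X, labels, splits)."""
    rows, labels, splits = [], [], []
    for sig, split in signals:
        if method == 1:
            bs = band_spec or default_band_edges(sig.fs)
            rows.append(method1_window_features(sig, band_spec=bs, norm_mode=norm_mode).values)
        elif method == 2:
            rows.append(compute_spectrogram(sig, spectrogram_params).flatten())
        else:
            raise ValueError("method must be 1 or 2")
        labels.append(sig.label)
        splits.append(split)
    return np.vstack(rows), np.array(labels), np.array(splits)


def train_and_evaluate(x: np.ndarray, labels: np.ndarray, splits: np.ndarray,
                       method: int, seed: int = 0, epochs: int | None = None,
                       uncertain_threshold: float = 0.6,
                       quantized: bool = False) -> tuple:
    """Train the method's classifier on the train split, score on test.

    Returns ``(model, history, ConfusionReport)``.
    """
    if method == 1:
        spec = ModelSpec("mlp", input_len=x.shape[1])
        cfg = TrainConfig.method1_defaults(seed=seed, quantized=quantized)
    else:
        spec = ModelSpec("cnn", input_len=x.shape[1])
        cfg = TrainConfig.method2_defaults(seed=seed, quantized=quantized)
    if epochs is not None:
        cfg.epochs = epochs
    model = build_model(spec, seed=seed)
    tr = splits == "train"
    history = train(model, x[tr], labels[tr], cfg)
    preds = predict_batch(model, x[~tr], uncertain_threshold=uncertain_threshold)
    report = confusion(labels[~tr], [p.label for p in preds])
    return model, history, report
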