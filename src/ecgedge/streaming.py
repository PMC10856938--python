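"""Streaming inference emulator.

Replays a preprocessed 128 Hz signal through the runtime loop of the
target device: Method 1 updates a rolling FIBF-feature buffer every
0.5 s and runs the dense classifier on the assembled 240-vector every
6 s; Method 2 recomputes the spectrogram of the trailing 6 s buffer at
the same inference cadence.  The first inference fires once a full
window of real samples has accumulated (the device fills its buffer
before classifying).  Every decision window is passed through the
skewness/kurtosis validity monitor; windows failing it are decided
``uncertain`` regardless of the classifier output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import EcgSignal, UNCERTAIN
from .features_m1 import FeatureVector, frame_features, FRAME_S, STAT_NAMES
from .fdm import BandSpec, default_band_edges
from .models import (DEFAULT_UNCERTAIN_THRESHOLD, Prediction, TrainedModel, predict)
from .preprocess import quality_check, QualityReport
from .spectrogram import SpectrogramParams, compute_spectrogram

logger = logging.getLogger(__name__)


@dataclass
class StreamEvent:
    """One inference emitted by the streaming loop."""

    time_s: float
    prediction: Prediction
    method: int
    quality: QualityReport
    quality_override: bool = False
    feature_update_times: list = field(default_factory=list)
    features: np.ndarray | None = None  # the vector the classifier saw


def stream_detect(
    signal: EcgSignal,
    method: int,
    model: TrainedModel,
    inference_s: float = 6.0,
    update_s: float = 0.5,
    threshold: float = DEFAULT_UNCERTAIN_THRESHOLD,
    band_spec: BandSpec | None = None,
    norm_mode: str = "maxabs",
    spectrogram_params: SpectrogramParams | None = None,
) -> list:
    """Run the streaming loop over ``signal`` and return its events.

    Returns one :class:`StreamEvent` per inference, fired at
    t = inference_s, 2*inference_s, ... while a full window of samples is
    available: ``floor(duration / inference_s)`` events in total.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    fs = signal.fs
    win_len = int(round(inference_s * fs))
    if signal.n_samples < win_len:
        raise ValueError(
            f"signal holds {signal.duration_s:.2f} s; one inference window needs {inference_s} s"
        )
    if band_spec is None:
        band_spec = default_band_edges(fs)
    n_events = signal.n_samples // win_len
    step = int(round(update_s * fs))
    frame_len = int(round(FRAME_S * fs))
    x = signal.samples

    events: list = []
    if method == 1:
        updates_per_window = int(round(inference_s / update_s))
        width = band_spec.n_bands * len(STAT_NAMES)
        buffer: list = []  # rolling per-update feature rows (time, row)
        n_updates_total = x.size // step
        for k in range(1, n_updates_total + 1):
            end = k * step
            start = end - frame_len
            if start >= 0:
                frame = x[start:end]
            else:
                frame = np.concatenate([np.zeros(-start), x[:end]])
            buffer.append((k * update_s, frame_features(frame, band_spec, fs, norm_mode)))
            buffer = buffer[-updates_per_window:]
            t = k * update_s
            if len(events) < n_events and abs(t % inference_s) < 1e-9 and len(buffer) == updates_per_window:
                values = np.concatenate([row for _, row in buffer])
                fv = FeatureVector(values=values, n_frames=updates_per_window,
                                   n_bands=band_spec.n_bands, window_s=inference_s, update_s=update_s)
                events.append(_emit(signal, t, win_len, fv.values, model, threshold, 1,
                                    [u for u, _ in buffer]))
    else:
        params = spectrogram_params or SpectrogramParams()
        for e in range(1, n_events + 1):
            t = e * inference_s
            window = signal.with_samples(x[int(round((t - inference_s) * fs)) : int(round(t * fs))])
            feats = compute_spectrogram(window, params).flatten()
            events.append(_emit(signal, t, win_len, feats, model, threshold, 2, [t]))
    logger.info("stream_detect: %d events over %.1f s (method %d)", len(events), signal.duration_s, method)
    return events


def _emit(signal, t, win_len, features, model, threshold, method, update_times) -> StreamEvent:
    end = int(round(t * signal.fs))
    window = signal.with_samples(signal.samples[end - win_len : end])
    quality = quality_check(window)
    pred = predict(model, features, uncertain_threshold=threshold)
    override = not quality.passed
    if override:
        pred = Prediction(probabilities=pred.probabilities, label=UNCERTAIN, threshold=threshold)
        logger.warning("window ending %.1f s failed the quality monitor; decision forced uncertain", t)
    return StreamEvent(time_s=t, prediction=pred, method=method, quality=quality,
                       quality_override=override, feature_update_times=list(update_times),
                       features=np.asarray(features, dtype=float))
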