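# Methods

This note records the models, conventions and open design choices behind
the package, and what its tests do and do not establish.

## Signal model and classes

The system observes a single lead-II ECG channel resampled to 128 Hz and
decides, once per 6 s window, among *healthy*, *infarcted*, *noise*, or
an *uncertain* abstention. The 6 s window covers several complete P-QRS-T
cycles at any heart rate in the supported 30–220 bpm range; the 2 s
analysis frame of Method 1 covers at least one full cycle down to 30 bpm.

## Synthetic data generator

The generator stands in for a clinical corpus; it produces the structure
the classifiers are designed to exploit, not a physiologically complete
ECG.

* **Beat template** — five Gaussians (P, Q, R, S, T) at fixed offsets
  from the R peak (−200, −35, 0, +35, +300 ms) with widths 25/10/12/10/50
  ms and amplitudes 0.15/−0.10/1.00/−0.15/0.30 (R normalized to 1). This
  is the standard analytically controllable morphology used by dynamical
  ECG models; all amplitudes are configurable.
* **Infarction morphology** — a constant amplitude offset (default 0.2)
  over the ST span, defined as S-center +20 ms to T-center −80 ms, plus
  an optional T-wave inversion (drawn with probability 0.5 per infarcted
  record in generated corpora). Defining the span off the Gaussian
  centers makes the offset's effect on the trace exact, so tests can
  assert it to machine precision.
* **Rhythm** — per-beat RR jitter with 2% standard deviation around the
  configured heart rate; corpus records draw heart rates uniformly from
  55–95 bpm.
* **Noise model** — baseline wander (0.3 Hz sinusoid), white broadband
  noise, and 50 Hz powerline, with per-class default amplitudes
  (0.05/0.01/0.01 for cardiac records; 0.40/0.30/0.20 for the noise
  class, which carries no cardiac template). Random phases and noise are
  drawn identically for healthy and infarcted configurations sharing a
  seed, so paired records differ exactly by the morphological change.
* **Corpora** — `generate_dataset` apportions classes by largest
  remainder, splits 80/20 stratified per class with test counts rounded
  half-up, and derives every record's seed from one base seed. The
  reference corpus size mirrors the full-scale setting (612 records);
  tests and the acceptance run use 90 records for speed.

What the generator does **not** emulate: inter-patient morphology
variability, arrhythmias, electrode-motion artifacts, respiration
modulation, or the heterogeneity of real MI presentations. Passing tests
therefore demonstrate that the pipelines separate classes whose defining
features are present and consistent — a correctness and separability
check, not a claim of clinical performance.

## Preprocessing

Down-sampling is rational and anti-aliased (polyphase), down-only; the
60 Hz low-pass is a zero-phase forward–backward Butterworth of order 4,
matching the zero-phase character of the analysis filter bank. Below
fs = 2.5 × cutoff (150 Hz) the cutoff sits too close to Nyquist for a
meaningful discrete-time response and the filter passes through with a
warning — at the 128 Hz working rate the low-pass belongs *before* the
down-sampler, which `preprocess_chain` enforces. Requantization maps
min→0, max→4095 with round-half-up (the convention used everywhere
amplitudes are quantized).

The validity monitor computes population skewness and raw (non-excess)
kurtosis. Defaults admit skewness in [−6, 6] and kurtosis in [1.2, 40]:
spiky lead-II morphology legitimately reaches skewness ≈ 4.3 and
kurtosis ≈ 28 at 30 bpm, while flat-lined input falls below the kurtosis
floor and gross spike artifacts exceed the ceiling. Both ranges are
configurable assumptions.

## FDM conventions

Band edges in Hz map to DFT bins by `round(f·N/fs)`; the lowest edge's
bin is included in the first band when its frequency equals the edge;
the Nyquist bin (N even) belongs to the top band and is treated as
self-conjugate. Two edges landing on one bin raise an error naming the
band. The default 0.5–4–12–30–60 Hz partition is a clinically motivated
choice (baseline/P–T content, low QRS, high QRS, high-frequency
residue); the exact boundaries are free parameters of the method and are
configurable everywhere. Exact-identity properties (reconstruction,
orthogonality, Parseval, all at 1e-9) hold whenever the bands tile every
bin 1…⌊N/2⌋; `full_tiling_spec` builds such a partition.

## Method-1 feature conventions

* Frames are referenced by their end time: frame k of a window ends at
  t = k·0.5 s and covers the preceding 2 s. In an isolated window the
  first three frames are left-padded with zeros; in streaming (and in
  `method1_window_features(..., history=...)`) they draw on real
  preceding samples.
* Normalization default is max-abs, applied per FIBF before the
  statistics; range normalization ([0, 1]) is available. Per-FIBF
  normalization makes skewness/kurtosis/entropy scale-free and bounds
  every energy feature by the frame length.
* Entropy uses the full two-sided squared FFT magnitude of the
  frame-length FIBF, P normalized by its sum, log base 2, 0·log 0 := 0.
  A flat spectrum of N bins gives the maximum log₂N.
* Degenerate conventions: σ = 0 ⇒ skewness = kurtosis = 0; all-zero
  spectrum ⇒ entropy = 0; an all-zero FIBF skips normalization.

## Method-2 conventions

Frame and stride convert to samples by round-half-up (1.4 s → 179,
0.2 s → 26 at 128 Hz); this is the only convention under which a 6 s
window yields exactly 23 frames, and with 65 one-sided bins the
1495-value image, so it is treated as normative. Frames (179 samples)
exceed the 128-point FFT; the first 128 samples are transformed
(truncation, no taper — the simplest convention consistent with a
fixed-length FFT per frame). Power is |FFT/nfft|², mapped to [0, 1] by
`clip((10·log₁₀(P+ε) − floor)/(−floor))` with floor = −100 dB and
ε = 10^(floor/10), so silence sits exactly at the floor.

## Classifiers

The two architectures end, as specified, at their last hidden layer; a
3-unit softmax head is appended. Loss is categorical cross-entropy,
optimizer Adam, batch size 32 — standard choices where none are fixed.
The CNN reads its input as 23 time rows × 65 frequency channels and
convolves along time. The engine is plain seeded NumPy (Glorot-uniform
init, inverted dropout, 'same' padding, average pooling over the samples
actually present in a partial window), so identical configurations
reproduce identical weights bit-for-bit.

Abstention: the arg-max class is emitted only if its probability clears
the confidence threshold (default 0.6, configurable); ties break toward
the lowest class index. Raising the threshold can only convert decisions
into abstentions, never the reverse.

Quantization emulation snaps each weight matrix to a per-tensor affine
uint8 grid and fake-quantizes activations after every dense/conv/swish
stage with ranges calibrated on a supplied set; biases stay in float,
emulating 32-bit accumulators. Re-quantizing a quantized model is a
no-op. This is a numerical emulation of post-training quantization, not
a deployment artifact.

## Evaluation

Uncertain is a decision column, never a trained class. Per class,
abstentions on that class count as false negatives and never as false
positives, and accuracy = Σ diagonal / all windows, so abstaining always
costs accuracy and recall. Because the printed row-percentages of a
confusion table cannot reveal whether abstained windows were excluded
from recall denominators, both conventions are computed
(`recall` and `recall_excluding_uncertain`); the inclusive one is the
default everywhere.

## Streaming emulator

Feature rows refresh every 0.5 s; inference fires every 6 s once a full
window of real samples exists (warm-up: no partial or padded windows are
classified at stream start beyond the padding inside the first window's
early frames). Every decision window passes through the validity
monitor; failing windows are forced to uncertain and flagged. Method 2
recomputes the full spectrogram of the trailing buffer each cycle —
simple and exactly equivalent to any incremental scheme.

Known limitation: classifiers trained on isolated windows have seen
zero-padded early frames, while streamed windows after warm-up feed real
history into those frames. The feature pipelines are identical (the
stream/batch parity test asserts equality to 1e-9 given the same
history), but the feature *distribution* shifts, and streamed decisions
on mid-stream windows are less confident than batch decisions on
isolated windows. Training on streamed features removes the mismatch.

## Problem sizes

Tests and the acceptance script use a 90-record corpus (≈ 72 train / 18
test windows), 100 random frames for the exact-identity checks, and
60 s records for streaming; these sizes make every property observable
while keeping the full suite fast on a single CPU. The corpus generator
scales to the full 612-record setting unchanged.
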