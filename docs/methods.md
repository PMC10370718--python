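# Methods

## Problem and pipeline

`chirpseg` segments single-channel audio recordings of animal sound events —
the motivating case is courtship recordings containing two stridulatory
chirp classes, a short "A" chirp (mean duration 0.14 s) and a longer "B"
chirp (mean 0.42 s), against a background class "X" — and attaches a
calibrated per-frame uncertainty to every label. The pipeline is:

1. **Frontend.** Hann-windowed FFT magnitude spectrogram, projected onto a
   Mel filterbank, high-pass filtered by dropping the lowest Mel rows, and
   log₂-compressed.
2. **Segmentation model.** A 1-D U-Net maps the spectrogram to per-frame
   class posteriors (softmax columns summing to one).
3. **Ensemble.** Several independently trained members are aggregated per
   frame and class by the median softmax (the prediction is the argmax of
   the median) and the inter-quartile range IQR = p75 − p25 of the member
   softmax values (the uncertainty score of the predicted class).
4. **Abstention.** Frames whose prediction IQR exceeds a threshold
   τ ∈ [0, 1] are relabeled background; sweeping τ traces a
   precision–recall curve.
5. **HMM smoothing.** The hard label sequence is decoded through a
   configurable discrete-emission HMM (Viterbi), removing implausible
   single-frame interruptions and transitions that the class structure
   forbids (A and B are never adjacent).
6. **Evaluation.** Maximal same-label runs form events; runs shorter than a
   minimum length are discarded; events are matched against truth regions
   to give event-wise precision/recall, alongside point-wise accuracy.

## Frontend conventions

* Framing uses a **no-padding convention**: only windows fully inside the
  signal are evaluated, so a signal of N samples yields
  `1 + floor((N − n_fft)/hop)` frames. This makes frame counts exactly
  reproducible and keeps the frame↔seconds map trivial
  (`seconds_per_frame = hop / sample_rate`).
* Defaults `n_fft = 1024`, `hop = 256`, `n_mels = 128` are round powers of
  two appropriate for 48 kHz recordings; `highpass_bins = 20` Mel rows are
  dropped to suppress low-frequency hum. All are configurable.
* The spectrogram is **magnitude** (not power) before the Mel filterbank;
  a `power` switch is provided.
* Log compression `log2(x + 1e-10)` is applied to the model input as well
  as for display: without it the magnitude dynamic range dominates
  training. The floor keeps silence finite. The flag is stored in each
  checkpoint so inference always reproduces the training preprocessing.
* A frame belongs to an annotated interval iff its **start time** lies in
  `[begin, end)` — half-open and unambiguous at boundaries.
* Multi-channel input is averaged to mono; the sample rate is always read
  from the WAV header.

## The 1-D U-Net

All convolutions run along the time axis; the frequency axis enters as
input channels, so every first-level kernel mixes the full frequency vector
of a frame at once. The encoder has `depth` levels with channel widths
`base_filters · 2^level` and 2× max pooling between levels; the decoder
mirrors it with nearest-neighbour upsampling and skip concatenation; a 1×1
convolution produces per-frame logits. Defaults (`depth = 4`,
`base_filters = 32`, kernel 3) give ≈ 0.66 M parameters. Time lengths are
padded (edge-replication) to a multiple of `2^(depth−1)` internally and
cropped on output, so any frame count is accepted and preserved.

The layers — convolution, pooling, upsampling, batch norm — and their
backward passes, cross-entropy losses and the Adam optimizer are
implemented in numpy inside the package (`chirpseg._nn`); gradients are
verified against central finite differences in the test suite.

**Batch normalization defaults off.** Training steps on one variable-length
clip at a time. Event clips and background clips have sharply different
per-channel statistics, so with batch norm the network learns to exploit
*per-clip* normalization; training loss goes to ~0 while eval-mode
(running-statistics) validation accuracy stalls around 0.85. Without batch
norm the same network reaches ≈ 1.0 validation accuracy within a few
epochs. BN remains available via `ModelConfig(use_batchnorm=True)` for
larger-batch training regimes.

A 2-D variant (3×3 convolutions over the time–frequency plane, head
averaged over frequency) is available through
`ModelConfig(two_dimensional=True)` for signals where localization in
frequency matters (e.g. bird song); it shares all training and ensembling
code.

**Binary mode** (two classes) replaces the softmax head by a single sigmoid
output p, expanded internally to the posterior (p, 1 − p) with row 0 the
probability of class index 0; the loss becomes binary cross-entropy.

## Training

Each member trains with Adam (default learning rate 1e-3) for a fixed
number of epochs (default 100; the scaled-down study below uses 20),
shuffling clip order per epoch. After every epoch the point-wise accuracy
on the validation split is recorded and the weight snapshot maximizing it
is kept. Examples are split 88 % / 12 % into train/validation. Everything
is deterministic given the seeds: member *i* of an ensemble uses
`base_seed + i` for initialization, shuffling and (for bootstrap members)
resampling.

Two ensemble strategies: **random_init** trains every member on the full
training set; **bootstrap** trains each member on a with-replacement
resample of the original size (expected unique fraction 1 − 1/e ≈ 63.2 %).
The resampling unit is one labeled clip, not a frame. Default ensemble:
10 random-init members (2 members are used in the scaled-down tests).

## Aggregation and uncertainty

Percentiles use **linear interpolation between order statistics** (the
numpy default). This matters for small ensembles: with two members the
median is the midpoint and the IQR is half the absolute difference; with
ten members of which eight agree exactly, both quartiles land on the
majority value and the IQR is 0. Argmax ties in the median are broken
toward the background class when a background index is supplied — a tie
never invents an event.

## Overlap-tile inference

Long recordings are evaluated in tiles of `tile_len` frames with
`tile_overlap` frames of context on each side; only the interior is kept,
and interiors abut exactly (half-open tiling). Context windows clamp to the
signal at its edges, so an input that fits within one tile is evaluated
identically to a direct forward pass. Because the network is purely
convolutional (with max pooling), outputs farther than one receptive field
(`1 + 4(k−1)(2^depth − 1)` frames; 121 at the defaults) from a tile seam are
bit-identical to single-pass evaluation. Two alignment constraints are
enforced: `tile_len` and `tile_overlap` must be multiples of
`2^(depth−1)` so the pooling grid has the same phase in every tile, and
`tile_len` must be at least the receptive field. Members may be passed as
checkpoint paths and are loaded one at a time, so a 30-member ensemble
never needs all models resident simultaneously.

## HMM smoothing

The smoother is a discrete-emission HMM whose states and observation
alphabet are the class labels; observations are the hard per-frame labels
after IQR abstention (applied in that fixed order). Decoding is Viterbi in
log space (structural zeros become −inf); ties break toward the lowest
state index at every step. The shipped chirp template uses sticky
self-transitions (0.99), structural zeros between A and B, and emission
self-probability 0.9 with the remainder on background; these numbers are
package defaults, chosen to bridge interruptions of up to roughly five
frames while leaving longer disagreements alone, and are fully
configurable. A two-state template ships for binary labeling. Smoothing
runs *before* the minimum-event-length filter: the HMM is part of
prediction, the length filter part of evaluation post-processing.
Baum–Welch learning and posterior decoding are out of scope.

## Event-wise evaluation

An event is a maximal run of identical non-background labels; runs shorter
than `min_event_frames` (default 10 frames ≈ 0.04 s at the 48 kHz / hop 192
frame rate of the motivating data) are discarded. A predicted event is a
**true positive** when at least `min_overlap` (default 0.5) of its frames
lie inside same-class truth regions — strict containment is too brittle
given that event boundaries in real annotations are partly guesswork — and
a false positive otherwise. Precision is predicted-side: TP/(TP+FP). A
truth event is **found** when any surviving same-class predicted event
overlaps it; recall is truth-side: found/(found+FN). Truth-side recall is
monotonically non-decreasing in the IQR threshold, because raising the
threshold only ever converts background frames to event frames (frames
never switch between non-background classes), so surviving runs only grow
or merge. Two predicted fragments inside one truth region count as two
TPs; the truth region counts as found once. Zero-denominator conventions:
precision is 1.0 with no predictions; recall is 0.0 when truth events
exist but none are found, 1.0 when there are none to find. Whole-percent
accuracy reporting truncates toward zero. For slice-level binary
classification, the slice label is the modal frame label with ties
resolving to the greatest label, which is the background class under the
package's A < B < X ordering.

## Synthetic scenes

The generator emulates the courtship recordings that motivated the tool,
with defaults frozen to the study conditions: 48 kHz sample rate, mean
durations 0.14 s (A) and 0.42 s (B) (standard deviation 18 % of the mean,
clipped to [0.4, 2]× the mean), same-class runs of 3–6 chirps with
0.05–0.15 s gaps inside a run and 0.35–0.7 s between runs, and no A–B
adjacency. The A chirp is a ~6 kHz carrier with tooth-strike amplitude
modulation (80–130 Hz) and an exponentially decaying tail; the B chirp is
a longer ~3.5 kHz carrier with slow (20–40 Hz) amplitude modulation.
Background is low-level 1/f-ish noise (one-pole filtered white noise)
plus a faint 120 Hz hum. Noise corruption draws zero-mean Gaussian samples
with σ = RMS_signal / 10^(SNR_dB/20), added pointwise.

What the generator does **not** emulate: reverberation, microphone
frequency response, amplitude variation across chirps, overlapping or
truncated events, non-stationary background (voices, door slams), and
annotator label noise at event boundaries. Passing tests therefore show
that the pipeline recovers events whose spectro-temporal signatures it has
seen under calibrated noise — not that it handles the full variability of
field recordings.

## Scaled-down study sizes

The self-contained end-to-end study (test suite and acceptance script)
uses: four 30 s training scenes with 12 events per class each (≈ 190
clips after adding 1:1 background slices), a reduced model (depth 3,
base_filters 16, ≈ 93 k parameters), a 64-band Mel frontend, two
random-init members, and 20 epochs; evaluation is a held-out 30 s scene
with 15 events per class, scored at 50 dB and 20 dB SNR with abstention
off (τ = 1) and HMM smoothing on. At 50 dB this recovers every event of
both classes (F1 = 1.0); at 20 dB performance collapses, reproducing the
qualitative noise-robustness shape of the full-scale system.

## Numerical choices

* Percentile interpolation: linear between order statistics (documented
  above; affects small ensembles).
* Viterbi in log space; tie-break toward the lowest state index; an
  all-(−inf) column raises an error naming the first impossible frame.
* HMM probability rows within 1e-6 of summing to one are renormalized;
  anything further off is a configuration error.
* Log-compression floor 1e-10; cross-entropy clamps probabilities at
  1e-300 to keep the loss finite.
* `split_train_val` rounds `fraction · N` to the nearest integer and keeps
  both sides non-empty.
* Weight initialization is He-normal scaled by fan-in; all randomness
  flows through `numpy.random.default_rng` seeded explicitly.

## Known limitations

* Training is single-example SGD in pure numpy: ample for the scaled-down
  studies here, but far slower than a GPU framework at full scale.
* Hyperparameter search is out of scope; defaults were fixed once.
* The discrete-emission HMM sees only hard labels; a posterior-emission
  (continuous) variant could use more of the ensemble's information.
* The right-whale-style binary mode is exercised on synthetic data and the
  published confusion counts only; the corpus itself is not packaged.
* Resampling between sample rates and non-WAV codecs are unsupported.
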