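# Methods

This note documents the modelling assumptions, parameter choices and
numerical details of the `emomusic` pipeline, and what its tests do and
do not establish.

## The mapping problem

The pipeline treats EEG→music as discrete sequence translation. Both
modalities are continuous, so each is first quantized against a learned
vocabulary: per-window feature vectors are clustered with DBSCAN, and a
window's token ID is the nearest cluster centroid (or `unk`). A
transformer encoder–decoder then learns the cross-modal mapping at the
token level, trained with a masked-audio infilling objective. The
working assumption is that a shared latent driver (the listener's
emotional trajectory) makes EEG tokens predictive of concurrent audio
tokens; the model's job is to recover that correspondence.

## Preprocessing

EEG is band-passed 4–45 Hz with a zero-phase order-4 Butterworth
(applied forward–backward, so the effective order is 8 and phase is
preserved), resampled to 128 Hz by polyphase filtering when needed, and
baseline-corrected by dropping the 3 s pre-stimulus segment and
subtracting its per-channel mean from the remainder. Audio is
peak-normalised per trial to remove level confounds before MFCC. Both
modalities are cut into non-overlapping half-open `[t, t+4)` s windows;
the trailing partial window is dropped. Windows are baseline-corrected
per trial, not per window.

## Features

* **EEG**: differential entropy per channel and band,
  `h = ½ ln(2πe σ²)` with `σ²` the variance of the band-filtered
  window — the Gaussian closed form, the standard estimator in EEG
  emotion work. Default bands θ 4–8, α 8–13, β 13–30, γ 30–45 Hz (all
  inside the analysis filter; the configuration validator enforces
  this). Zero-variance bands would give −∞ and are floored at −20 nats
  with a warning. One DE frame per 4 s window, flattened channel-major
  to a `32·4 = 128`-dimensional vector.
* **Audio**: 20 MFCCs from 25 ms Hamming frames at 10 ms hop
  (power spectrum → 40-filter mel bank → log with a 1e−10 floor →
  orthonormal DCT-II), mean-pooled to one 20-vector per 4 s window so
  both modalities tokenize at the same frame rate.

## Discretization

DBSCAN is implemented classically: core points have ≥ MinPts
neighbours within ε (self included); clusters are grown breadth-first
through core points' neighbourhoods; border points take the label of
the first cluster to reach them; the rest is noise. The test suite
checks label-partition equality against an independent reference
implementation on randomized instances.

Features are z-scored per dimension before clustering (DE and MFCC
scales differ by orders of magnitude); the dictionary stores the
scaling and re-applies it when encoding new frames. Defaults when ε and
MinPts are not given: `MinPts = max(4, min(2·dim, n/25))`, and ε from
the sorted MinPts-th nearest-neighbour distance curve — if its upper
tail jumps by more than 1.5× between consecutive values (the signature
of a noise tail) ε cuts just below the jump; otherwise the data is
treated as noise-free and ε = 1.2× the 95th percentile, which makes
nearly every point core and clusters the ε-connected components. Both
are overridable in configuration.

Dictionary entries are ordered by descending cluster size (ties: first
frame index) so IDs are stable across runs; each entry keeps the
centroid and its `R = 5` nearest members (interpretability metadata;
the model only uses centroids). Encoding maps a frame to the nearest
centroid, with ties resolved to the lowest ID, and to the reserved
`unk` ID when the nearest centroid is farther than `ε·noise_factor`
(default 1.5) — the model needs a total mapping, and `unk` doubles as a
learnable "none of the known timbres" class.

## Tokens

`token(pos) = content(pos) + √d_model·embed(ID(pos)) + PE(pos)`.

* The **content frontend** is a fixed random-weight 3-layer 1-D conv
  stack (kernels 7-5-3, decimating strides, GELU, mean pool, layer
  norm, linear projection to `d_model`), seeded and never trained —
  a cheap fixed featurizer in the random-projection tradition. The
  learnable part of the representation is carried by the ID embeddings.
* The **ID embedding** is a learned table of size `vocab+1` (the +1 is
  `unk`). It is scaled by `√d_model` at composition — the standard
  recipe — so its magnitude matches the unit-amplitude sinusoidal
  encoding; without this the positional encoding drowns the embeddings
  and even the identity (copy) task is unlearnable at small step
  budgets.
* The **positional encoding** is sinusoidal with the usual geometric
  wavelength ladder from 2π to 10000·2π; composition is additive
  (concatenation was rejected to keep `d_model` uniform across the
  three summands). The PE indexes *position*; the discrete *value*
  enters only through the embedding.

## Model

Pre-norm transformer. Encoder: `d_layers` blocks of multi-head
self-attention + feed-forward (GELU). Decoder: self-attention (not
causal — this is infilling, not autoregression), cross-attention over
the encoder output, feed-forward, and a linear head over the audio
vocabulary. Defaults: `d_model 64`, 4 heads, `d_ff 256`, `d_layers 12`
(the depth at which this architecture peaks; desk-scale experiments and
all tests use 2).

Two initialisation/wiring choices matter at small training budgets and
are part of the architecture:

* **Near-identity Q/K initialisation** — attention starts
  position-selective because the PE rows are nearly orthogonal, instead
  of spending gradient steps rediscovering positional routing.
* **Aligned-memory injection** — EEG and audio windows share one clock
  (window i of each modality covers the same 4 s), so the encoder
  output of frame i is added to the decoder input of frame i before the
  decoder blocks. Cross-attention is retained, letting the decoder
  consult the rest of the EEG sequence. Without this shortcut, the
  10-epoch training budget is consumed learning cross-attention
  routing and held-out accuracy roughly halves. The flag
  `aligned_memory=False` disables it.

**Masking.** `round(mask_ratio·L)` positions per sequence are drawn
without replacement (seeded per epoch and sequence); masked inputs
become `√d·mask_embedding + PE`. The default ratio is 0.5: with 15
tokens per trial and a handful of trials, the classic 15% ratio yields
~2 supervised positions per sequence per step and the masked loss never
leaves chance within the training budget; dense masking is what makes
desk-scale training work. The ratio is configurable.

**Loss.** `FL = (1−α)·FLm + α·FLu`, with both terms mean negative
log-likelihoods of the true token IDs (the masked/unmasked position
sets respectively). The NLL form (rather than a raw sum of
log-probabilities) makes the loss nonnegative and size-invariant.
`α = 0.2` keeps the objective mask-dominant while still anchoring
visible positions. Optimiser: Adam, lr 1e−3, sequence-level batches of
4, 10 epochs by default; all seeded, reproducible on one thread.
Prediction targets are audio dictionary IDs (classification over
`V = vocab+1`); Hits@k needs a ranked discrete candidate set, which
rules out regression on raw features. The continuous audio feature for
reconstruction is the centroid of the predicted ID.

## Evaluation

* **Split**: seeded shuffle of subject IDs, `round(0.2·n)` held out —
  no subject appears on both sides.
* **Hits@k**: `rank = 1 + #{j: p_j > p_ref} + #{j < ref: p_j = p_ref}`
  (ties resolved toward the lower index — deterministic and never
  flattering); `hits[k]` is the fraction of evaluated positions with
  rank ≤ k, reported for k ∈ {1, 3, 5, 10, 20}. Chance is `k/V`.
* Two framings are reported: **masked** (score the positions hidden at
  the training ratio; multiple independent mask draws can be pooled to
  grow n on short sequences) and **generation** (all positions masked —
  pure EEG→audio prediction).
* **Ablations**: clustering can be switched off per modality and
  replaced by per-dimension median binning (frame ID = frequency-ranked
  observed bin tuple, vocabulary capped at 64, rare tuples → `unk`) to
  isolate the dictionary's contribution; the backbone can be swapped
  for an LSTM or a token-wise MLP; depth is sweepable.
* **Reconstruction**: predicted IDs → centroid MFCCs → inverse DCT →
  exponential → mel-filterbank pseudo-inverse (clipped at 0) → envelope
  held constant over each token's window → 32 iterations of
  Griffin–Lim phase recovery (seeded random initial phase, 512-point
  FFT, 75% overlap). `unk` renders as silence.

## Synthetic study conditions

The generator emulates the structure of a DEAP-like corpus: per trial,
32-channel EEG at 128 Hz with 3 s baseline + 60 s stimulus, paired with
60 s of 8 kHz mono audio. A first-order Markov chain over K = 4
emotional states (stay probability 0.9, one state per 4 s frame) drives
both modalities: each state emits a band-limited EEG oscillation (one
canonical band per state — θ, α, β, γ — with fixed random channel
loadings) and a harmonic audio stack on a state-specific fundamental,
with the voicing alternating between even and odd windows (a two-bar
accompaniment pattern), giving 2K ≈ 8 distinct audio timbres. Additive
white Gaussian noise (default SD 0.3 against unit-amplitude templates)
exercises DBSCAN's noise handling. Templates are shared across
subjects; subjects differ by noise realisation and a ±5% gain, keeping
cross-subject generalisation well-posed. Defaults: 5 subjects × 3
trials — ~180 training window pairs after the 8:2 split, sized so the
full suite and the acceptance script run in minutes on one CPU.

What passing tests show: the pipeline's machinery is correct and the
EEG→audio token mapping is recoverable end to end when a shared latent
driver exists. What they do not show: performance on real EEG, where
the coupling is far weaker and nonstationary, artifacts abound,
template structure is absent, and inter-subject variability is much
larger than a gain factor. The generator has no musical syntax, no
video stimuli, and no physiological realism beyond band structure.

## Numerical details

* All floating point is float64; the autodiff engine is a minimal
  reverse-mode tensor graph (verified against finite differences).
* Filter edge effects are avoided in tests by trimming 2 s margins;
  degenerate inputs (silent windows, zero-variance bands, empty mask
  sets, empty dictionaries) raise typed errors or apply documented
  floors rather than producing NaNs.
* Seeds: one root seed fans out to per-stage streams via a hashed
  derivation, so any stage can be reproduced in isolation; every
  stochastic operation (latent chain, noise, masks, splits, init,
  Griffin–Lim phases) draws from such a stream.
* WAV I/O is 16-bit PCM; fixture round-trips are exact to one
  quantization step.

## Limitations

* Desk-scale only: the bundled numpy engine is single-threaded and
  suits hundreds of training steps; training at corpus scale would need
  a compiled framework and the full 12-layer default.
* The content frontend is fixed (random weights); a trainable frontend
  could recover information the dictionaries discard, at the cost of
  much longer training.
* `Hits@k` evaluates token ranking, not musical quality; no perceptual
  or music-theoretic evaluation is included.
* Dictionary sizes depend on the ε/MinPts heuristic; on data without
  clean cluster structure the heuristic can over- or under-split, and
  explicit parameters should be set instead.
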