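# Methods

## Problem and model

`wnetecg` reconstructs a continuous lead-II ECG waveform (mV) from a raw,
unaligned PPG signal recorded simultaneously at 125 Hz. The central
difficulty is the pulse arrival time (PAT): the PPG pulse onset of a beat
trails that beat's ECG R peak by up to 2 s, and the delay is
subject-specific. Earlier beat-by-beat approaches removed the PAT in
preprocessing by aligning PPG onsets to R peaks — which requires the very
ECG one is trying to avoid recording. Here, no alignment is ever
performed: the network sees long (8.192 s) windows and learns the
subject's PAT as part of the mapping.

The model is a **W-Net**: two cascaded 1-D U-blocks. Each U-block is a
fully convolutional encoder–decoder in the wave U-Net lineage — `depth`
encoder stages of (convolution, kernel 15 → batch normalization → leaky
ReLU, slope 0.1 → max-pool ÷2), a bottleneck stage, and `depth` decoder
stages of (upsample ×2 → skip concatenation with the matching-resolution
encoder output → convolution → batch normalization → leaky ReLU). Channel
widths double per level from `base_filters`. The second U-block receives
the first's output concatenated with the raw input on the channel axis,
and a final kernel-1 convolution with a bare leaky-ReLU activation (no
batch normalization, no saturating nonlinearity) produces the ECG. The
unbounded output matters physiologically: normal R waves can exceed 1 mV,
so a tanh-style output layer would clip them.

Training minimizes, per segment pair,

    Loss = mal + mse + (1 − |r|)

where `mal = max_i |ref_i − rec_i|` forces R-wave fidelity (the R wave is
brief, so pointwise-mean terms barely see it), `mse` is the mean squared
error, and `r` is the Pearson product-moment correlation. A batch is the
mean of per-segment losses; the max in `mal` is never taken across a
batch. The `|r|` (rather than `r`) is implemented exactly as published,
although it leaves anti-correlated reconstructions unpenalized; with the
other two terms active this never manifested as a failure mode.

## Pipeline

1. **Split first, window second.** Each recording is split at the
   `floor(0.8·T)` sample boundary into train/test. Windowing before
   splitting would leak up to `window − stride` = 768 test samples into
   training windows.
2. **Windowing.** 1024-sample windows, stride 256 (75% overlap); a
   trailing window shorter than 1024 samples is discarded. Indices are
   0-based half-open throughout.
3. **Normalization.** The PPG is z-scored with mean/SD computed from the
   training split only; the statistics are stored in the checkpoint
   sidecar and re-applied at inference. The ECG target stays in mV,
   unscaled, because the output layer is unbounded.
4. **Training.** Adam, initial learning rate 1e-3, decayed ×0.1 every 800
   optimizer steps (staircase on *steps*, i.e. mini-batch updates, not
   epochs), at most 500 epochs, batches of 128 segment pairs. These are
   the published values and the package defaults; the desk-scale profile
   used by the tests and the acceptance script is smaller (below). No
   early stopping: the epoch cap is the only criterion.
5. **Stitching.** Reconstructed windows are merged by iteratively dropping
   the trailing `window − stride` samples of the accumulated signal and
   appending the next full window: K windows yield `(K−1)·stride + window`
   samples, each earlier window contributing its first `stride` samples
   and the last window appearing in full. No overlap averaging.
6. **Evaluation.** RMSE (mV), Pearson's r, and a normalized DTW distance
   on the stitched test reconstruction, with the reference truncated to
   the stitched length. Experiment I scores directly; Experiment II first
   aligns the two signals at their cross-correlation peak (search window
   ±250 samples = ±2 s, the PAT bound). Metrics are computed per stitched
   record, not per window.

### DTW details

The local cost `d_ij = sqrt((ref_i − rec_j)² + (i − j)²)` mixes amplitude
(mV) and index (samples) inside one radical, exactly as published, and the
distance is reported in mV as the source does. The distance is the minimum
over monotone paths from (0, 0) to (N−1, N−1) with steps right/up/diagonal
— both endpoint cells included — divided by 2N for the normalized value.
Tie-breaks among equal-cost predecessors prefer diagonal, then vertical,
then horizontal, so the returned path is deterministic; ties do not affect
the distance. Two kernels exist: a full-matrix DP with backtracking
(`dtw`, O(N²) memory, used where the path is wanted) and a rolling
two-row DP (`dtw_distance`, O(N) memory) used on stitched records, where
N ≈ 15,000 would otherwise need a ~1 GB matrix. Unequal lengths are
rejected rather than padded, since the construction fixes both endpoints
of an N×N matrix.

## Numerical engine

No deep-learning framework is used: the layers (convolution, batch
normalization, leaky ReLU, max pooling, upsampling), their backward
passes, and Adam are implemented in numpy inside `wnetecg.nn`. Arrays are
channels-last `(batch, length, channels)` float64; the convolution is
evaluated as a single GEMM against all kernel taps followed by K shifted
adds, and its backward pass as two GEMMs plus a scatter — the same
arithmetic as im2col without the K-fold buffer. Every backward pass is
verified against central finite differences in the test suite (including
through batch-norm batch statistics), and the forward convolution against
`scipy.signal.correlate`. Weights use fan-in-scaled (He) initialization
with the leaky-ReLU gain and a user-set seed; batch norm uses eps 1e-5 and
momentum 0.9 for its running estimates, which make inference
deterministic and batch-size invariant. Training is exactly reproducible
given the seed on a single thread.

Design points that were genuinely open, and how they were fixed:

- **Depth / filter counts** are schematic in the source architecture
  diagram; they are config knobs (defaults depth 4, base 16 doubling per
  level; the parameter count is regression-tested so changes must be
  deliberate).
- **Upsampling** is nearest-neighbor ×2 by default (linear interpolation
  available via config): only the factor is prescribed.
- **Skip merges** are channel concatenations, the wave U-Net convention,
  not additions.
- **Padding** is symmetric zero padding so every stage preserves length —
  the stitching rule requires 1024-sample outputs.
- The learning-rate "decay by 0.1" is multiplicative (×0.1), matching
  standard learning-rate-attenuation practice.
- For a zero-variance signal the Pearson term is defined as r = 0 with a
  warning, so a degenerate batch cannot produce NaNs mid-training.

## Synthetic subjects

The generator (`wnetecg.synthetic`) emulates exactly the structure the
task depends on and nothing more:

- **ECG**: per beat, five Gaussian bumps — P (0.15 mV, 40 ms wide, 200 ms
  before R), Q (−0.10 mV), R (1.2 mV by default, 12 ms wide — deliberately
  above 1 mV to exercise the unbounded output), S (−0.15 mV), T (0.30 mV,
  250 ms after R) — plus white noise (SD 0.02 mV).
- **PPG**: per beat, a systolic hump (1.0 a.u., peaking 150 ms after the
  pulse onset) plus a smaller delayed diastolic hump (0.35 a.u., 450 ms),
  the onset lagging the R peak by a constant, subject-specific PAT
  (default 0.25 s; validated to lie strictly inside (0, 2) s); plus
  0.25 Hz sinusoidal baseline wander (0.1 a.u., random phase) and white
  noise (SD 0.02 a.u.).
- **Rhythm**: RR intervals from a truncated normal with mean 60/HR and SD
  propagated from the heart-rate SD, truncated to [0.33, 2.0] s (30–180
  bpm) so no window is degenerate.

Everything is seeded (independent child streams for rhythm, ECG noise and
PPG noise) and records are bit-reproducible. Ground-truth R-peak times,
onset times and the true PAT travel with the record as annotations.

A Gaussian-bump ECG was chosen over a dynamical-system ECG model because
the reconstruction method is agnostic to the generator and the bump
parameters are directly assertable in tests. What the generator does *not*
emulate — motion artifacts, skin-pigmentation effects, arrhythmia, PAT
drift within a record, sensor nonlinearities — bounds what passing tests
show: they demonstrate that the pipeline recovers a constant
subject-specific PAT and morphology from quasi-periodic data, not that it
handles pathological or artifact-laden recordings.

## Desk-scale profile and what the numbers mean

The tests and `scripts/acceptance.py` use one synthetic subject of 600 s
and a reduced W-Net (depth 3, base 8 → ~204k parameters), trained for 50
epochs with batch 32 (≈ 400 optimizer steps; the learning rate therefore
stays at 1e-3 throughout). On the held-out final 20% (14,848 stitched
samples) this attains r ≈ 0.98, RMSE ≈ 0.05 mV, normalized DTW ≈ 0.02 mV
and zero residual cross-correlation lag, with Experiment I and II reports
identical — the model has learned the 0.25-s PAT end-to-end, with no
alignment anywhere in the pipeline. These figures are properties of the
synthetic subject and the reduced profile, not reproductions of any
clinical-dataset result; the full-scale defaults (depth 4, base 16, 500
epochs, batch 128) remain available for real recordings read through the
`matrix3xT` adapter.

## Known limitations

- Subject-specific by construction: a model trained on one record does
  not transfer to another subject (different PAT and morphology).
- The `|r|` loss term tolerates anti-correlated outputs, as published.
- Full-matrix DTW is quadratic in memory; use `dtw_distance` for long
  signals.
- The equal-length requirement of the DTW implementation follows the
  N×N construction; comparing traces of different lengths requires
  truncation by the caller (the evaluation pipeline truncates the
  reference to the stitched length).
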