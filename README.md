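# wnetecg

Subject-specific reconstruction of continuous lead-II ECG waveforms (mV)
from raw photoplethysmography (PPG), with **no pulse-arrival-time
alignment anywhere in the pipeline**.

PPG is cheap to measure (smartwatches, finger probes) but clinicians
diagnose from the ECG. The two signals are linked beat-for-beat, yet the
PPG pulse onset trails the ECG R peak of the same beat by the pulse
arrival time (PAT) — up to 2 s, different for every subject. Methods that
first align PPG onsets to R peaks need the ECG they are trying to
synthesize. `wnetecg` instead trains a **W-Net** — two cascaded 1-D
U-blocks (encoder–decoder stacks of conv(k=15) → batch-norm →
LeakyReLU(0.1) with ×2 pooling/upsampling and skip concatenations; the
second U-block sees the first's output concatenated with the raw PPG; a
final kernel-1 convolution with a bare LeakyReLU emits unbounded mV) — on
long 1024-sample (8.192 s) windows of one subject's recording, so the
subject's PAT is learned by the model itself.

Training minimizes, per window pair,

```
Loss = mal + mse + (1 − |r|)
mal  = max_i |ECGref(i) − ECGrec(i)|      (R-wave fidelity)
mse  = (1/l) Σ_i (ECGref(i) − ECGrec(i))²
r    = Pearson correlation of the two windows
```

with Adam (lr 1e-3, ×0.1 every 800 steps, ≤500 epochs, batch 128 by
default). The first 80% of a recording trains the model; reconstructed
test windows (stride 256) are stitched by keeping each window's first 256
samples, and scored with RMSE (mV), Pearson's r, and a normalized dynamic
time warping distance

```
d_ij = sqrt((ECGref(i) − ECGrec(j))² + (i − j)²),   d̄ = DTW / 2N   (mV)
```

both directly (Experiment I) and after cross-correlation alignment
(Experiment II) — agreement between the two shows the reconstruction
carries no phase error.

A seeded synthetic generator (Gaussian-bump P/Q/R/S/T morphology with
R > 1 mV, two-hump PPG pulses trailing each R peak by a configurable PAT,
RR variability, noise and baseline wander) makes the whole pipeline
testable offline; the `matrix3xT` reader ingests the cuffless
blood-pressure dataset convention (rows PPG / ABP / ECG at 125 Hz, ABP
discarded) for real recordings. The network engine (layers, backward
passes, Adam) is implemented in numpy inside the package and is verified
against finite differences and `scipy.signal.correlate` in the tests.

## Worked example

Train a reduced subject-specific model on one synthetic subject (600 s at
125 Hz, heart rate 70 ± 3 bpm, PAT 0.25 s) and score the held-out final
20% — about 7 minutes on one CPU core:

```python
from wnetecg import (SyntheticSubjectConfig, WNetConfig, TrainConfig,
                     SegmentationConfig, generate_paired_record,
                     fit_subject, split_record, evaluate_record)

subject = SyntheticSubjectConfig(duration_s=600, hr_mean=70, hr_sd=3,
                                 pat_s=0.25, seed=1)
record = generate_paired_record(subject)
model, history = fit_subject(record,
                             WNetConfig(depth=3, base_filters=8),
                             TrainConfig(max_epochs=50, batch_size=32, seed=1))
_, test = split_record(record, SegmentationConfig())
print(evaluate_record(model, test, align=False))   # Experiment I
print(evaluate_record(model, test, align=True))    # Experiment II
```

Output:

```
EvalReport(rmse=0.04732364758099851, pearson_r=0.9795750900678374, dtw_norm=0.018805935696378274, xcorr_lag=0, record_id='synthetic/test')
EvalReport(rmse=0.04732364758099851, pearson_r=0.9795750900678374, dtw_norm=0.018805935696378274, xcorr_lag=0, record_id='synthetic/test')
```

Reading it: the reconstruction of 14,848 unseen samples correlates with
the reference ECG at r = 0.980 with 0.047 mV RMSE and a 0.019 mV
normalized DTW distance, and the residual cross-correlation lag is **0
samples** although training never aligned the signals — the model
absorbed the 0.25-s PAT. Experiments I and II coincide because there is
no phase error left to remove.

The same pipeline is available from the shell:

```sh
wnetecg simulate --config subject.yaml --out-dir data/
wnetecg train --record data/record.txt --config train.yaml --out-dir run/
wnetecg reconstruct --record data/record.txt --model run/model --out-dir run/
wnetecg evaluate --record data/record.txt --model run/model --out-dir run/
```

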