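# Methods

## The screening problem

Ambulatory and personal ECG devices produce far more signal than
cardiologists can read. The pipeline here frames triage as binary
classification of fixed 15-second windows of a single lead (MLII): a window
is *anomalous* if it contains at least one annotated beat, rhythm change or
signal-quality event from a 21-class anomalous vocabulary, and *normal*
only if every annotated beat in it is normal. No attempt is made to say
*which* anomaly is present; the operating goal is high anomalous recall —
a false alarm costs a wasted expert look, a miss costs an undiagnosed
patient.

## Data conventions

Recordings follow the MIT-BIH CSV export convention: integer ADC samples at
360 Hz, 11-bit quantisation over ±5 mV, so `mV = (adc − 1024) · 10 / 2048`
and 1024 is exactly 0 V. Signals are kept as raw ADC integers end to end;
no filtering, baseline correction or per-segment standardisation is applied
anywhere in the pipeline. Conversion to millivolts is a single explicit
affine map, applied (by default) only at the network input, where it is
harmless by construction: batch normalization after the first convolution
absorbs any affine rescaling, and a config flag feeds raw ADC instead.

Windows are half-open `[start, end)` in 0-based sample coordinates; an
annotation at sample `s` belongs to window `floor(s / 5400)`. Trailing
partial windows are dropped (the classifier input length is fixed; standard
30-minute records divide evenly, so the rule only matters for odd-length
input). Windows containing no annotations at all are labeled normal,
flagged `annotated=False`, counted in the run log, and can be excluded by
a switch; an annotation symbol outside the configured normal/anomalous
vocabulary is always a hard error, never silently normal.

## Splits

Two designs are supported. *Segment-wise* splits assign windows at random
(stratified by class) regardless of their source recording — the common
holdout practice, which lets windows of the same patient appear on both
sides. *Patient-wise* splits keep every window of a recording on one side,
so test patients are genuinely unseen; a leakage audit (also exposed as
`ecgscreen audit-split`) asserts the record sets are disjoint. Class
imbalance is handled by undersampling only: the training pool takes an
equal seeded draw per class and all surplus flows to the test pool, with an
optional helper to subsample the test pool to a fixed composition (e.g.
60/40). All draws are seeded and tie-broken by lexicographic
`(record_id, segment_index)` order, which makes split manifests
byte-identical across runs.

## Model

The classifier is four convolutional blocks — Conv1D → BatchNorm →
MaxPool → ReLU — then AvgPool(2) → Flatten → Dropout(0.6) →
Dense(2, L2 penalty 0.001, softmax). Convolutions are *valid* (no padding)
with output length `floor((L − k)/s) + 1`; pooling is non-overlapping with
output length `floor(L / p)`. Both conventions are forced by the published
per-layer output-shape column, which the shape calculus reproduces exactly:

    (5400;1) → conv(80, stride 8) (666;128) → pool (166;128)
    → conv(4) (163;256) → pool (40;256) → conv(4) (37;256) → pool (9;256)
    → conv(2) (8;512) → pool (2;512) → avg (1;512) → 512 → 2

One documented inconsistency: the published parameter listing says the
fourth convolution has kernel size 4, but its own output shapes
(9;256)→(8;512) admit only kernel 2 under valid convolution. This package
follows the shape column (kernel 2); the alternative (kernel 4) yields
(6;512)→(1;512) and an identical parameter count elsewhere.

The engine is written in NumPy (float32, channels-last, im2col + BLAS
matmuls) with exact backpropagation, verified against central finite
differences in the test suite. Choices the architecture description leaves
open, fixed here and recorded in every run manifest:

| choice | value | note |
|---|---|---|
| optimizer | Adam, lr 1e−3, β = (0.9, 0.999) | least-surprising default for a softmax head |
| loss | categorical cross-entropy + L2 | L2 applies to the dense weights only |
| batch size | 32 | |
| epochs | exactly as configured, no early stopping | default 200; scaled runs use fewer |
| weight init | Glorot-uniform, seeded; zero bias | |
| batch norm | learned affine, ε = 1e−3, running-stat momentum 0.9 | momentum chosen so inference statistics converge within short trainings |
| class order | (normal, anomalous); exact ties → anomalous | recall-first screening posture |

Training is seeded end to end (init, shuffling, dropout); two runs with the
same seeds produce identical learning curves in single-threaded execution.
Ten-fold cross-validation builds stratified folds in which every pool id is
validated exactly once, and reports per-fold accuracy/loss/anomalous recall
with mean and population standard deviation.

## Metrics and patient-level aggregation

Per-class accuracy, precision, recall and F1 are computed from the 2×2
confusion matrix treating each class as positive in turn; a zero
denominator reports the metric as undefined (`None`), never as 0. Reported
values are percentages rounded half-up to 2 decimals; full precision is
retained internally.

A recording is *flagged* when at least one of its segments is predicted
anomalous, and *truly anomalous* when at least one segment truly is;
patient-level recall is flagged-and-true over true. Because the flag is an
existential relaxation *per record*, patient-level recall always dominates
the record-averaged anomalous segment recall. It does **not** in general
dominate the segment-weighted overall anomalous recall: that quantity
weights records by their anomalous-segment counts, and when misses
concentrate in records with few anomalous segments the two means can order
either way. (A counterexample: one record with 4/4 anomalous segments
detected, another whose single anomalous segment is missed — segment recall
80%, patient recall 50%.) The property test asserts the correct,
per-record form.

A second documented inconsistency in the published tables: the first
experiment's matrix (583/57/52/374) yields overall accuracy 957/1066 =
89.77%, not the printed 89.51%; and its anomalous precision 374/431 =
86.7749% prints as 86.77 at two decimals, not the printed 86.78. All other
printed cells of both experiments' tables reproduce exactly under half-up
rounding. Tests assert the matrix-consistent values.

## The simulator

The generator exists to make every stage testable with controllable ground
truth, not to produce physiologically validated waveforms. Each beat is a
sum of five Gaussian bumps (P, Q, R, S, T) with amplitudes giving a normal
beat ≈ 1.2 mV peak-to-peak; beats are placed at a jittered mean RR of
0.8 s (default jitter sd 0.04 s) and annotated at their R-peak sample.
White noise (default sd 0.02 mV) is added, and the millivolt trace is
quantised to the 11-bit ADC convention with clipping at the rails.

Anomalies fire per beat as independent Bernoulli draws from a random stream
separate from the signal-noise stream, so event placement and noise are
independently reproducible. Built-in morphologies: PVC (`V`) — premature by
a factor 0.6 of the RR interval, widened, inverted, large, followed by a
compensatory pause; atrial premature beat (`A`) — premature with normal
morphology; artifact (`|`) — a windowed broadband burst. Ground-truth
window labels are derived by applying the labeling rule to the true event
list, and a round-trip test checks that labels re-derived from the written
CSV files through the real segmentation path match the generator's truth
manifest exactly.

What the simulator does *not* model — baseline wander, respiration,
electrode motion, inter-patient morphology variation, rhythm-level
anomalies that alter timing without altering beat shape — bounds what
passing tests show: they demonstrate that the pipeline is correct and that
the classifier learns a cleanly separable distinction; they say nothing
about accuracy on clinical recordings, which additionally requires the
database-download harness.

## Problem sizes

The verification runs use scaled problem sizes chosen to exercise the
full-size model: the learnability benchmark trains the complete
5400-sample architecture on 400 synthetic segments (70/30 split) for 20
epochs and requires ≥ 95% validation accuracy — the run converges to 100%
within a few epochs; the patient-level check evaluates the trained model on
eight held-out 2-minute simulated recordings (half clean, half with PVCs).
Unit and property tests use a structurally identical two-block
configuration on 120-sample inputs so the whole suite stays fast.

## Known limitations

* No QRS detection or beat-centred analysis: a window is the unit of
  decision, so a single anomalous beat marks all 15 s.
* The NumPy engine targets CPU-scale experiments; there is no GPU path and
  checkpoints (pickled models) are not portable across package versions.
* Softmax + cross-entropy on two classes is an over-parametrised logistic
  regression head; it is kept for fidelity to the published head layout.
* Clinical-database results depend on which records enter the training
  side of the patient-wise split; the published choice of 28 training
  records is not documented, so the package takes a user-supplied list or
  a seeded random choice.
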