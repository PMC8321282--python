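# ecgscreen

Binary screening of single-lead ECG recordings for personal heart-health
monitoring. The package answers one triage question per 15-second stretch of
signal — *does anything here warrant a cardiologist's eye?* — so that only
suspicious recordings from wearable or Holter devices need expert review.

It implements the full pipeline around a four-block 1D convolutional
classifier:

* **I/O** for MIT-BIH-style CSV exports: a sample table (integer ADC values,
  360 Hz, 11-bit over ±5 mV with 1024 = 0 V) and an annotation table
  (timestamp, sample index, beat/rhythm symbol), with explicit ADC↔mV
  conversion and MLII lead selection;
* **segmentation** into non-overlapping 15-s windows of 5400 samples, each
  labeled *anomalous* as soon as one of its annotated beats carries any of
  21 anomalous classes (beat, rhythm and signal-quality alike), *normal*
  only when every beat is normal;
* **dataset construction**: class balancing by undersampling, stratified
  segment-wise splits, record-disjoint patient-wise splits with a leakage
  audit, and stratified k-fold plans;
* **the classifier**: four blocks of Conv1D → BatchNorm → MaxPool → ReLU
  (valid convolution, non-overlapping pooling) followed by
  AvgPool → Flatten → Dropout(0.6) → Dense(2, L2 = 0.001, softmax),
  trained with Adam on categorical cross-entropy — implemented in NumPy
  with gradient-checked backpropagation;
* **evaluation**: 2×2 confusion matrices with per-class
  accuracy/precision/recall/F1,

  `Accuracy = (TP+TN)/(TP+TN+FP+FN)`, `Precision = TP/(TP+FP)`,
  `Recall = TP/(TP+FN)`, `F1 = 2TP/(2TP+FP+FN)`,

  plus a patient-level roll-up that flags a whole recording as soon as one
  of its segments is predicted anomalous;
* **a synthetic annotated-ECG simulator** (Gaussian PQRST morphology,
  per-beat anomaly rates, R-peak-anchored annotations) so the entire
  pipeline is testable without downloading clinical databases.

## Worked example

Simulate four 5-minute recordings (two clean, two with premature
ventricular contractions), segment them, build a patient-wise split, train
for 10 epochs and evaluate on the held-out patients:

```sh
ecgscreen simulate --duration 300 --pvc-rate 0.3 --records 4 --seed 11 --out sim
for r in sim00 sim01 sim02 sim03; do
  ecgscreen segment --signal sim/$r.csv --annotations sim/${r}_ann.csv \
      --out ${r}_segments.csv
done
ecgscreen build-dataset --segments sim00_segments.csv --segments sim01_segments.csv \
    --segments sim02_segments.csv --segments sim03_segments.csv \
    --mode patientwise --train-records sim00,sim02 --out manifest.csv
ecgscreen train --manifest manifest.csv --segments sim00_segments.csv \
    --segments sim01_segments.csv --segments sim02_segments.csv \
    --segments sim03_segments.csv --epochs 10 --seed 1 --out run
ecgscreen evaluate --model run --manifest manifest.csv \
    --segments sim00_segments.csv --segments sim01_segments.csv \
    --segments sim02_segments.csv --segments sim03_segments.csv \
    --partition test --report report.json
```

This prints, per step:

```
20 segments (0 anomalous) -> sim00_segments.csv
20 segments (20 anomalous) -> sim02_segments.csv
manifest with 80 rows -> manifest.csv
final val accuracy 91.67% -> run
overall accuracy 97.5% -> report.json
```

and `report.json` contains the segment-level confusion matrix
`[[20, 0], [1, 19]]` (one anomalous segment of the held-out patient was
missed), per-class metrics (anomalous recall 95.0%), and the patient-level
roll-up: the one truly anomalous held-out recording was flagged
(`"recall": 100.0`) with no false-alarm recordings — the point of the
existential flagging rule is exactly that a missed segment rarely means a
missed patient.

Any printed metric table can be recomputed from raw counts:

```sh
ecgscreen metrics-from-confusion --tn-nn 241 --tn-na 194 --tn-an 77 --tn-aa 1288
```

gives overall accuracy 84.94%, anomalous recall 94.36%, normal F1 64.01%.
`ecgscreen model-summary` prints the architecture's per-layer shape trace,
starting `Input Shape (5400;1)`, `Conv1D (666;128)`, …, `Dense (2)`.

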