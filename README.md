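# sleepseg

Per-sample segmentation of **sleep arousals** in multi-channel
polysomnograms with a deep 1D encoder–decoder network.

Sleep arousals — brief intrusions of wakefulness into sleep — are scored
manually from overnight polysomnographic recordings (13 channels: six EEG
derivations F3-M2 … O2-M1, one EOG, chin/abdominal/chest EMG, airflow,
SaO₂, ECG, sampled at 200 Hz), which takes hours per record.  `sleepseg`
implements an automatic pipeline for this task: a 1D U-Net translates a
whole record *x* ∈ ℝ^(13×T) into one arousal probability ŷᵢ ∈ [0, 1] per
5-ms sample, trained against expert labels yᵢ ∈ {−1, 0, 1} (arousal = 1,
sleep = 0, non-scored wake/apnea regions = −1, excluded from both loss and
scoring).

The pipeline's pieces, each a module here:

- **Data model & IO** (`sleepseg.records`) — canonical 13-channel records,
  an HDF5 container, PhysioNet-2018-style WFDB `.mat`/`.hea` and EDF
  read-only adapters, flat-text `.vec` probability files, zero-center
  padding, block-average resolution reduction, 60/15/25 dataset splits.
- **Normalization** (`sleepseg.preprocess`) — per-channel Gaussian
  normalization x′ = (x − x̄)/s, and rank-based **quantile normalization**
  onto a reference built by averaging the sorted training records, which
  removes monotone per-record distortions (instrument gain, offset)
  exactly.
- **Augmentation** (`sleepseg.augment`) — random permutation of the six
  interchangeable EEG channels and coin-flip ABD/chest EMG swapping (chin
  EMG excluded), record-level magnitude jitter ×U(0.90, 1.15), optional
  time stretching (off by default).
- **Model** (`sleepseg.nn`) — the 1D U-Net: encoder "ccp" blocks
  (conv–conv–pool), a bottleneck, decoder "ccu" blocks (upscale–concat–
  conv–conv), kernel-7 same-padded convolutions, batch normalization,
  ReLU, sigmoid output.  The full-scale configuration takes a 2²³-sample
  input down to a 256-sample bottleneck while channels grow 13 → 480, for
  35 convolution layers in total.  Forward, backward and Adam are
  implemented directly on numpy arrays.
- **Training** (`sleepseg.training`) — masked cross-entropy (default) and
  Sørensen–dice losses, Adam with per-update learning-rate decay, best-
  validation-epoch selection, and multi-resolution ensembling (coarse
  tracks upsampled by repetition, averaged pointwise).
- **Scoring** (`sleepseg.metrics`) — the challenge-style **gross** AUPRC
  and AUROC: all scored samples of all records pooled (longer records weigh
  more), precision/recall evaluated on the fixed cutoff grid t_j = j/1000,
  AUPRC = Σ_j P_j (R_j − R_{j+1}).  A constant predictor scores exactly the
  pooled arousal prevalence, which is reported as the baseline.
- **Synthetic data** (`sleepseg.synth`) — a seeded generator of records
  with planted arousal signatures (EMG amplitude bursts, EEG high-band
  power shifts), non-scored wake edges and apnea blocks, overdispersed
  per-record event counts and per-record gain jitter, so the entire
  pipeline is testable at desk scale without downloads.

## Worked example

```python
import json
from sleepseg import ArousalSegmenter, SynthConfig, generate_dataset

items, manifest = generate_dataset(
    SynthConfig(n_records=120, record_length=2**14, seed=42))
records = [r for r, _, _ in items]
labels = [l for _, l, _ in items]

model = ArousalSegmenter(resolution="eighth", input_length=2048,
                         epochs=10, random_state=0)
model.fit(records[:100], labels[:100])
report = model.evaluate(records[100:], labels[100:])
print(json.dumps(report.to_dict(), indent=2))
```

prints

```json
{
  "gross_auprc": 0.9156284458386731,
  "gross_auroc": 0.9858989509887379,
  "prevalence": 0.08658049836579547,
  "n_records": 20
}
```

The held-out gross AUPRC of 0.92 against a prevalence baseline of 0.087
shows the network has learned the planted arousal signature rather than the
base rate; `report.per_record` holds per-record AUPRC/AUROC, dice and
Jaccard (records without any arousal get an absent, not zero, AUPRC).

The same pipeline is available from the shell:

```sh
sleepseg synth --n 60 --length 8192 --seed 7 --out data/
sleepseg train --data data/ --resolution eighth --input-length 1024 \
         --epochs 5 --seed 1 --out model/
sleepseg predict --model model/ --data data/ --out preds/
sleepseg evaluate --labels data/ --preds preds/
sleepseg visualize --record data/syn-0000.h5 --preds preds/syn-0000.vec \
         --out tracks.png
```

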