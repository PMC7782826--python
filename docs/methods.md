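# Methods

## Problem and data model

A polysomnogram is a 13-channel overnight recording (six EEG derivations,
one EOG, chin/abdominal/chest EMG, airflow, SaO₂, ECG) sampled at 200 Hz.
Each sample carries a label in {−1, 0, 1}: arousal (1), sleep (0), or
non-scored (−1; wakefulness at the record edges and apnea/hypopnea arousal
regions).  The task is per-sample binary segmentation: one arousal
probability per 5-ms sample.  Non-scored samples are excluded from the
training loss as well as from all metrics — the signal there does not mean
"not arousal", and training on it would teach falsehoods.  Records are kept
whole: the network sees the entire recording at once so that context from
seconds to hours can inform each sample.

## Normalization

Two per-channel schemes are implemented.  *Gaussian*: x′ = (x − x̄)/s with
the sample standard deviation (N−1 denominator); constant channels return
zeros with a warning.  *Quantile*: each channel is mapped by rank onto a
reference distribution built by averaging the sorted training records.
Because records differ in length by hours, rank replacement is generalized
to a fixed evenly spaced quantile grid (default 10,001 points) with linear
interpolation on both sides of the mapping; ties receive their average rank
before grid mapping.  The rank mapping depends only on the order of values,
so any strictly monotone per-record distortion — instrument gain, offset —
is removed exactly; this is the batch-effect-removal property that makes
quantile normalization the default.  Normalization happens before padding,
so padded zeros never enter the statistics.

## Architecture

The model is a 1D U-Net.  Encoder: n levels of "ccp" blocks, each
conv→batchnorm→ReLU twice followed by pooling (max by default, average
available).  Bottleneck: two further conv→batchnorm→ReLU stages.  Decoder:
n "ccu" blocks — parameter-free nearest-neighbor upscaling by the mirrored
pooling factor, concatenation with the same-scale encoder output along the
channel axis, then two conv→batchnorm→ReLU stages.  A final width-1
convolution plus sigmoid produces one probability per input sample.  All
convolutions are same-padded (kernel 7 by default), so temporal lengths are
controlled purely by pooling/upscaling, and the output length always equals
the input length.

The full-scale configuration uses 8 levels with pooling sizes
[4,4,4,4,4,4,4,2] (product 2¹⁵), taking a 2²³ = 8,388,608-sample input to a
256-sample bottleneck, with channels growing 13 → 480.  The convolution
count is 2·8 + 2 + 2·8 + 1 = 35, the output projection included.  The
half- and eighth-resolution variants (2²² and 2²⁰ inputs, produced by
averaging every 2 or 8 successive time points) redistribute the pooling
factors ([4×6,2,2] and [4×4,2×4]) so the bottleneck stays at 256 samples
and the layer count at 35.  The per-level channel widths are a free choice
constrained only by the 13 → 480 endpoints and monotonicity; the default
schedule is [30, 60, 90, 120, 180, 240, 360, 480].  Whether alternative
block decompositions could also sum to 35 layers is under-determined; this
one satisfies every stated constraint simultaneously and is
config-overridable.

The network, its backward pass and the Adam optimizer are implemented
directly on numpy arrays (im2col convolutions, explicit batch-norm
backprop); gradients are verified against finite differences in the test
suite.  Batch-norm running statistics (EMA weight 0.1) are frozen at
inference time, making prediction deterministic.

## Training

Batch size is 1 — one whole record per update; with full-length records a
single record already provides a well-estimated batch-norm statistic, and
larger batches of multi-million-sample inputs would be memory-prohibitive.
Records are zero-center-padded to the configured input length (offset
⌊(target − n)/2⌋, left-biased), with padded labels −1.  Label tracks at
reduced resolutions are block-voted with precedence 1 > −1 > 0, preserving
the rare arousal class.  Per epoch the training records are visited in a
fresh random order with fresh augmentation draws; validation loss is
computed augmentation-free in inference mode, and the weights of the
minimum-validation-loss epoch are returned.

The default loss is masked cross-entropy, with ŷ clipped to
[1e−7, 1 − 1e−7]; a soft dice loss and an equal-weight combination are
available.  The dice coefficient is implemented in two conventions:
`standard` (factor 2, maximum 1) used for evaluation, and `as_printed`
(no factor 2, maximum 0.5 for perfect binary agreement) for comparability
with the training-loss formula.  Adam uses lr 1e−4 with per-update decay
lr_t = lr/(1 + 1e−5·t) at full scale — "decay rate" is interpreted as the
step-wise learning-rate decay of the era's frameworks, not weight decay
(config-overridable).  The desk-scale default is lr 1e−3: with only ~2k
updates in a scaled run, a proportionally larger step is needed to traverse
the same loss landscape.

Augmentation operates on normalized signals, per record per epoch: a
uniform random permutation of the six EEG rows (full permutation rather
than pairwise swaps — the channels are declared interchangeable, so the
full symmetric group maximizes diversity), ABD/chest swapped with
probability 1/2, chin EMG and EOG excluded; one magnitude scalar
~U(0.90, 1.15) per record (a wider U(0.80, 1.25) variant is available);
time stretching (linear signal interpolation, nearest-neighbor labels)
ships but defaults off, as it degrades rather than helps.

Predictions from models at different resolutions are ensembled by
upsampling each coarse track to the native rate by value repetition,
averaging pointwise with equal weights, and cropping to the pre-padding
record extent.

## Scoring

The gross (overall) AUPRC and AUROC pool all scored samples of all records
before thresholding, so longer records contribute proportionally more.
Thresholds are the fixed grid t_j = j/1000 with "≥ cutoff" inclusion;
AUPRC = Σ_j P_j (R_j − R_{j+1}) with R_1001 := 0 and P_j := 1 when nothing
exceeds the cutoff (extending the PR curve to recall 0); AUROC uses the
trapezoid rule on the same grid with (TPR, FPR)_1001 := (0, 0) — a
rectangle rule would score a constant predictor 1, which is absurd.  The
precision denominator is the standard TP + FP.  A constant predictor's
gross AUPRC equals the pooled prevalence exactly, so the prevalence is
reported as the baseline.  Per-record metrics are computed independently;
records without arousal samples get an absent (NaN), not zero, AUPRC.

Against an oracle that sweeps every distinct predicted value as a
threshold, the fixed grid agrees exactly when predictions lie on the grid;
for continuous predictions the residual is discretization of order one grid
step, which can reach a few 1e−3 for sparse instances where a positive
sits just above a cutoff.  The equivalence tests therefore draw
predictions on the scoring grid (isolating implementation from
discretization), and rank-invariance is asserted on dense instances where
the discretization bound holds.

## Synthetic data

The generator emulates the statistical structure of overnight recordings at
desk scale (2¹⁴-sample records by default, lengths jittered to 85–100% of
the target): band-limited noise EEG/EOG, amplitude-modulated noise EMG, a
slow airflow oscillation, near-constant drifting SaO₂, an impulse-train
ECG.  Arousal events occupy ~7% of scored time, with log-uniform durations
(100–600 samples) and gamma-Poisson overdispersed per-record counts
(capped at 40% occupancy so placement without overlap always succeeds);
wake edges (5% each end) and Poisson apnea blocks are labeled −1.  During
events the abdominal and chest EMG are amplified ×3 and the EEG high band
×2 — identically across each interchangeable group, so channel swapping is
label-neutral by construction.  A per-record gain ~U(0.5, 2.0) gives
quantile normalization a batch effect to remove.

What passing tests on this data show: the pipeline can recover a planted,
physiologically plausible arousal signature from realistic label sparsity
and non-scored structure, end to end.  What they do not show: performance
on real polysomnograms, whose arousal correlates are far subtler and
noisier, whose inter-individual variability is not two gain parameters,
and whose annotations carry scorer disagreement.  Headline numbers on real
data require the full-scale network and the public challenge corpora.

## Desk-scale experiment sizes

The learnability experiment trains the eighth-resolution scaled
configuration — three levels, pooling [4,4,4], channels [12,16,24], ~43k
parameters, 2048-sample inputs — for 10 epochs on 200 synthetic records
(15% held out internally for epoch selection) and evaluates on 50 further
records.  These sizes were chosen as the smallest at which the gross
metrics are stable across seeds; all randomness flows from a single fixed
seed, so runs are reproducible.

## Known limitations

- EDF reading requires the optional `mne` dependency; EDF+ annotations and
  montage re-referencing are out of scope.
- The WFDB adapter covers the PhysioNet-2018 `.mat`/`.hea` dialect only.
- No bootstrap confidence intervals and no per-event (as opposed to
  per-sample) detection scoring.
- The sleep-stage track is a coarse blocked sequence for visualization;
  no stage-dynamics modeling, and no apnea physiology.
- Single-process training only; full-scale (2²³-input) training is
  supported by the code but is a GPU-cluster-sized computation elsewhere,
  not something to run here.
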