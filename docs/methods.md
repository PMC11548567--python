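# Methods

## Problem and pipeline

`lungsound` classifies single respiratory cycles — one inhalation–exhalation
period of a chest-wall sound recording — into four clinically standard
categories: **normal**, **crackle** (discontinuous adventitious sound),
**wheeze** (continuous adventitious sound), and **both** (crackles and
wheezes in the same cycle).  The pipeline is:

1. **Ingestion** (`icbhi_io`): recordings arrive as WAV files with a
   same-stem annotation text file giving, per cycle, its time span and two
   binary flags (crackle present, wheeze present).  The four flag pairs map
   bijectively onto the four classes.
2. **Preprocessing** (`preprocess`): resample to 4 kHz (the adventitious
   band lies below 2 kHz, so Nyquist is respected), cut out annotated
   cycles, truncate cycles longer than 2.7 s to their initial 2.7 s, then
   crop or zero-pad to the model's fixed 8000-sample input (2.0 s), and
   peak-normalize each clip to unit amplitude.
3. **Balancing** (`smote`): SMOTE oversampling of minority classes in the
   training partition only (see below).
4. **Classification** (`arch`, `nn`, `model`): a 1D convolutional network on
   the raw waveform.
5. **Tuning and evaluation** (`tune`, `evaluate`): exhaustive grid search
   scored by stratified k-fold cross-validation; reports carry a 4×4
   confusion matrix, per-class precision/recall/F1, and macro-averaged
   one-vs-rest sensitivity/specificity.

## Fixed-length clip construction

Two length parameters coexist deliberately: the cycle truncation (2.7 s,
the mean cycle duration, applied first) and the model input length
(8000 samples = 2.0 s at 4 kHz, applied second as crop-or-pad).  Keeping
both reproduces the reference layer shapes exactly while honouring the
truncation rule.  Short cycles are zero-padded by default; periodic wrap
padding is available (`pad_mode="wrap"`).  Sample index mapping uses
`round(t * rate)` with half-open `[start, end)` spans so adjacent cycles
never share a boundary sample.

## The network

The reference architecture (`arch.default_arch`) is four
conv–maxpool–dropout blocks over the raw waveform — filters 8/16/32/64,
valid stride-1 convolutions, pool width 3 — then flatten and a
256/128/64-unit dense funnel into a 4-way softmax.  The kernel widths
(13, 11, 9, 7) and the pool width 3 are derived constants: they are the
unique solutions of the reference per-layer output lengths under valid
convolution (`L - k + 1`) and floor-division pooling (`⌊L / p⌋`), e.g.
`8000 - k + 1 = 7988 ⇒ k = 13`.  Hidden activations are ReLU, the head is
softmax, dropout defaults to 0.3 everywhere.  Total trainable parameters:
1,618,724, the sum of the per-layer counts
(112, 1424, 4640, 14400, 1556736, 32896, 8256, 260).

`arch.summarize` computes every output shape and parameter count by pure
arithmetic; `nn.Network` allocates the weights and counts parameters by
summing array sizes.  The two counts are independent routes and are
cross-checked in the test suite, including property-based tests over random
architectures.

The training engine (`lungsound.nn`) is a self-contained NumPy
implementation — im2col-style convolutions via stride tricks, manual
backpropagation verified against finite differences, inverted dropout, Adam
and SGD optimizers, float32 throughout.  Training defaults: Adam, learning
rate 1e-3 (the centre of the tuning grid's {1e-4, 1e-3, 1e-2}), batch 32,
categorical cross-entropy.  An optional step learning-rate decay
(`lr_decay`, off by default) and focal loss
(−(1 − p)^γ · log p, `loss="focal"`) are available; focal loss is the
alternative treatment of class imbalance to SMOTE, with γ = 2 by default.
Determinism: weight initialization, dropout masks and shuffling all derive
from the configured seed, so identical data + config + seed reproduce the
training history exactly.

**Prediction rule.**  Fitted models predict by Monte-Carlo dropout: the
softmax outputs of 10 stochastic forward passes (dropout active, masks from
a seeded stream) are averaged, so prediction is still deterministic.  With
dropout layers between every block, a single dropout-free pass is not the
expectation of the training-time network — the max-pool and ReLU
nonlinearities make the eval-time activations systematically larger, which
in practice inflates transient-evidence channels and biases predictions
toward the crackle-bearing classes.  Evaluating the network in the regime
it was trained in removes that bias; on the synthetic task it is worth
several points of validation accuracy.  The per-epoch validation history
recorded during training still uses the cheap single-pass forward (it is a
progress signal, not the final report), and `mc_samples=0` recovers the
plain pass.

## SMOTE

For each minority-class sample x_i, one of its k = 5 nearest same-class
neighbours x_j (Euclidean distance on the fixed-length waveform vectors,
ties broken toward the lower index) is selected and a synthetic sample

    x_new = x_i + r · (x_j − x_i),   r ~ Uniform[0, 1]

is added, cycling through the minority rows in order until every class
reaches the majority count.  Every synthetic row is therefore a convex
combination of two same-class originals, which the tests verify
coordinate-wise.  Balancing is applied strictly to training data — inside
cross-validation, to each fold's training split — and held-out partitions
are verified byte-identical before and after.

## Grid search and cross-validation

The tuning grid is {32, 64, 128} first-layer filters × {3, 5, 7} kernel
width × {0.2, 0.3, 0.4} dropout × {64, 128, 256} dense units ×
{1e-4, 1e-3, 1e-2} learning rate = 243 configurations.  Because the grid
gives one value per knob while the network has four conv blocks and three
dense layers, the knobs are treated as first-layer base values with the
reference progression applied (filters double and kernels shrink by 2 per
block; dense units halve per layer).  Configurations whose shapes collapse
are skipped and logged.  Scoring is mean validation accuracy over
stratified folds (macro-F1 is computable from the same reports); ranking
ties break toward fewer parameters, then grid order.  Stratified folds come
from scikit-learn's `StratifiedKFold` (shuffled, seeded), guaranteeing
per-class fold counts within one.  The protocol used throughout is:
cross-validation and tuning on the 70 % training partition, with the 30 %
holdout reserved for the final report.

## Evaluation conventions

Confusion rows are true classes, columns predictions.  Precision is
diagonal over column sum, recall diagonal over row sum, F1 their harmonic
mean with 0/0 defined as 0 (logged).  Multiclass sensitivity equals macro
recall; specificity is one-vs-rest true-negative rate, macro-averaged.
Micro-averaged recall equals accuracy on single-label data — an identity
the tests exercise as an internal consistency check.

## Synthetic respiratory sounds

The generator (`synth`) emulates the four classes at the signal level, not
the physiology:

- **Breath base**: Gaussian noise low-passed at 500 Hz under a
  raised-cosine inspiration/expiration envelope (fractions 0.45/0.55), with
  a −40 dB broadband noise floor.  Cycle durations are uniform on 1–4 s.
- **Crackles**: 5–14 exponentially damped sinusoid bursts per cycle,
  5–15 ms long, centre frequencies 200–1800 Hz, amplitudes 1.2–2.2 relative
  to the breath peak, at uniform random positions.  The damped-sinusoid
  transient is the standard signal model for discontinuous lung sounds.
- **Wheezes**: a sustained tone occupying 40–80 % of the cycle, fundamental
  150–900 Hz with 2 % vibrato and a second harmonic, amplitude 0.5–0.9
  relative to the breath peak — a narrowband spectrogram ridge.
- **Both**: superposition of the two event types.

Clips are peak-normalized to ±0.95 and written as 16-bit PCM WAV plus
ICBHI-convention annotations, so the on-disk fixtures exercise the same
readers as real data.  Burst count 0 is allowed and documented: the clip
degenerates to normal-class statistics.

Fixture quality is certified by a deliberately trivial two-feature
classifier: Welch-spectrum peak-to-median power ratio in the 120–1000 Hz
band (tonality) and maximum short-window excess kurtosis after a 1.2 kHz
high-pass (transience; the high-pass prevents a co-occurring wheeze tone
from diluting the burst statistic).  The operating thresholds (30 and 8)
were fixed once during generator design and sit in the wide gap between the
class score distributions (event-free clips score below ~15 and ~5;
wheezes above ~45, crackles above ~13).  This classifier separates a
balanced 40-clip set essentially perfectly, which certifies that the four
classes are learnable from the signal; it plays no role in the CNN
pipeline beyond optional validity screening.

What the generator does **not** model: heart sounds, ambient noise,
sensor/coupling artifacts, patient-to-patient spectral variation,
overlapping cycles, and the long-tailed duration distribution of real
recordings.  Tests passing on these fixtures therefore demonstrate that the
pipeline's machinery is correct and that the network can learn genuinely
discriminative acoustic structure — they do not certify clinical
performance on real auscultation data, which requires the
full external database.

## Validity screening

The original annotation workflow reviewed spectrograms manually and discarded
adventitious clips lacking visible events.  The automated stand-in
(`validity_screen`) scores a labelled clip with the same tonality/transience
features, normalised so 1.0 is the natural operating point, and admits the
clip iff the evidence for its label reaches the threshold.  Screening is
monotone in the threshold, off by default for real data (the labels are
expert-made) and available for fixture QC.

## Problem sizes

The learnability demonstration trains the full reference network on a
balanced synthetic set of 400 clips per class (1120 training / 480
validation after the stratified 70/30 split) for 30 epochs and scores the
fitted model on the validation partition with the Monte-Carlo dropout
prediction rule — about ten minutes on one CPU core.  A fraction of the
synthetic clips carry irreducible label noise by construction: cycles
longer than 2 s are cropped to their initial 2 s, so an adventitious event
placed late in a long cycle can be cropped out while its label remains —
the same effect the truncation rule produces on real recordings.  Unit and property tests use much smaller
architectures and datasets (tens of samples, inputs of 40–64 samples) so
the whole suite stays fast; the full architecture is exercised end-to-end
once.  Cross-validation and grid-search tests run on low-dimensional
separable toy signals, since their contracts (partitioning, leakage safety,
ranking) are independent of the audio domain.

## Known limitations

- The NumPy engine is CPU-bound and single-threaded; it is meant for
  desk-scale experiments, not for training on the full external database.
- Grid search over all 243 configurations with the full architecture is
  computationally heavy; the implementation supports it, but the tests and
  examples exercise reduced grids and reduced architectures.
- The widely quoted grand total of 1,610,466 parameters is inconsistent with
  the sum of the per-layer counts in the same table (1,618,724); the
  per-layer counts are internally consistent and are treated as ground
  truth.
- The reference tuning grid (filters 32–128, kernels 3–7) cannot generate
  the reference final architecture (filters 8–64, kernels 13–7); the grid
  machinery is implemented as specified and the final architecture is kept
  as the independent reference network.
- Residual connections and batch normalization appear in narrative
  descriptions of such networks but not in the layer table reproduced here;
  the sequential topology is authoritative.  Residual skips are deliberately
  not offered: under valid convolutions the block input and output lengths
  differ, so identity shortcuts are ill-defined without padding or projection
  layers the table does not contain.
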