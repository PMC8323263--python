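# Methods

## Problem and scope

The package classifies fixed-length windows of single-channel scalp EEG
into epileptic states. Two task designs are built in: a two-class design
(non-epileptic vs epileptic activity) and a three-class design
(normal / interictal / ictal on record-per-class data; interictal /
preictal / ictal on annotated clinical-style sessions). Evaluation follows
the clinical convention: stratified 10-fold cross-validation with
sensitivity, specificity and accuracy averaged over folds.

## The network

The classifier is a residual 1-D CNN front end feeding stacked independent
recurrent (indRNN) layers.

**Residual blocks.** Three blocks with 64, 128 and 64 filters. Each block
is Conv(k=8, s=1) → BN → LeakyReLU → Conv(k=5, s=2) → BN → LeakyReLU →
Conv(k=3, s=1) → BN, merged with a shortcut before a final LeakyReLU
(slope 0.01). All convolutions are "same"-padded, so each block halves the
time axis: T → ceil(T/2). The shortcut is a kernel-1 stride-2 projection
followed by BN. Blocks 1 and 2 declare the projection; block 3 nominally
does not, but its channel count changes 128 → 64, and an elementwise add
cannot type-check across different channel counts, so a projection is
inserted there as well. A declared-projection-free block with matching
channels uses plain stride-2 subsampling. The published layer table lists
stride 2 on the middle convolution but stride 1 on the kernel-1 shortcut;
that combination cannot produce addable shapes, so the projection uses the
block's total stride (2) — the only shape-consistent reading.

**Pooling.** The layer table's pooling row ("GlobalAveragePooling1D, 2") is
ambiguous: a global average pool emits a single vector, leaving a recurrent
layer nothing to recur over, yet it carries a size-2 parameter. The default
reading here is average pooling with pool size 2 over time (`pool="avg2"`),
which preserves a sequence for the recurrence. The alternative reading —
global average pooling per temporal sub-segment, recurrence over the
sub-segment features — is implemented as `pool="global"` with a
configurable sub-segment count (default 16).

**indRNN.** Each layer computes `h_t = ReLU(W x_t + u ⊙ h_{t-1} + b)` with
a per-unit scalar recurrent weight `u` and no hidden-to-hidden matrix;
stacking two 128-unit layers lets units interact across layers instead.
`u` is initialized uniform on [-1, 1] and clipped to `|u| ≤ 2^(1/T)` after
every optimizer step, where T is the pooled sequence length — the bound
under which a unit's memory over a T-step window cannot blow up. Batch
norm follows each recurrent layer, normalizing per feature over
(batch × time). The final layer's last hidden state feeds a 256-unit dense
layer (LeakyReLU) and a softmax head.

**Training.** SGD with momentum on categorical cross-entropy. The published
configuration fixes batch size 64 and "512 iterations", read here as 512
epochs (the idiom of the toolkit vocabulary it uses); a config flag
(`iteration_unit="steps"`) provides the batch-update reading. Learning rate
and momentum are not published; the defaults are the conventional 0.01 and
0.9, exposed in `TrainConfig`. Inputs are standardized per window (zero
mean, unit variance): amplitude scales differ across acquisition systems,
and the classifier should respond to waveform shape and rhythm, not gain.
Every window shorter than a full batch still contributes (no drop-last).

**Numerics.** Everything is float32. Convolutions are evaluated as
BLAS-accumulated GEMMs, one per kernel tap and stride phase, over the
flattened (batch·time, channels) matrix, with channels-last layout;
gradient and weight-gradient passes reuse per-layer scratch buffers, so a
training step allocates almost nothing. Batch norm uses eps 1e-3 and
momentum 0.9 on the running moments. The Keras-style 0.99 was considered
and rejected as default: in runs of a few hundred optimizer steps the
running statistics would retain a large fraction of their (0, 1)
initialization, and inference-mode predictions visibly diverge from
training-mode behaviour (observed as train accuracy 1.0 vs evaluation
accuracy at chance). 0.99 remains available via
`ArchitectureSpec.bn_momentum`. Independently of the momentum, `fit()`
finishes with *precise batch norm*: one training-mode pass over the
training set replaces the exponential running moments with the exact
population statistics of each normalized input — the population-statistics
inference step of the original batch-norm procedure, of which the running
average is the cheap approximation. Batch-norm statistics use float64
accumulators; gradient reductions use float32. LeakyReLU's derivative at
exactly 0 is taken as 1 (the positive branch).

## Seizure-period labeling

Given expert onset/offset annotations, a recording partitions into four
states over half-open intervals [start, end) in seconds:

- seizures closer than 30 min (previous offset to next onset) merge into
  one clinical event, transitively;
- **ictal** is the merged event spans;
- **preictal** is `[onset - 35 min, onset - 5 min)` — the earliest 30 min
  of the 35 min before onset, leaving a 5-min horizon gap; it is clipped at
  the record start and truncated at an earlier event's offset. The source
  text does not say *which* 30 of the 35 min; taking the earliest leaves a
  pre-onset gap, standard in seizure-prediction labeling;
- **interictal** requires ≥ 60 min after the previous offset *and*
  ≥ 40 min before the next onset. (The source sentence reads "at least 1 h
  after seizure and at least 40 min after seizure", which is internally
  inconsistent; the second clause is read as *before* the next onset.)
  Record edges impose no clearance;
- everything else — postictal recovery, clearance margins, the 5-min
  horizon gap — is **excluded** and never labeled.

A window receives a class only if it lies wholly inside one interval;
windows straddling boundaries are dropped rather than majority-voted, so
state transitions contribute no label noise. Class balancing is seeded
uniform undersampling to the minority count; it never alters labels, only
multiplicity. All clearances are configurable (`PeriodParams`), which the
tests use to build short sessions.

The merge gap is measured offset-to-onset ("the interval between the two
seizures" is not precise about this); onset-to-onset would merge strictly
more, and the offset-to-onset reading keeps a long seizure from swallowing
a genuinely separate later event.

## Synthetic data

The generator exists so that every pipeline stage — including learning —
is testable offline with no download. Classes are deliberate caricatures
of clinical signatures, not biophysical simulations:

- **normal**: 1/f ("pink") background (RMS 20 µV) plus a 10-Hz alpha
  sinusoid (10 µV peak);
- **interictal**: background plus Poisson-timed biphasic ~70-ms spikes at
  0.5 events/s, peak amplitude 5× the background RMS;
- **preictal**: alpha power reduced 30%, spike rate doubled;
- **ictal**: background plus a continuous ~3-Hz spike-and-wave discharge
  at 5× background RMS.

Defaults: 500 Hz sampling (matching clinical acquisition), 173.61 Hz for
Bonn-style records. Everything is deterministic given the seed. A 3-Hz
band-energy threshold separates ictal from normal windows with 100%
accuracy at these defaults, so the end-to-end learning task is well-posed
by construction, and a learning failure indicts the implementation, not
the data.

Clinical-style sessions pack n ≥ 2 seizures into a requested duration with
full preictal stretches and clearance zones, then paint each derived
interval with its class texture (excluded stretches get plain background).
Labeling a session therefore recovers the generated textures; windows lost
at interval boundaries are dropped, not mislabeled.

What the generator does **not** emulate: real artifact structure (EMG, eye
blinks, electrode pops), non-stationary background drift, inter-subject
variability, or realistic preictal dynamics — passing tests show the
pipeline and optimizer work, not that the architecture reaches its
published clinical scores on real recordings. Those require the external
Bonn download (`scripts/bonn_external.py`) or clinical data.

## Evaluation

Confusion counts are one-vs-rest per class. Binary tasks score the seizure
class as positive. The published reports give single Sen/Spe values for
three-class tasks without defining them; here multi-class Sen/Spe are
macro-averaged one-vs-rest and Acc is the fraction of correctly classified
windows. A zero denominator (e.g. no positives in a fold) flags the score
as undefined (NaN) rather than silently reporting 0.

Cross-validation is stratified; for record-based datasets (Bonn-style
series cut into several windows) whole records are assigned to folds so
windows of one record never straddle the train/test boundary
(`groups` argument; a window-level mode exists since the published
protocol does not state its split unit). Each fold trains an independent
model seeded as `seed + fold`; reported scores are arithmetic fold means.

## Problem sizes in the automated checks

The test suite trains the reduced (16/32/16-filter) model on 100
ten-second 500-Hz windows per class — 300 windows for the three-class
task, 200 after balancing for the two-class task — with 30-epoch SGD at
batch 32 and 10-fold cross-validation. `scripts/acceptance.py` recomputes
both experiments at the same window counts with 5-fold cross-validation,
the package's desk-scale reproduction setting. The full-size architecture
(64/128/64 filters, 512 epochs, batch 64) is exercised for construction,
shape and parameter-count conformance, and is the default for real data.

## Known limitations

- At the desk scale the automated checks use, the three-class synthetic
  task does not reach the near-perfect scores of the two-class task: the
  suite measures ~0.87 mean 10-fold accuracy for three classes against
  ~0.99 for two. The limiting boundary is normal vs interictal — detecting
  a Poisson-distributed handful of 70-ms spikes per 10-s window — which
  simple summary features separate cleanly but which the network, trained
  on ~90 windows per class for 30 epochs, generalizes imperfectly. More
  data or longer training closes the gap only partially; the number is a
  property of the architecture at this scale, not of the optimizer
  settings (learning rate, momentum, activation slope and initialization
  variants all land within a few points).
- CPU-only; a full-size 512-epoch run on the Bonn data is an overnight job.
- Single channel; no montage handling, re-referencing or artifact
  rejection (raw amplitudes are fed as-is by design).
- The indRNN recurrence equation is adopted from the method's published
  recipe; the source layer table prints only unit counts.
- Postictal is excluded from every task rather than modeled.
- Strides other than 1 and 2 are supported by the convolution's phase
  decomposition but untuned.
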