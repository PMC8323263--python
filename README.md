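# eegrcnn

Automatic recognition of epileptic states in single-channel EEG with a
residual 1-D convolutional network combined with an independent recurrent
neural network (indRNN) — the "RCNN" architecture — plus everything needed
around it: Bonn-dialect ASCII record I/O, clinical seizure-period labeling
(interictal / preictal / ictal), a seeded synthetic EEG generator, and
10-fold sensitivity/specificity/accuracy evaluation.

## Who this is for

Researchers working on seizure detection and prediction from scalp EEG who
want a self-contained, CPU-only, fully tested reference implementation of
the RCNN window classifier: raw 10-s EEG segments go in, one of
{normal, interictal, preictal, ictal} (per task design) comes out, with the
cross-validated clinical scores

    Sen = TP / (TP + FN)      Spe = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FN + TN + FP)

reported per fold and averaged, exactly as printed in the seizure-detection
literature.

## The model

Each fixed-length window (default 10 s; per-window standardized) passes
through three residual blocks of same-padded 1-D convolutions
(64/128/64 filters, kernels 8/5/3, one stride-2 stage and a kernel-1
projection shortcut per block, batch norm + LeakyReLU), temporal average
pooling, and two stacked 128-unit indRNN layers whose recurrence is

    h_t = ReLU(W x_t + u ⊙ h_{t-1} + b),    |u_i| ≤ 2^(1/T),

i.e. each hidden unit recurs only onto itself through a scalar weight — no
hidden-to-hidden matrix — which keeps deep recurrent stacks trainable. A
256-unit dense layer and a softmax head produce the class probabilities.
Training is SGD with momentum on categorical cross-entropy (batch 64,
512 epochs by default). The whole network, including training, is
implemented in numpy with numba-jitted kernels; no GPU or deep-learning
framework is required.

Clinical-style recordings are labeled from expert seizure annotations:
seizures closer than 30 min merge into one event; preictal is the earliest
30 min of the 35 min before onset; interictal keeps a 1-h clearance after
the previous offset and 40 min before the next onset; everything else
(postictal, margins) is excluded.

## Worked example

Train and evaluate the three-class task (normal / interictal / ictal) on
the built-in synthetic generator, with a desk-scale model:

```python
import eegrcnn as E
from eegrcnn.tasks import make_synthetic_task
from eegrcnn.model import TrainConfig, cross_validate

X, y = make_synthetic_task("three_class", n_per_class=100, seed=42)
cv = cross_validate(
    X, y,
    arch=E.reduced_architecture(3),              # 16/32/16-filter variant
    config=TrainConfig(epochs=30, batch_size=32, seed=42),
    k=10, seed=42,
)
print(cv.summary())
```

which prints (abridged) a table in the layout of the published results:

```
Method          Spec     Sen     Acc
RCNN           93.50   87.00   87.00

fold      Spec     Sen     Acc  n_test
0        93.33   86.67   86.67      30
1        95.00   90.00   90.00      30
2        91.67   83.33   83.33      30
...
9        91.67   83.33   83.33      30
```

`Spec`/`Sen`/`Acc` are the fold-averaged specificity, sensitivity and
accuracy in percent (macro one-vs-rest for multi-class); each fold row is
one held-out tenth of the windows. Ictal windows separate essentially
perfectly at this scale; the residual errors sit on the normal/interictal
boundary (sparse-spike detection — see `docs/methods.md`). The analogous
two-class run (non-epileptic vs epileptic) scores 100/100/100 at this
scale. The same pipeline runs from the shell:

```bash
eegrcnn simulate   --out-dir data/ --classes normal,interictal,ictal --n 30 --seed 7
eegrcnn train-eval --dataset data/ --task three_class --out-dir run/ --epochs 30
eegrcnn predict-stream --model run/model.npz --record data/ictal_000.txt
eegrcnn inspect-arch --input-len 4096
```

Every command writes a JSON manifest (config, seeds, input digests,
per-fold confusion matrices) sufficient to re-run it bit-compatibly.

## Layout

- `eegrcnn.io` — Bonn-dialect ASCII records, annotation CSVs, window segmentation
- `eegrcnn.labeling` — seizure merging, period derivation, window labeling, class balancing
- `eegrcnn.synthetic` — seeded class-distinct EEG textures and annotated sessions
- `eegrcnn.nn` — conv/BN/indRNN layers, residual blocks, the architecture builder
- `eegrcnn.model` — `WindowClassifier.fit()` → results; `cross_validate`; fold logic
- `eegrcnn.metrics` — confusion counting and Sen/Spe/Acc
- `eegrcnn.tasks` — task assembly (two-/three-class) from synthetic, Bonn-style or session data
- `eegrcnn.cli` — `simulate`, `train-eval`, `predict-stream`, `inspect-arch`

See `docs/methods.md` for the scientific and numerical details.
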