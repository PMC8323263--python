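"""Fitting and evaluating the window classifier.

The surface follows the statsmodels convention: :class:`WindowClassifier` is
the model object (data + architecture), its :meth:`~WindowClassifier.fit`
returns a :class:`WindowClassifierResults` carrying the trained network,
the loss history and evaluation helpers, and :func:`cross_validate` returns
a :class:`CrossValidationResults` with per-fold and mean scores and a
``summary()`` table in the layout of the published result tables.

Inputs are standardized per window (zero mean, unit variance) before the
network: amplitude units differ between acquisition systems, and the
classifier should react to waveform shape and rhythm, not to gain.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import ConfigError, DataError, ValidationError
from .metrics import (
    Metrics,
    confusion_matrix,
    positive_class_index,
    score_confusion,
)
from .nn.network import ArchitectureSpec, RCNNetwork, build_rcnn
from .nn.optim import SGD


@dataclass
class TrainConfig:
    """SGD training configuration.

    ``epochs`` counts full passes over the training set (the published
    "512 iterations" read as epochs, the common Keras idiom); set
    ``iteration_unit='steps'`` to read it as individual batch updates
    instead. Learning rate and momentum are conventional SGD settings —
    the published configuration does not print them.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 512
    iteration_unit: str = "epochs"  # or 'steps'
    seed: int = 0
    standardize: bool = True
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if self.iteration_unit not in ("epochs", "steps"):
            raise ValidationError("iteration_unit must be 'epochs' or 'steps'")


def standardize_windows(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling per window (guarding flat windows)."""
    X = np.asarray(X, dtype=np.float32)
    mean = X.mean(axis=1, keepdims=True)
    std = X.std(axis=1, keepdims=True)
    return (X - mean) / np.maximum(std, np.float32(1e-8))


class WindowClassifier:
    """RCNN classifier over fixed-length EEG windows.

    Parameters
    ----------
    X : ndarray, (n_windows, window_len)
        Raw window matrix.
    y : array of str or int
        Class label per window. String labels are encoded in sorted order.
    arch : ArchitectureSpec, optional
        Defaults to the full published architecture with ``n_class`` set
        from the labels.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, arch: ArchitectureSpec | None = None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValidationError("X must be (n_windows, window_len)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y lengths differ")
        if y.dtype.kind in "iu":
            classes = np.unique(y)
            self.class_names = [str(c) for c in classes]
            y_enc = np.searchsorted(classes, y)
        else:
            self.class_names = sorted(set(str(v) for v in y))
            lut = {c: i for i, c in enumerate(self.class_names)}
            y_enc = np.asarray([lut[str(v)] for v in y])
        n_class = len(self.class_names)
        if n_class < 2:
            raise DataError("need at least two classes to fit a classifier")
        if arch is None:
            arch = ArchitectureSpec(n_class=n_class)
        elif arch.n_class != n_class:
            raise ConfigError(
                f"architecture has n_class={arch.n_class} but data has "
                f"{n_class} classes ({self.class_names})"
            )
        self.X = X
        self.y = y_enc.astype(np.int64)
        self.arch = arch
        self.input_len = X.shape[1]

    @classmethod
    def from_windows(cls, labeled_windows, arch: ArchitectureSpec | None = None):
        """Build from a list of :class:`~eegrcnn.labeling.LabeledWindow`."""
        if not labeled_windows:
            raise DataError("no labeled windows supplied")
        X = np.stack([lw.window.samples for lw in labeled_windows])
        y = np.asarray([lw.label for lw in labeled_windows])
        return cls(X, y, arch=arch)

    def fit(self, config: TrainConfig | None = None) -> "WindowClassifierResults":
        """Train with SGD + momentum on categorical cross-entropy."""
        config = config or TrainConfig()
        present = np.unique(self.y)
        if present.size != len(self.class_names):
            missing = sorted(
                set(range(len(self.class_names))) - set(present.tolist())
            )
            names = ", ".join(self.class_names[i] for i in missing)
            raise DataError(f"class(es) absent from training set: {names}")
        X = standardize_windows(self.X) if config.standardize else np.asarray(
            self.X, dtype=np.float32
        )
        net = build_rcnn(self.arch, self.input_len, seed=config.seed)
        opt = SGD(net.parameters(), lr=config.learning_rate, momentum=config.momentum)
        rng = np.random.default_rng(config.seed)
        n = X.shape[0]
        if config.iteration_unit == "epochs":
            n_epochs = config.epochs
            max_steps = None
        else:
            steps_per_epoch = max(1, -(-n // config.batch_size))
            n_epochs = max(1, -(-config.epochs // steps_per_epoch))
            max_steps = config.epochs
        loss_history: list[float] = []
        steps_done = 0
        for _ in range(n_epochs):
            order = rng.permutation(n) if config.shuffle else np.arange(n)
            losses = []
            for start in range(0, n, config.batch_size):
                if max_steps is not None and steps_done >= max_steps:
                    break
                idx = order[start : start + config.batch_size]
                opt.zero_grad()
                losses.append(net.loss_and_backward(X[idx], self.y[idx]))
                opt.step()
                steps_done += 1
            if losses:
                loss_history.append(float(np.mean(losses)))
        # precise BN: replace the EMA inference statistics with the exact
        # population moments over the training set
        net.recalibrate_bn(X, batch_size=config.batch_size)
        return WindowClassifierResults(self, net, config, loss_history)


@dataclass
class EvaluationResult:
    """Confusion matrix plus derived scores for one evaluation set."""

    confusion: np.ndarray
    metrics: Metrics
    n: int


class WindowClassifierResults:
    """A fitted classifier: network, training history, evaluation helpers."""

    def __init__(
        self,
        model: WindowClassifier,
        net: RCNNetwork,
        config: TrainConfig,
        loss_history: list[float],
    ):
        self.model = model
        self.net = net
        self.config = config
        self.loss_history = loss_history
        self.class_names = model.class_names

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if self.config.standardize:
            return standardize_windows(X)
        return np.asarray(X, dtype=np.float32)

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        X = self._prepare(X)
        out = [
            self.net.predict_proba(X[i : i + batch_size])
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "iu":
            return y.astype(np.int64)
        lut = {c: i for i, c in enumerate(self.class_names)}
        try:
            return np.asarray([lut[str(v)] for v in y], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"unknown label {exc.args[0]!r}") from exc

    def evaluate(self, X: np.ndarray, y) -> EvaluationResult:
        """Confusion counts and Sen/Spe/Acc on a held-out set."""
        X = np.asarray(X)
        if X.shape[0] == 0:
            raise DataError("empty evaluation set")
        y_enc = self.encode_labels(y)
        pred = self.predict(X)
        cm = confusion_matrix(y_enc, pred, len(self.class_names))
        positive = positive_class_index(self.class_names)
        return EvaluationResult(
            cm, score_confusion(cm, positive_class=positive), n=X.shape[0]
        )

    def summary(self) -> str:
        lines = [
            "RCNN window classifier (fitted)",
            f"  classes: {', '.join(self.class_names)}",
            f"  input length: {self.model.input_len} samples",
            f"  parameters: {self.net.count_params()}",
            f"  epochs run: {len(self.loss_history)}  "
            f"final loss: {self.loss_history[-1]:.4f}" if self.loss_history else
            "  (no training steps run)",
            f"  max |recurrent weight|: {self.net.max_abs_recurrent_weight():.4f} "
            f"(bound {self.net.u_clip:.4f})",
        ]
        return "\n".join(lines)


def make_folds(
    n_items: int, k: int = 10, seed: int = 0, labels: np.ndarray | None = None
) -> np.ndarray:
    """Assign each item to one of ``k`` folds (sizes differ by at most 1).

    Seeded and deterministic; stratified by class when ``labels`` is given.
    """
    if n_items < k:
        raise DataError(f"cannot split {n_items} items into {k} folds")
    idx = np.arange(n_items)
    folds = np.empty(n_items, dtype=np.int64)
    if labels is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(idx)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(idx, np.asarray(labels))
    for fold_id, (_, test_idx) in enumerate(split):
        folds[test_idx] = fold_id
    return folds


class CrossValidationResults:
    """Per-fold confusion matrices and Sen/Spe/Acc, plus fold means."""

    def __init__(
        self,
        class_names: list[str],
        fold_assignment: np.ndarray,
        confusions: list[np.ndarray],
        per_fold: list[Metrics],
        loss_histories: list[list[float]],
        predictions: np.ndarray | None = None,
    ):
        self.class_names = class_names
        self.fold_assignment = fold_assignment
        self.confusions = confusions
        self.per_fold = per_fold
        self.loss_histories = loss_histories
        #: per-window predicted class index, each from its held-out fold
        self.predictions = predictions

    @property
    def k(self) -> int:
        return len(self.per_fold)

    @property
    def mean_sen(self) -> float:
        return float(np.mean([m.sen for m in self.per_fold]))

    @property
    def mean_spe(self) -> float:
        return float(np.mean([m.spe for m in self.per_fold]))

    @property
    def mean_acc(self) -> float:
        return float(np.mean([m.acc for m in self.per_fold]))

    def fold_digest(self) -> str:
        return hashlib.sha256(self.fold_assignment.tobytes()).hexdigest()

    def summary(self, method_name: str = "RCNN") -> str:
        """Text table in the layout of the published result tables."""
        lines = [
            f"{'Method':<12}{'Spec':>8}{'Sen':>8}{'Acc':>8}",
            f"{method_name:<12}{100 * self.mean_spe:>8.2f}"
            f"{100 * self.mean_sen:>8.2f}{100 * self.mean_acc:>8.2f}",
            "",
            f"{'fold':<6}{'Spec':>8}{'Sen':>8}{'Acc':>8}{'n_test':>8}",
        ]
        for i, (m, cm) in enumerate(zip(self.per_fold, self.confusions)):
            lines.append(
                f"{i:<6}{100 * m.spe:>8.2f}{100 * m.sen:>8.2f}"
                f"{100 * m.acc:>8.2f}{int(cm.sum()):>8}"
            )
        return "\n".join(lines)

    def to_manifest(self) -> dict:
        return {
            "classes": self.class_names,
            "k": self.k,
            "fold_digest": self.fold_digest(),
            "per_fold": [
                {
                    "sen": m.sen,
                    "spe": m.spe,
                    "acc": m.acc,
                    "confusion": cm.tolist(),
                }
                for m, cm in zip(self.per_fold, self.confusions)
            ],
            "mean": {
                "sen": self.mean_sen,
                "spe": self.mean_spe,
                "acc": self.mean_acc,
            },
            "final_losses": [h[-1] if h else None for h in self.loss_histories],
        }


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    arch: ArchitectureSpec | None = None,
    config: TrainConfig | None = None,
    k: int = 10,
    seed: int | None = None,
    groups: np.ndarray | None = None,
) -> CrossValidationResults:
    """Stratified k-fold cross-validation of the window classifier.

    Trains ``k`` independent models, one per held-out fold; reports per-fold
    confusion matrices and Sen/Spe/Acc plus their arithmetic means, which is
    how the published scores are defined. When ``groups`` ties windows to
    source records, whole records are assigned to folds (stratified by the
    record's class) so that windows of one record never leak across the
    train/test boundary.
    """
    config = config or TrainConfig()
    seed = config.seed if seed is None else seed
    X = np.asarray(X)
    y = np.asarray(y)
    if groups is not None:
        groups = np.asarray(groups)
        uniq, first_idx = np.unique(groups, return_index=True)
        group_folds = make_folds(uniq.size, k=k, seed=seed, labels=y[first_idx])
        lut = {g: f for g, f in zip(uniq, group_folds)}
        folds = np.asarray([lut[g] for g in groups], dtype=np.int64)
    else:
        folds = make_folds(X.shape[0], k=k, seed=seed, labels=y)
    confusions, per_fold, histories = [], [], []
    predictions = np.full(X.shape[0], -1, dtype=np.int64)
    class_names: list[str] | None = None
    for fold_id in range(k):
        test = folds == fold_id
        train = ~test
        model = WindowClassifier(X[train], y[train], arch=arch)
        fold_config = TrainConfig(**{**asdict(config), "seed": seed + fold_id})
        results = model.fit(fold_config)
        ev = results.evaluate(X[test], y[test])
        predictions[test] = results.predict(X[test])
        confusions.append(ev.confusion)
        per_fold.append(ev.metrics)
        histories.append(results.loss_history)
        class_names = results.class_names
    return CrossValidationResults(
        class_names, folds, confusions, per_fold, histories, predictions
    )
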