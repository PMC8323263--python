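"""Assembling classification tasks (window matrices + labels) from sources.

Two task designs mirror the published experiments:

* ``two_class`` — non-epileptic vs epileptic activity. On synthetic or
  Bonn-style data this is {normal, interictal} relabelled *non-epileptic*
  against ictal *epileptic*, balanced by seeded random undersampling of the
  majority side (the published experiments face the same 400-vs-100
  imbalance and subsample the non-epileptic records). On clinical-style
  sessions it is preictal vs ictal.
* ``three_class`` — normal / interictal / ictal on record-per-class data;
  interictal / preictal / ictal on annotated sessions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .exceptions import ConfigError, DataError
from .io import read_annotations, read_bonn_ascii, segment_record
from .labeling import (
    LabeledWindow,
    PeriodParams,
    balance_classes,
    derive_periods,
    label_windows,
    merge_seizures,
)
from .synthetic import SynthSpec, gen_class_windows

TASKS = ("two_class", "three_class")


def _relabel_two_class(y: np.ndarray) -> np.ndarray:
    return np.where(y == "ictal", "epileptic", "non-epileptic")


def _balance_xy(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded undersampling of every class to the minority count."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size > n_min:
            idx = idx[np.sort(rng.choice(idx.size, n_min, replace=False))]
        keep.extend(idx.tolist())
    keep = sorted(keep)
    return X[keep], y[keep]


def make_synthetic_task(
    task: str,
    n_per_class: int = 100,
    fs: float = 500.0,
    window_s: float = 10.0,
    seed: int = 0,
    base_spec: SynthSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic window dataset for one task design.

    ``three_class`` returns ``n_per_class`` windows each of normal /
    interictal / ictal. ``two_class`` pools normal+interictal as
    non-epileptic against ictal and balances to ``n_per_class`` per side.
    """
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}; expected one of {TASKS}")
    X, y = gen_class_windows(
        n_per_class,
        classes=("normal", "interictal", "ictal"),
        fs=fs,
        window_s=window_s,
        seed=seed,
        base_spec=base_spec,
    )
    if task == "three_class":
        return X, y
    y2 = _relabel_two_class(y)
    return _balance_xy(X, y2, seed=seed)


def two_class_subset(y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices + relabeled labels of the balanced two-class subset.

    Relabels a three-class label vector ({normal, interictal} ->
    non-epileptic, ictal -> epileptic) and undersamples the majority side
    to the minority count with the same seeded procedure
    :func:`make_synthetic_task` uses, so the subset of an existing
    three-class window set is reproducible.
    """
    y2 = _relabel_two_class(np.asarray(y))
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y2, return_counts=True)
    n_min = counts.min()
    keep: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y2 == c)
        if idx.size > n_min:
            idx = idx[np.sort(rng.choice(idx.size, n_min, replace=False))]
        keep.extend(idx.tolist())
    keep = np.asarray(sorted(keep))
    return keep, y2[keep]


def load_bonn_task(
    directory: str | Path,
    task: str,
    fs: float,
    window_s: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load a directory of Bonn-dialect ASCII records into (X, y, groups).

    Record classes come from ``manifest.json`` (written by ``simulate``) or,
    failing that, from the filename prefix before the first underscore.
    Records are cut into ``window_s`` windows (default: the whole record as
    one window); ``groups`` ties each window to its source record so
    cross-validation can split at the record level.
    """
    directory = Path(directory)
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}; expected one of {TASKS}")
    manifest = directory / "manifest.json"
    file_classes: dict[str, str] = {}
    if manifest.exists():
        import json

        file_classes = json.loads(manifest.read_text()).get("files", {})
    paths = sorted(p for p in directory.glob("*.txt"))
    if not paths:
        raise DataError(f"no .txt records found in {directory}")
    X, y, groups = [], [], []
    for path in paths:
        cls = file_classes.get(path.name) or path.stem.split("_")[0]
        record = read_bonn_ascii(path, fs=fs)
        if window_s is None:
            windows = [record.samples]
        else:
            windows = [w.samples for w in segment_record(record, window_s)]
        for w in windows:
            X.append(w)
            y.append(cls)
            groups.append(path.stem)
    lengths = {len(w) for w in X}
    if len(lengths) > 1:
        raise DataError(f"records produce unequal window lengths: {sorted(lengths)}")
    X = np.asarray(X)
    y = np.asarray(y)
    groups = np.asarray(groups)
    if task == "two_class":
        y = _relabel_two_class(y)
        X, y, groups = _balance_grouped(X, y, groups, seed)
    return X, y, groups


def _balance_grouped(X, y, groups, seed):
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size > n_min:
            idx = idx[np.sort(rng.choice(idx.size, n_min, replace=False))]
        keep.extend(idx.tolist())
    keep = sorted(keep)
    return X[keep], y[keep], groups[keep]


def load_session_task(
    directory: str | Path,
    task: str,
    fs: float,
    params: PeriodParams | None = None,
    seed: int = 0,
    overlap_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Load an annotated session directory into a balanced window dataset.

    Expects one or more ``*.txt`` records plus ``annotations.csv``. Windows
    are cut at ``params.window_s``, labeled by the derived seizure periods,
    and balanced across the task's class set by seeded undersampling.
    ``overlap_s > 0`` enables overlapping-window augmentation (off by
    default: it multiplies windows without adding independent signal).
    """
    directory = Path(directory)
    params = params or PeriodParams()
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}; expected one of {TASKS}")
    class_set = (
        {"preictal", "ictal"} if task == "two_class"
        else {"interictal", "preictal", "ictal"}
    )
    ann_path = directory / "annotations.csv"
    if not ann_path.exists():
        raise DataError(f"missing annotations.csv in {directory}")
    annotations = read_annotations(ann_path)
    labeled: list[LabeledWindow] = []
    for path in sorted(directory.glob("*.txt")):
        record = read_bonn_ascii(path, fs=fs)
        events = annotations.get(record.subject_id, [])
        merged = merge_seizures(events, gap_min=params.merge_gap_min)
        periods = derive_periods(merged, record.duration_s, params)
        windows = segment_record(record, params.window_s, overlap_s=overlap_s)
        labeled.extend(label_windows(windows, periods, class_set))
    if not labeled:
        raise DataError(f"no labeled windows produced from {directory}")
    balanced = balance_classes(labeled, seed=seed, classes=class_set)
    X = np.stack([lw.window.samples for lw in balanced])
    y = np.asarray([lw.label for lw in balanced])
    return X, y
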