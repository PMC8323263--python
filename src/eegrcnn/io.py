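"""Single-channel EEG record I/O and window segmentation.

The on-disk dialect is the one used by the public Bonn EEG benchmark: one
plain-text ASCII file per record, one sample value per line (LF or CRLF).
Amplitudes are kept exactly as read — no filtering, detrending or artifact
rejection — because the classifier consumes the raw signal.

Seizure annotation tables are CSV with header ``subject,onset_s,offset_s``,
one row per annotated seizure, times in seconds from record start.

Windowed datasets persist as a single ``.npz`` container holding the window
matrix (``n_windows x window_len`` float32), a label vector, a provenance
table (subject id, window start time) and the sampling rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, ValidationError
from .labeling import SeizureEvent

#: Sampling rate (Hz) conventionally used for the public Bonn records. The
#: benchmark's documentation states 173.61 Hz and 4097 samples per 23.6-s
#: series; neither is baked into the parser — ``fs`` is always explicit.
DEFAULT_BONN_FS = 173.61


@dataclass
class EEGRecord:
    """One single-channel recording.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in µV (arbitrary reference), in acquisition order.
    fs : float
        Sampling rate in Hz, strictly positive.
    subject_id : str
        Identifier of the subject / record.
    start_offset_s : float
        Time of the first sample, seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "unknown"
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("EEGRecord.samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("EEGRecord.samples must be finite")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class Window:
    """A fixed-length excerpt of a record, in seconds-from-record-start."""

    samples: np.ndarray
    fs: float
    subject_id: str
    t_start_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.t_start_s < 0:
            raise ValidationError("window start time must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s


def read_bonn_ascii(path: str | Path, fs: float = DEFAULT_BONN_FS) -> EEGRecord:
    """Read a Bonn-dialect ASCII record (one numeric sample per line).

    The subject id is the filename stem. Blank lines are ignored; any other
    non-numeric line raises :class:`DataError` naming the line number.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise DataError(f"cannot read EEG record {path}: {exc}") from exc
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            values.append(float(stripped))
        except ValueError:
            raise DataError(
                f"{path}: line {lineno} is not a number: {stripped!r}"
            ) from None
    if not values:
        raise DataError(f"{path}: no samples found (empty record)")
    return EEGRecord(np.asarray(values), fs=fs, subject_id=path.stem)


def write_bonn_ascii(record: EEGRecord, path: str | Path, fmt: str = "%.17g") -> None:
    """Write a record in the Bonn ASCII dialect.

    The default format round-trips float64 exactly through text.
    """
    path = Path(path)
    with path.open("w") as fh:
        for v in record.samples:
            fh.write(fmt % v)
            fh.write("\n")


def read_annotations(path: str | Path) -> dict[str, list[SeizureEvent]]:
    """Read a seizure annotation CSV into per-subject sorted event lists.

    Expected header: ``subject,onset_s,offset_s``. Each row must satisfy
    ``onset_s < offset_s``; events of one subject must not overlap.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read annotations {path}: {exc}") from exc
    required = {"subject", "onset_s", "offset_s"}
    if not required.issubset(table.columns):
        raise DataError(
            f"{path}: annotation header must contain {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    for idx, row in table.iterrows():
        if not float(row.onset_s) < float(row.offset_s):
            raise ValidationError(
                f"{path}: row {idx + 1}: onset_s ({row.onset_s}) must be < "
                f"offset_s ({row.offset_s})"
            )
    out: dict[str, list[SeizureEvent]] = {}
    for subject, group in table.groupby("subject", sort=True):
        events = sorted(
            (SeizureEvent(float(r.onset_s), float(r.offset_s)) for r in group.itertuples()),
            key=lambda e: e.onset_s,
        )
        for prev, nxt in zip(events, events[1:]):
            if nxt.onset_s < prev.offset_s:
                raise ValidationError(
                    f"{path}: overlapping events for subject {subject!r}: "
                    f"[{prev.onset_s}, {prev.offset_s}) and [{nxt.onset_s}, {nxt.offset_s})"
                )
        out[str(subject)] = events
    return out


def write_annotations(events: dict[str, list[SeizureEvent]], path: str | Path) -> None:
    """Write per-subject seizure events as ``subject,onset_s,offset_s`` CSV."""
    rows = [
        {"subject": subject, "onset_s": ev.onset_s, "offset_s": ev.offset_s}
        for subject in sorted(events)
        for ev in events[subject]
    ]
    pd.DataFrame(rows, columns=["subject", "onset_s", "offset_s"]).to_csv(
        path, index=False
    )


def segment_record(
    record: EEGRecord, window_s: float, overlap_s: float = 0.0
) -> list[Window]:
    """Cut a record into fixed-length windows.

    Windows start at t = 0 and advance by ``window_s - overlap_s``. A trailing
    remainder shorter than one window is discarded (fixed-length segments only;
    padding would fabricate signal). A window longer than the record yields an
    empty list with a warning, not an error.
    """
    if not 0 <= overlap_s < window_s:
        raise ValidationError(
            f"need 0 <= overlap_s < window_s, got overlap_s={overlap_s}, "
            f"window_s={window_s}"
        )
    window_len = int(round(window_s * record.fs))
    if window_len < 1:
        raise ValidationError(f"window_s={window_s} is shorter than one sample")
    if window_len > record.n_samples:
        warnings.warn(
            f"window ({window_s} s) longer than record "
            f"({record.duration_s:.6g} s); no windows produced",
            stacklevel=2,
        )
        return []
    step = int(round((window_s - overlap_s) * record.fs))
    step = max(step, 1)
    windows = []
    for start in range(0, record.n_samples - window_len + 1, step):
        windows.append(
            Window(
                samples=record.samples[start : start + window_len],
                fs=record.fs,
                subject_id=record.subject_id,
                t_start_s=record.start_offset_s + start / record.fs,
            )
        )
    return windows


@dataclass
class WindowDataset:
    """In-memory windowed dataset: matrix + labels + provenance."""

    X: np.ndarray  # (n_windows, window_len) float32
    labels: np.ndarray  # (n_windows,) unicode
    subjects: np.ndarray  # (n_windows,) unicode
    t_start_s: np.ndarray  # (n_windows,) float64
    fs: float

    def __len__(self) -> int:
        return self.X.shape[0]


def save_windows(dataset: WindowDataset, path: str | Path) -> None:
    """Persist a windowed dataset as a ``.npz`` container (documented format)."""
    np.savez(
        path,
        X=dataset.X.astype(np.float32),
        labels=np.asarray(dataset.labels, dtype=np.str_),
        subjects=np.asarray(dataset.subjects, dtype=np.str_),
        t_start_s=np.asarray(dataset.t_start_s, dtype=np.float64),
        fs=np.float64(dataset.fs),
    )


def load_windows(path: str | Path) -> WindowDataset:
    try:
        with np.load(path) as data:
            return WindowDataset(
                X=data["X"],
                labels=data["labels"],
                subjects=data["subjects"],
                t_start_s=data["t_start_s"],
                fs=float(data["fs"]),
            )
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot load window dataset {path}: {exc}") from exc
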