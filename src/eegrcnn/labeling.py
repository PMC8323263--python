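"""Seizure-period derivation and window labeling.

A long clinical recording with expert-annotated seizure onsets/offsets is
partitioned into four states:

* **ictal** — the annotated seizure spans themselves;
* **preictal** — the earliest 30 min of the 35 min before each onset, i.e.
  ``[onset - 35 min, onset - 5 min)``, leaving a 5-min horizon gap immediately
  before the seizure;
* **interictal** — baseline activity at least 1 h after the previous seizure's
  offset and at least 40 min before the next onset;
* **excluded** — everything else (postictal recovery, clearance margins and
  the pre-onset horizon gap); excluded time is never labeled.

Seizures closer than 30 min (offset to next onset) are clinically one event
and are merged before periods are derived. All intervals are half-open
``[start, end)`` in seconds from record start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, ValidationError

Interval = tuple[float, float]


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure, seconds from record start, ``onset < offset``."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValidationError(
                f"seizure onset ({self.onset_s}) must be < offset ({self.offset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class PeriodParams:
    """Tunable clearances of the period-derivation rules (minutes).

    Defaults implement: preictal = 30 min within the 35 min pre-onset,
    merge gap 30 min, interictal >= 60 min post-offset and >= 40 min
    pre-onset, 10-s analysis windows.
    """

    preictal_lead_min: float = 35.0
    preictal_len_min: float = 30.0
    merge_gap_min: float = 30.0
    post_offset_clear_min: float = 60.0
    pre_onset_clear_min: float = 40.0
    window_s: float = 10.0

    def __post_init__(self) -> None:
        if self.preictal_len_min > self.preictal_lead_min:
            raise ValidationError(
                "preictal_len_min cannot exceed preictal_lead_min"
            )
        for name in (
            "preictal_lead_min",
            "preictal_len_min",
            "merge_gap_min",
            "post_offset_clear_min",
            "pre_onset_clear_min",
            "window_s",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class PeriodIntervals:
    """Disjoint sorted interval lists that partition ``[0, duration)``."""

    preictal: list[Interval] = field(default_factory=list)
    ictal: list[Interval] = field(default_factory=list)
    interictal: list[Interval] = field(default_factory=list)
    excluded: list[Interval] = field(default_factory=list)

    def classes(self) -> dict[str, list[Interval]]:
        return {
            "preictal": self.preictal,
            "ictal": self.ictal,
            "interictal": self.interictal,
            "excluded": self.excluded,
        }

    def class_at(self, t: float) -> str | None:
        """State claiming time ``t`` (None outside the record)."""
        for name, intervals in self.classes().items():
            for s, e in intervals:
                if s <= t < e:
                    return name
        return None


def _check_sorted_disjoint(events: list[SeizureEvent]) -> None:
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset_s < prev.onset_s:
            raise ValidationError("events must be sorted by onset")
        if nxt.onset_s < prev.offset_s:
            raise ValidationError(
                f"events overlap: [{prev.onset_s}, {prev.offset_s}) and "
                f"[{nxt.onset_s}, {nxt.offset_s})"
            )


def merge_seizures(
    events: list[SeizureEvent], gap_min: float = 30.0
) -> list[SeizureEvent]:
    """Merge seizures separated by less than ``gap_min`` minutes.

    The gap is measured offset-to-next-onset. Merging is transitive (a chain
    of close events collapses to one span) and idempotent.
    """
    _check_sorted_disjoint(events)
    if not events:
        return []
    gap_s = gap_min * 60.0
    merged = [events[0]]
    for ev in events[1:]:
        last = merged[-1]
        if ev.onset_s - last.offset_s < gap_s:
            merged[-1] = SeizureEvent(last.onset_s, max(last.offset_s, ev.offset_s))
        else:
            merged.append(ev)
    return merged


def _subtract(intervals: list[Interval], holes: list[Interval]) -> list[Interval]:
    """Set-difference of sorted disjoint interval lists."""
    out: list[Interval] = []
    for s, e in intervals:
        pieces = [(s, e)]
        for hs, he in holes:
            nxt: list[Interval] = []
            for ps, pe in pieces:
                if he <= ps or hs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < hs:
                    nxt.append((ps, hs))
                if he < pe:
                    nxt.append((he, pe))
            pieces = nxt
        out.extend(p for p in pieces if p[0] < p[1])
    return sorted(out)


def derive_periods(
    events: list[SeizureEvent],
    record_duration_s: float,
    params: PeriodParams | None = None,
) -> PeriodIntervals:
    """Partition ``[0, record_duration_s)`` into the four seizure states.

    ``events`` must already be merged (see :func:`merge_seizures`) and lie
    within the record. With no events the whole record is interictal.
    """
    params = params or PeriodParams()
    _check_sorted_disjoint(events)
    dur = float(record_duration_s)
    if dur <= 0:
        raise ValidationError("record duration must be > 0")
    for ev in events:
        if ev.onset_s < 0 or ev.offset_s > dur:
            raise ValidationError(
                f"event [{ev.onset_s}, {ev.offset_s}) outside record [0, {dur})"
            )
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset_s - prev.offset_s < params.merge_gap_min * 60.0:
            raise ValidationError(
                "events closer than the merge gap; call merge_seizures first"
            )

    lead = params.preictal_lead_min * 60.0
    horizon = (params.preictal_lead_min - params.preictal_len_min) * 60.0
    post_clear = params.post_offset_clear_min * 60.0
    pre_clear = params.pre_onset_clear_min * 60.0

    ictal = [(ev.onset_s, ev.offset_s) for ev in events]

    preictal: list[Interval] = []
    for i, ev in enumerate(events):
        lo = ev.onset_s - lead
        hi = ev.onset_s - horizon
        lo = max(lo, 0.0)
        if i > 0:  # truncate at the previous seizure's offset
            lo = max(lo, events[i - 1].offset_s)
        if lo < hi:
            preictal.append((lo, min(hi, dur)))

    # Interictal candidates: >= post_clear after previous offset and
    # >= pre_clear before next onset (record edges impose no clearance).
    candidates: list[Interval] = []
    bounds = [0.0] + [ev.offset_s for ev in events]
    nexts = [ev.onset_s for ev in events] + [dur]
    for i, (lo0, hi0) in enumerate(zip(bounds, nexts)):
        lo = lo0 if i == 0 else lo0 + post_clear
        hi = hi0 if i == len(events) else hi0 - pre_clear
        lo, hi = max(lo, 0.0), min(hi, dur)
        if lo < hi:
            candidates.append((lo, hi))
    # Guard the partition invariant for non-default clearances.
    interictal = _subtract(candidates, sorted(ictal + preictal))

    claimed = sorted(ictal + preictal + interictal)
    excluded = _subtract([(0.0, dur)], claimed)
    return PeriodIntervals(
        preictal=sorted(preictal),
        ictal=sorted(ictal),
        interictal=sorted(interictal),
        excluded=excluded,
    )


@dataclass
class LabeledWindow:
    """A window plus its assigned class label."""

    window: "Window"  # noqa: F821 - eegrcnn.io.Window (kept untyped to avoid cycle)
    label: str


def label_windows(
    windows: list,
    periods: PeriodIntervals,
    class_set: set[str] | None = None,
) -> list[LabeledWindow]:
    """Assign a period class to every window wholly inside one interval.

    A window gets a label iff its full span ``[t_start, t_end)`` lies inside a
    single interval of a class in ``class_set``. Windows straddling interval
    boundaries, inside excluded regions, or of classes outside the task are
    dropped (not mislabeled): transitions are label noise, not evidence.
    """
    class_set = class_set or {"preictal", "ictal", "interictal"}
    out: list[LabeledWindow] = []
    per_class = periods.classes()
    for w in windows:
        t0, t1 = w.t_start_s, w.t_end_s
        for name in ("preictal", "ictal", "interictal"):
            if name not in class_set:
                continue
            if any(s <= t0 and t1 <= e for s, e in per_class[name]):
                out.append(LabeledWindow(w, name))
                break
    return out


def balance_classes(
    items: list[LabeledWindow],
    seed: int,
    classes: set[str] | None = None,
) -> list[LabeledWindow]:
    """Undersample every class to the minority count, uniformly at random.

    Deterministic given ``seed``; labels are never altered, only multiplicity.
    ``classes`` (default: the labels present) must each occur at least once.
    """
    by_class: dict[str, list[int]] = {}
    for i, item in enumerate(items):
        by_class.setdefault(item.label, []).append(i)
    wanted = classes or set(by_class)
    missing = sorted(wanted - set(by_class))
    if missing:
        raise DataError(f"no windows for class(es): {', '.join(missing)}")
    n_min = min(len(by_class[c]) for c in wanted)
    rng = np.random.default_rng(seed)
    kept: list[int] = []
    for c in sorted(wanted):
        idx = by_class[c]
        if len(idx) > n_min:
            chosen = rng.choice(len(idx), size=n_min, replace=False)
            kept.extend(idx[j] for j in sorted(chosen))
        else:
            kept.extend(idx)
    return [items[i] for i in sorted(kept)]
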