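"""Seizure merging, period derivation and window labeling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eegrcnn.exceptions import DataError, ValidationError
from eegrcnn.io import EEGRecord, segment_record
from eegrcnn.labeling import (
    LabeledWindow,
    PeriodParams,
    SeizureEvent,
    balance_classes,
    derive_periods,
    label_windows,
    merge_seizures,
)


def brute_force_state(t, events, duration, params=None):
    """Independent per-second classifier implementing the period rules."""
    params = params or PeriodParams()
    lead = params.preictal_lead_min * 60
    horizon = (params.preictal_lead_min - params.preictal_len_min) * 60
    post = params.post_offset_clear_min * 60
    pre = params.pre_onset_clear_min * 60
    for i, ev in enumerate(events):
        if ev.onset_s <= t < ev.offset_s:
            return "ictal"
    for i, ev in enumerate(events):
        lo = max(ev.onset_s - lead, 0.0)
        if i > 0:
            lo = max(lo, events[i - 1].offset_s)
        if lo <= t < ev.onset_s - horizon:
            return "preictal"
    ok = True
    for ev in events:
        if ev.offset_s <= t < ev.offset_s + post:
            ok = False
        if ev.onset_s - pre <= t < ev.onset_s:
            ok = False
    return "interictal" if ok else "excluded"


class TestMergeSeizures:
    def test_merges_events_closer_than_gap(self):
        evs = [SeizureEvent(1000, 1060), SeizureEvent(2500, 2590)]
        merged = merge_seizures(evs, gap_min=30)
        # 2500 - 1060 = 1440 s < 1800 s: clinically one seizure
        assert merged == [SeizureEvent(1000, 2590)]

    def test_keeps_events_beyond_gap(self):
        evs = [SeizureEvent(0, 60), SeizureEvent(4000, 4060)]
        assert merge_seizures(evs, gap_min=30) == evs

    def test_chain_merges_transitively(self):
        evs = [SeizureEvent(0, 60), SeizureEvent(1500, 1560), SeizureEvent(3000, 3060)]
        assert merge_seizures(evs, gap_min=30) == [SeizureEvent(0, 3060)]

    def test_idempotent(self):
        evs = [SeizureEvent(0, 60), SeizureEvent(1500, 1560), SeizureEvent(9000, 9100)]
        once = merge_seizures(evs)
        assert merge_seizures(once) == once

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            merge_seizures([SeizureEvent(100, 200), SeizureEvent(0, 50)])

    def test_event_validation(self):
        with pytest.raises(ValidationError):
            SeizureEvent(50, 40)


class TestDerivePeriods:
    def test_single_event_worked_example(self):
        periods = derive_periods([SeizureEvent(7200, 7300)], 36000.0)
        assert periods.preictal == [(5100.0, 6900.0)]
        assert periods.ictal == [(7200.0, 7300.0)]
        assert periods.interictal == [(0.0, 4800.0), (10900.0, 36000.0)]
        assert periods.excluded == [
            (4800.0, 5100.0), (6900.0, 7200.0), (7300.0, 10900.0)
        ]

    def test_preictal_clipped_at_record_start(self):
        periods = derive_periods([SeizureEvent(600, 700)], 36000.0)
        assert periods.preictal == [(0.0, 300.0)]

    def test_empty_event_list_is_all_interictal(self):
        periods = derive_periods([], 1000.0)
        assert periods.interictal == [(0.0, 1000.0)]
        assert not periods.preictal and not periods.ictal and not periods.excluded

    def test_matches_bruteforce_per_second(self):
        events = [SeizureEvent(7200, 7300), SeizureEvent(20000, 20150)]
        duration = 30000.0
        periods = derive_periods(events, duration)
        for t in range(0, int(duration), 7):
            assert periods.class_at(t) == brute_force_state(t, events, duration), t

    def test_unmerged_events_rejected(self):
        with pytest.raises(ValidationError, match="merge"):
            derive_periods([SeizureEvent(0, 60), SeizureEvent(100, 160)], 10000.0)

    @given(
        onsets=st.lists(st.integers(0, 200), min_size=0, max_size=4),
        duration=st.integers(500, 2000),
    )
    def test_partition_property(self, onsets, duration):
        """Every second belongs to exactly one of the four states."""
        params = PeriodParams(
            preictal_lead_min=1.0, preictal_len_min=0.5, merge_gap_min=0.5,
            post_offset_clear_min=1.0, pre_onset_clear_min=0.8,
        )
        t0 = 0.0
        events = []
        for o in sorted(onsets):
            onset = max(t0 + 40.0, float(o * 10))  # keep beyond the merge gap
            offset = onset + 15.0
            if offset >= duration:
                break
            events.append(SeizureEvent(onset, offset))
            t0 = offset
        periods = derive_periods(events, float(duration), params)
        # disjointness + coverage, via interval arithmetic
        all_iv = sorted(
            periods.preictal + periods.ictal + periods.interictal + periods.excluded
        )
        assert all(e > s for s, e in all_iv)
        assert all_iv[0][0] == 0.0
        assert all_iv[-1][1] == duration
        for (s1, e1), (s2, e2) in zip(all_iv, all_iv[1:]):
            assert e1 == pytest.approx(s2), "gap or overlap in partition"
        for t in range(0, duration, 13):
            assert periods.class_at(t) == brute_force_state(
                t, events, duration, params
            )


def _mk_window(t0, dur=10.0, fs=10.0):
    from eegrcnn.io import Window

    return Window(np.zeros(int(dur * fs)), fs=fs, subject_id="s", t_start_s=t0)


class TestLabelWindows:
    @pytest.fixture
    def periods(self):
        return derive_periods([SeizureEvent(7200, 7300)], 36000.0)

    def test_window_inside_preictal(self, periods):
        lw = label_windows([_mk_window(5100.0)], periods)
        assert len(lw) == 1 and lw[0].label == "preictal"

    def test_straddling_window_dropped(self, periods):
        assert label_windows([_mk_window(6895.0)], periods) == []

    def test_window_inside_ictal(self, periods):
        lw = label_windows([_mk_window(7240.0, dur=5.0)], periods)
        assert len(lw) == 1 and lw[0].label == "ictal"

    def test_class_set_filters(self, periods):
        lw = label_windows([_mk_window(0.0)], periods, class_set={"preictal", "ictal"})
        assert lw == []

    def test_no_window_overlaps_ictal_unless_ictal(self, periods):
        rec = EEGRecord(np.zeros(360000), fs=10.0)
        windows = segment_record(rec, 10.0)
        for lw in label_windows(windows, periods):
            if lw.label != "ictal":
                assert lw.window.t_end_s <= 7200 or lw.window.t_start_s >= 7300


class TestBalanceClasses:
    def _items(self, counts, seed=0):
        out = []
        i = 0
        for label, n in counts.items():
            for _ in range(n):
                out.append(LabeledWindow(_mk_window(float(i)), label))
                i += 1
        return out

    def test_downsamples_to_minority(self):
        items = self._items({"non-epileptic": 400, "epileptic": 100})
        balanced = balance_classes(items, seed=0)
        labels = [it.label for it in balanced]
        assert labels.count("non-epileptic") == 100
        assert labels.count("epileptic") == 100

    def test_already_balanced_unchanged(self):
        items = self._items({"a": 5, "b": 5})
        balanced = balance_classes(items, seed=1)
        assert sorted(id(x) for x in balanced) == sorted(id(x) for x in items)

    def test_seed_determinism_and_variation(self):
        items = self._items({"a": 400, "b": 100})
        pick = lambda s: tuple(
            it.window.t_start_s for it in balance_classes(items, seed=s)
        )
        assert pick(7) == pick(7)
        assert pick(7) != pick(8)

    def test_missing_class_named(self):
        items = self._items({"a": 3})
        with pytest.raises(DataError, match="b"):
            balance_classes(items, seed=0, classes={"a", "b"})

    def test_labels_never_change(self):
        items = self._items({"a": 10, "b": 4})
        balanced = balance_classes(items, seed=0)
        starts = {it.window.t_start_s: it.label for it in items}
        for it in balanced:
            assert starts[it.window.t_start_s] == it.label
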