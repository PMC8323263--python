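"""Synthetic EEG generator: determinism, spectral structure, sessions."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from eegrcnn.exceptions import DataError
from eegrcnn.io import segment_record
from eegrcnn.labeling import PeriodParams, derive_periods, label_windows
from eegrcnn.synthetic import (
    SynthSpec,
    gen_background,
    gen_class_record,
    gen_class_windows,
    gen_clinical_session,
)


class TestBackground:
    def test_seeded_determinism(self):
        spec = SynthSpec(seed=11)
        a = gen_background(spec).samples
        b = gen_background(spec).samples
        np.testing.assert_array_equal(a, b)
        c = gen_background(SynthSpec(seed=12)).samples
        assert not np.array_equal(a, c)

    def test_pure_alpha_when_no_noise(self):
        spec = SynthSpec(amp_background=0.0, alpha_amp=10.0, duration_s=20.0)
        rec = gen_background(spec)
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / spec.fs)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(rec.samples)))]
        assert peak == pytest.approx(spec.alpha_hz, abs=0.1)
        assert np.max(rec.samples) == pytest.approx(10.0, rel=0.05)

    def test_one_over_f_spectral_slope(self):
        spec = SynthSpec(duration_s=60.0, alpha_amp=0.0, seed=5)
        rec = gen_background(spec)
        f, pxx = sps.welch(rec.samples, fs=spec.fs, nperseg=4096)
        band = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log10(f[band]), np.log10(pxx[band]), 1)[0]
        assert -1.5 <= slope <= -0.5


class TestClassRecords:
    def test_unknown_class_rejected(self):
        with pytest.raises(DataError, match="unknown class"):
            gen_class_record(SynthSpec(class_name="postictal"))

    def test_ictal_dominant_frequency(self):
        rec = gen_class_record(SynthSpec(class_name="ictal", duration_s=30.0, seed=2))
        f, pxx = sps.welch(rec.samples, fs=500.0, nperseg=4096)
        assert f[np.argmax(pxx)] == pytest.approx(3.0, abs=0.5)

    def test_interictal_spike_count_poisson(self):
        """Matched-filter spike detection recovers a count inside the
        central 99% interval of Poisson(rate * duration) = Poisson(300)."""
        from eegrcnn.synthetic import _spike_kernel

        spec = SynthSpec(class_name="interictal", duration_s=600.0, seed=3)
        rec = gen_class_record(spec)
        bg = gen_class_record(
            SynthSpec(class_name="normal", duration_s=600.0, seed=3)
        )
        rms_bg = np.sqrt(np.mean(bg.samples**2))
        kernel = _spike_kernel(spec.fs)
        mf = np.correlate(rec.samples, kernel, mode="same") / (kernel @ kernel)
        peaks, _ = sps.find_peaks(
            mf, height=2.5 * rms_bg, distance=int(0.07 * spec.fs)
        )
        lo, hi = stats.poisson.ppf([0.005, 0.995], mu=300)
        assert lo <= len(peaks) <= hi
        # and the detector is silent on the spike-free background
        mf0 = np.correlate(bg.samples, kernel, mode="same") / (kernel @ kernel)
        assert len(sps.find_peaks(mf0, height=2.5 * rms_bg)[0]) == 0

    def test_ictal_much_larger_than_normal(self):
        a = gen_class_record(SynthSpec(class_name="normal", seed=9))
        b = gen_class_record(SynthSpec(class_name="ictal", seed=9))
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(b.samples) > 2 * rms(a.samples)

    def test_band_power_threshold_separates_ictal_from_normal(self):
        """A 3-Hz band-energy threshold gives 100% separation at defaults —
        the end-to-end learning task is well-posed by construction."""
        X, y = gen_class_windows(30, classes=("normal", "ictal"), seed=4)
        energies = []
        for row in X:
            f, pxx = sps.periodogram(row, fs=500.0)
            band = (f >= 2.0) & (f <= 4.0)
            energies.append(pxx[band].sum() / pxx.sum())
        energies = np.asarray(energies)
        thresh = np.median(energies)
        pred = np.where(energies > thresh, "ictal", "normal")
        assert (pred == y).mean() == 1.0

    def test_preictal_differs_from_interictal(self):
        # doubled spike rate and damped alpha: higher spike density
        pre = gen_class_record(
            SynthSpec(class_name="preictal", duration_s=120.0, seed=6)
        )
        inter = gen_class_record(
            SynthSpec(class_name="interictal", duration_s=120.0, seed=6)
        )
        kurt = lambda x: stats.kurtosis(x)
        assert kurt(pre.samples) > 0.5  # spiky, heavy-tailed
        f, p_pre = sps.welch(pre.samples, fs=500.0, nperseg=2048)
        _, p_int = sps.welch(inter.samples, fs=500.0, nperseg=2048)
        alpha = (f >= 9) & (f <= 11)
        assert p_pre[alpha].sum() < p_int[alpha].sum()


SHORT = PeriodParams(
    preictal_lead_min=3.0, preictal_len_min=2.0, merge_gap_min=1.0,
    post_offset_clear_min=2.0, pre_onset_clear_min=2.5, window_s=10.0,
)


class TestClinicalSession:
    def test_constructs_requested_seizures(self):
        rec, events = gen_clinical_session(
            2, 3600.0, fs=50.0, seed=0, params=SHORT
        )
        assert len(events) == 2
        assert rec.duration_s == pytest.approx(3600.0)
        gap = events[1].onset_s - events[0].offset_s
        assert gap >= SHORT.merge_gap_min * 60.0

    def test_infeasible_duration_states_minimum(self):
        with pytest.raises(DataError, match="minimum feasible duration"):
            gen_clinical_session(2, 60.0, fs=50.0, seed=0, params=SHORT)

    def test_at_least_two_seizures_required(self):
        from eegrcnn.exceptions import ValidationError

        with pytest.raises(ValidationError):
            gen_clinical_session(1, 36000.0, fs=50.0, seed=0)

    def test_labeling_recovers_generated_textures(self):
        """Segment + derive_periods + label_windows recovers >= 95% of the
        windows with the class texture they were generated as."""
        rec, events = gen_clinical_session(2, 3600.0, fs=50.0, seed=1, params=SHORT)
        periods = derive_periods(events, rec.duration_s, SHORT)
        windows = segment_record(rec, SHORT.window_s)
        labeled = label_windows(windows, periods)
        assert len(labeled) >= 0.5 * len(windows)  # sanity: plenty survive
        # physical check, independent of the labeling machinery: the ictal
        # texture is a high-amplitude 3-Hz discharge, interictal is baseline
        rms = lambda x: float(np.sqrt(np.mean(x**2)))
        by_label = {}
        agree = total = 0
        inter_rms = np.median(
            [rms(lw.window.samples) for lw in labeled if lw.label == "interictal"]
        )
        for lw in labeled:
            total += 1
            looks_ictal = rms(lw.window.samples) > 2.0 * inter_rms
            if (lw.label == "ictal") == looks_ictal:
                agree += 1
        assert total > 0
        assert agree / total >= 0.95

    def test_session_determinism(self):
        a, ea = gen_clinical_session(2, 3600.0, fs=50.0, seed=5, params=SHORT)
        b, eb = gen_clinical_session(2, 3600.0, fs=50.0, seed=5, params=SHORT)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert ea == eb
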