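"""Seeded synthetic single-channel EEG with class-distinct structure.

The generator emulates the qualitative signatures clinicians use to tell
seizure states apart, as caricatures tuned for testability rather than
biophysical realism:

* **normal** — 1/f ("pink") background noise plus a 10-Hz alpha rhythm;
* **interictal** — background plus sporadic biphasic epileptiform spikes
  (Poisson-timed, ~70 ms, large relative to background RMS);
* **preictal** — background with alpha power reduced by 30% and spikes at
  twice the interictal rate;
* **ictal** — background plus a continuous high-amplitude rhythmic
  spike-and-wave discharge at ~3 Hz.

Everything is deterministic given the spec's seed. Long clinical-style
sessions are assembled so that the period-derivation rules recover exactly
the class textures that were generated — see :func:`gen_clinical_session`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DataError, ValidationError
from .io import EEGRecord
from .labeling import PeriodParams, SeizureEvent, derive_periods

CLASS_NAMES = ("normal", "interictal", "preictal", "ictal")

#: Duration of one biphasic epileptiform spike, seconds.
SPIKE_DUR_S = 0.07


@dataclass
class SynthSpec:
    """Parameters of one synthetic record.

    Amplitudes are µV; ``amp_background`` is the RMS of the 1/f noise floor,
    ``alpha_amp`` the peak amplitude of the alpha sinusoid. Spike and
    spike-wave amplitudes scale with the background RMS via ``sw_amp_mult``.
    """

    fs: float = 500.0
    duration_s: float = 10.0
    class_name: str = "normal"
    seed: int = 0
    amp_background: float = 20.0
    alpha_hz: float = 10.0
    alpha_amp: float = 10.0
    spike_rate_hz: float = 0.5
    sw_freq_hz: float = 3.0
    sw_amp_mult: float = 5.0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValidationError("fs must be > 0")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be > 0")
        for name in ("amp_background", "alpha_amp", "spike_rate_hz",
                     "sw_freq_hz", "sw_amp_mult"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ 1/f."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2  =>  PSD ~ 1/f
    x = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _background(spec: SynthSpec, rng: np.random.Generator,
                alpha_scale: float = 1.0) -> np.ndarray:
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    if spec.amp_background > 0:
        x += spec.amp_background * _pink_noise(n, spec.fs, rng)
    else:
        rng.standard_normal(np.fft.rfftfreq(n).size * 2)  # keep stream aligned
    phase = rng.uniform(0, 2 * np.pi)
    x += alpha_scale * spec.alpha_amp * np.sin(2 * np.pi * spec.alpha_hz * t + phase)
    return x


def _spike_kernel(fs: float) -> np.ndarray:
    """One biphasic (positive-then-negative) ~70 ms spike, unit peak."""
    n = max(int(round(SPIKE_DUR_S * fs)), 2)
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * np.hanning(n) * 1.85  # ~unit peak after taper


def _add_spikes(x: np.ndarray, fs: float, rate_hz: float, amp: float,
                rng: np.random.Generator) -> np.ndarray:
    """Superimpose Poisson-timed biphasic spikes of peak amplitude ``amp``."""
    duration = x.size / fs
    kernel = _spike_kernel(fs) * amp
    n_spikes = rng.poisson(rate_hz * duration)
    starts = np.sort(rng.uniform(0, duration, size=n_spikes))
    out = x.copy()
    for t0 in starts:
        i0 = int(round(t0 * fs))
        seg = kernel[: max(0, min(kernel.size, x.size - i0))]
        out[i0 : i0 + seg.size] += seg
    return out


def gen_background(spec: SynthSpec) -> EEGRecord:
    """Generate the class-independent background: 1/f noise + alpha rhythm."""
    rng = np.random.default_rng(spec.seed)
    x = _background(spec, rng)
    return EEGRecord(x, fs=spec.fs, subject_id=f"bg-{spec.seed:06d}")


def gen_class_record(spec: SynthSpec) -> EEGRecord:
    """Generate one record with the temporal/spectral signature of its class."""
    if spec.class_name not in CLASS_NAMES:
        raise DataError(
            f"unknown class {spec.class_name!r}; expected one of {CLASS_NAMES}"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.class_name == "normal":
        x = _background(spec, rng)
    elif spec.class_name == "interictal":
        x = _background(spec, rng)
        amp = spec.sw_amp_mult * _rms(x)
        x = _add_spikes(x, spec.fs, spec.spike_rate_hz, amp, rng)
    elif spec.class_name == "preictal":
        # alpha power down 30% (amplitude x sqrt(0.7)), spike rate doubled
        x = _background(spec, rng, alpha_scale=np.sqrt(0.7))
        amp = spec.sw_amp_mult * _rms(x)
        x = _add_spikes(x, spec.fs, 2.0 * spec.spike_rate_hz, amp, rng)
    else:  # ictal
        x = _background(spec, rng)
        amp = spec.sw_amp_mult * _rms(x)
        t = np.arange(x.size) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        slow = 0.7 * amp * np.sin(2 * np.pi * spec.sw_freq_hz * t + phase)
        x = x + slow
        # phase-locked sharp transients riding the slow wave
        period = 1.0 / spec.sw_freq_hz
        starts = np.arange(0, spec.duration_s - SPIKE_DUR_S, period)
        kernel = _spike_kernel(spec.fs) * amp
        for t0 in starts:
            i0 = int(round(t0 * spec.fs))
            seg = kernel[: max(0, min(kernel.size, x.size - i0))]
            x[i0 : i0 + seg.size] += seg
    return EEGRecord(
        x, fs=spec.fs, subject_id=f"{spec.class_name}-{spec.seed:06d}"
    )


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def gen_clinical_session(
    n_seizures: int,
    duration_s: float,
    fs: float = 500.0,
    seed: int = 0,
    params: PeriodParams | None = None,
    base_spec: SynthSpec | None = None,
) -> tuple[EEGRecord, list[SeizureEvent]]:
    """Generate a long annotated recording emulating one clinical subject.

    The timeline is packed so every seizure is preceded by a full preictal
    stretch and flanked by interictal baseline beyond the clearance zones:
    running :func:`~eegrcnn.labeling.derive_periods` on the returned events
    recovers, interval by interval, the class texture that was generated
    there. Excluded stretches (postictal, clearance margins, the pre-onset
    horizon gap) carry plain background.

    Raises :class:`DataError` if ``n_seizures`` cannot be packed into
    ``duration_s``, stating the minimum feasible duration.
    """
    if n_seizures < 2:
        raise ValidationError("a session must contain at least two seizures")
    params = params or PeriodParams()
    rng = np.random.default_rng(seed)
    pre_clear = params.pre_onset_clear_min * 60.0
    post_clear = params.post_offset_clear_min * 60.0
    lead = params.preictal_lead_min * 60.0
    inter_min = max(6.0 * params.window_s, 60.0)  # room for a few windows

    ictal_lens = rng.uniform(30.0, 90.0, size=n_seizures)
    # layout per seizure i: [interictal >= inter_min][pre-onset zone][ictal]
    # plus post-offset clearance before the next interictal block.
    min_dur = (
        inter_min + pre_clear  # before first onset
        + float(np.sum(ictal_lens))
        + (n_seizures - 1) * (post_clear + inter_min + pre_clear)
        + post_clear + inter_min  # trailing interictal
    )
    if duration_s < min_dur:
        raise DataError(
            f"cannot fit {n_seizures} seizures in {duration_s:.0f} s; "
            f"minimum feasible duration is {min_dur:.0f} s"
        )
    slack = duration_s - min_dur
    # spread the slack over the n_seizures+1 interictal blocks
    weights = rng.dirichlet(np.ones(n_seizures + 1))
    inter_lens = inter_min + slack * weights

    events: list[SeizureEvent] = []
    t = 0.0
    for i in range(n_seizures):
        t += inter_lens[i] + pre_clear
        onset = t
        offset = onset + ictal_lens[i]
        events.append(SeizureEvent(onset, offset))
        t = offset + post_clear
    assert t + inter_lens[-1] <= duration_s + 1e-6

    periods = derive_periods(events, duration_s, params)
    n_total = int(round(duration_s * fs))
    samples = np.empty(n_total)
    base = base_spec or SynthSpec(fs=fs)
    texture_of = {"preictal": "preictal", "ictal": "ictal",
                  "interictal": "interictal", "excluded": "normal"}
    piece = 0
    for state, intervals in periods.classes().items():
        for s, e in intervals:
            i0, i1 = int(round(s * fs)), int(round(e * fs))
            i1 = min(i1, n_total)
            if i1 <= i0:
                continue
            sub = replace(
                base,
                fs=fs,
                duration_s=(i1 - i0) / fs,
                class_name=texture_of[state],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            samples[i0:i1] = gen_class_record(sub).samples[: i1 - i0]
            piece += 1
    record = EEGRecord(samples, fs=fs, subject_id=f"session-{seed:06d}")
    return record, events


def gen_class_windows(
    n_per_class: int,
    classes: tuple[str, ...] = ("normal", "interictal", "ictal"),
    fs: float = 500.0,
    window_s: float = 10.0,
    seed: int = 0,
    base_spec: SynthSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: n independent windows per class, as (X, labels).

    Each window is one independently seeded record, so no two windows share
    background noise (the analogue of drawing distinct Bonn series).
    """
    base = base_spec or SynthSpec(fs=fs, duration_s=window_s)
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in classes:
        for _ in range(n_per_class):
            sub = replace(
                base,
                fs=fs,
                duration_s=window_s,
                class_name=cls,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            X.append(gen_class_record(sub).samples)
            y.append(cls)
    return np.asarray(X), np.asarray(y)
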