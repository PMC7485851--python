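"""Labeled synthetic two-channel RIP records.

The generator emulates the statistical structure the classifier relies
on, with ground-truth labels for every sample:

* SYB / ASB — quasi-sinusoidal breathing near 0.7-0.76 Hz with slow
  amplitude and frequency jitter; the abdominal channel lags the ribcage
  by a configurable phase (typically ~4 deg for synchronous, ~100 deg for
  asynchronous breathing).
* PAU — near-silence: residual excursions at most 10% of the preceding
  breathing amplitude, plus sensor noise (following the scoring
  convention that a pause drops the excursion by >= 90% of baseline).
* MVT — aperiodic band-limited (< 0.5 Hz) stochastic excursions with
  amplitude at least twice the breathing amplitude, partially correlated
  between belts.
* SIH — a single large breath (>= 2.5x amplitude) superposed on
  synchronous breathing.
* UNK — irregular low-amplitude breathing with drifting inter-belt
  phase, standing in for the residual class.

Amplitudes are in arbitrary units: RIP belts are uncalibrated and the
classifier is scale-invariant, so only ratios between segments matter.
All randomness flows from one explicitly passed generator; the same seed
reproduces the same record bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .record import PatternSequence, RIPRecord

#: breathing amplitude assumed to precede a record's first segment, so a
#: leading PAU still has a well-defined "10% of baseline" ceiling
_DEFAULT_BASELINE_AMPLITUDE = 1.0

_SUPPORTED = {"SYB", "ASB", "PAU", "MVT", "SIH", "UNK"}


@dataclass(frozen=True)
class PatternSpec:
    """One homogeneous stretch of a synthetic record."""

    label: str
    duration_s: float
    breath_freq_hz: float = 0.72
    phase_deg: float = 4.0
    amplitude: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.label not in _SUPPORTED:
            raise ValueError(f"unsupported pattern label {self.label!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.phase_deg <= 180.0:
            raise ValueError("phase_deg must lie in [0, 180]")


@dataclass
class SyntheticRecord:
    """A generated record together with its ground truth."""

    record: RIPRecord
    truth: PatternSequence
    specs: list[PatternSpec]
    seed: int | None = None


def _slow_jitter(n: int, fs: float, rng: np.random.Generator,
                 sd: float, tau_s: float = 8.0) -> np.ndarray:
    """Smooth multiplicative jitter ~ 1 + sd * slow gaussian process."""
    if n == 0:
        return np.ones(0)
    width = max(3, int(round(tau_s * fs)) | 1)
    raw = rng.standard_normal(n + 2 * width)
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")[width:-width]
    denom = np.std(smooth)
    if denom > 0:
        smooth = smooth / denom
    return 1.0 + sd * smooth


def _breathing_pair(
    n: int, fs: float, rng: np.random.Generator,
    freq_hz: float, phase_deg: float, amplitude: float, noise_sd: float,
    freq_jitter: float = 0.04, amp_jitter: float = 0.10,
    phase_drift_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-sinusoidal pair with the abdomen lagging by ``phase_deg``."""
    t_phase = 2 * np.pi * np.cumsum(freq_hz * _slow_jitter(n, fs, rng, freq_jitter)) / fs
    amp = amplitude * _slow_jitter(n, fs, rng, amp_jitter)
    lag = np.deg2rad(phase_deg) * np.ones(n)
    if phase_drift_deg > 0:
        drift = np.deg2rad(phase_drift_deg) * (_slow_jitter(n, fs, rng, 1.0, tau_s=15.0) - 1.0)
        lag = np.abs(lag + drift)
    rcg = amp * np.sin(t_phase) + noise_sd * amplitude * rng.standard_normal(n)
    abd = amp * np.sin(t_phase - lag) + noise_sd * amplitude * rng.standard_normal(n)
    return rcg, abd


def _movement_pair(
    n: int, fs: float, rng: np.random.Generator,
    amplitude: float, noise_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Aperiodic excursions band-limited below 0.5 Hz, amplitude >= 2x breathing."""
    sos = sps.butter(4, 0.4, btype="lowpass", fs=fs, output="sos")
    pad = int(5 * fs)
    common = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    indiv1 = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    indiv2 = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    def scale(x: np.ndarray) -> np.ndarray:
        s = np.std(x)
        return x / s if s > 0 else x
    target_rms = 2.0 * amplitude / np.sqrt(2.0)  # >= 2x breathing excursion
    rcg = target_rms * scale(0.7 * scale(common) + 0.3 * scale(indiv1))
    abd = target_rms * scale(0.7 * scale(common) + 0.3 * scale(indiv2))
    rcg += noise_sd * amplitude * rng.standard_normal(n)
    abd += noise_sd * amplitude * rng.standard_normal(n)
    return rcg, abd


def generate_segment(
    spec: PatternSpec, fs: float, rng: np.random.Generator,
    preceding_amplitude: float = _DEFAULT_BASELINE_AMPLITUDE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one labeled segment; returns (rcg, abd, labels)."""
    n = max(1, int(round(spec.duration_s * fs)))
    label = spec.label
    if label in ("SYB", "ASB"):
        rcg, abd = _breathing_pair(
            n, fs, rng, spec.breath_freq_hz, spec.phase_deg,
            spec.amplitude, spec.noise_sd,
        )
    elif label == "PAU":
        # residual excursions capped at 10% of the preceding breath amplitude
        residual = 0.05 * preceding_amplitude
        rcg, abd = _breathing_pair(
            n, fs, rng, spec.breath_freq_hz, spec.phase_deg,
            residual, noise_sd=0.0,
        )
        rcg += spec.noise_sd * preceding_amplitude * 0.2 * rng.standard_normal(n)
        abd += spec.noise_sd * preceding_amplitude * 0.2 * rng.standard_normal(n)
    elif label == "MVT":
        rcg, abd = _movement_pair(n, fs, rng, spec.amplitude, spec.noise_sd)
    elif label == "SIH":
        rcg, abd = _breathing_pair(
            n, fs, rng, spec.breath_freq_hz, spec.phase_deg,
            spec.amplitude, spec.noise_sd,
        )
        # one deep breath: a gaussian-windowed extra cycle mid-segment
        center = n // 2
        width = fs / spec.breath_freq_hz  # one breath period, in samples
        t = np.arange(n)
        envelope = np.exp(-0.5 * ((t - center) / (width / 2.0)) ** 2)
        sigh = 2.5 * spec.amplitude * envelope * np.sin(
            2 * np.pi * spec.breath_freq_hz * (t - center) / fs + np.pi / 2
        )
        rcg = rcg + sigh
        abd = abd + sigh
    elif label == "UNK":
        rcg, abd = _breathing_pair(
            n, fs, rng, spec.breath_freq_hz, spec.phase_deg,
            0.35 * spec.amplitude, spec.noise_sd * 3.0,
            freq_jitter=0.25, amp_jitter=0.45, phase_drift_deg=60.0,
        )
    else:  # pragma: no cover - guarded by PatternSpec
        raise ValueError(f"unsupported pattern label {label!r}")
    labels = np.full(n, label, dtype="U7")
    return rcg, abd, labels


def generate_record(
    specs: list[PatternSpec], fs: float = 50.0, seed: int | None = None,
    crossfade_s: float = 0.2,
) -> SyntheticRecord:
    """Concatenate labeled segments with short cross-fades.

    Adjacent segments are blended with a raised-cosine cross-fade of at
    most ``crossfade_s`` seconds to avoid step discontinuities; the
    cross-faded samples keep the *incoming* segment's label.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    rcg_parts: list[np.ndarray] = []
    abd_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    preceding_amp = _DEFAULT_BASELINE_AMPLITUDE
    for spec in specs:
        rcg, abd, labels = generate_segment(spec, fs, rng, preceding_amp)
        if spec.label in ("SYB", "ASB", "SIH", "UNK"):
            preceding_amp = spec.amplitude if spec.label != "UNK" else 0.35 * spec.amplitude
        rcg_parts.append(rcg)
        abd_parts.append(abd)
        label_parts.append(labels)

    n_fade = int(round(crossfade_s * fs))
    rcg_all, abd_all, lab_all = rcg_parts[0], abd_parts[0], label_parts[0]
    for rcg, abd, labels in zip(rcg_parts[1:], abd_parts[1:], label_parts[1:]):
        fade = min(n_fade, rcg_all.size, rcg.size)
        if fade > 0:
            ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, fade)))
            rcg_all = np.concatenate([
                rcg_all[:-fade],
                (1 - ramp) * rcg_all[-fade:] + ramp * rcg[:fade],
                rcg[fade:],
            ])
            abd_all = np.concatenate([
                abd_all[:-fade],
                (1 - ramp) * abd_all[-fade:] + ramp * abd[:fade],
                abd[fade:],
            ])
            # cross-fade samples take the incoming pattern's label
            lab_all = np.concatenate([lab_all[:-fade], labels[:fade], labels[fade:]])
        else:
            rcg_all = np.concatenate([rcg_all, rcg])
            abd_all = np.concatenate([abd_all, abd])
            lab_all = np.concatenate([lab_all, labels])

    record = RIPRecord(rcg=rcg_all, abd=abd_all, fs=fs)
    return SyntheticRecord(
        record=record,
        truth=PatternSequence(labels=lab_all),
        specs=list(specs),
        seed=seed,
    )


def study_like_specs(
    total_duration_s: float = 1200.0,
    seed: int | None = None,
    fractions: dict[str, float] | None = None,
) -> list[PatternSpec]:
    """Segment plan mirroring the pattern mix of an infant recovery-room
    record: mostly synchronous breathing with interspersed pauses,
    movement, asynchrony, sighs and irregular filler.

    Fractions default to SYB 0.60, MVT 0.15, UNK 0.11, ASB 0.07,
    PAU 0.05, SIH 0.02.  Pattern episodes use physiologic durations
    (pauses of ~5-15 s, movements of ~10-30 s) and are shuffled between
    synchronous-breathing stretches, always starting with breathing so
    every pause has a baseline breath to be referenced against.
    """
    fractions = fractions or {
        "SYB": 0.60, "MVT": 0.15, "UNK": 0.11, "ASB": 0.07,
        "PAU": 0.05, "SIH": 0.02,
    }
    rng = np.random.default_rng(seed)
    budgets = {k: v * total_duration_s for k, v in fractions.items()}

    def _episodes(label: str, lo: float, hi: float, **kw) -> list[PatternSpec]:
        specs: list[PatternSpec] = []
        remaining = budgets.get(label, 0.0)
        while remaining > 1.0:
            dur = float(min(remaining, rng.uniform(lo, hi)))
            freq = float(rng.uniform(0.66, 0.80))
            specs.append(PatternSpec(label=label, duration_s=dur,
                                     breath_freq_hz=freq, **kw))
            remaining -= dur
        return specs

    events = (
        _episodes("PAU", 5.0, 15.0)
        + _episodes("MVT", 10.0, 30.0)
        + _episodes("ASB", 15.0, 40.0, phase_deg=100.0)
        + _episodes("SIH", 6.0, 10.0, phase_deg=4.0)
        + _episodes("UNK", 10.0, 25.0, phase_deg=30.0)
    )
    rng.shuffle(events)

    # interleave: split the SYB budget into one stretch before each event
    n_gaps = len(events) + 1
    weights = rng.uniform(0.5, 1.5, size=n_gaps)
    weights /= weights.sum()
    syb_total = budgets.get("SYB", 0.0)
    plan: list[PatternSpec] = []
    for i, event in enumerate(events):
        dur = max(2.0, float(weights[i] * syb_total))
        plan.append(PatternSpec(label="SYB", duration_s=dur,
                                breath_freq_hz=float(rng.uniform(0.70, 0.80)),
                                phase_deg=4.0))
        plan.append(event)
    plan.append(PatternSpec(label="SYB", duration_s=max(2.0, float(weights[-1] * syb_total)),
                            breath_freq_hz=0.76, phase_deg=4.0))
    return plan


def generate_study_like_record(
    total_duration_s: float = 1200.0, fs: float = 50.0, seed: int | None = None,
) -> SyntheticRecord:
    """Convenience wrapper: study-like plan -> record, one seed for both."""
    specs = study_like_specs(total_duration_s, seed=seed)
    return generate_record(specs, fs=fs, seed=seed)
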