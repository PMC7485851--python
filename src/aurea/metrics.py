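"""Per-sample respiratory metrics from a two-channel RIP record.

Six metrics feed the pattern classifiers, two more are descriptive:

* ``nv_rcg``, ``nv_abd`` — log normalized variance.  The instantaneous
  variance of the detrended signal, normalized by its running quantile, is
  very low during respiratory pauses (pediatric apnea scoring rules define
  a pause as excursions below ~10% of the preceding baseline).
* ``npp_rcg``, ``npp_abd`` — log normalized nonperiodic power.  A moving
  average whose spectral nulls sit at the respiratory frequency and its
  harmonics notches out periodic breathing; what remains is dominated by
  aperiodic low-frequency movement artifact.
* ``b_plus``, ``b_minus`` — synchronous / asynchronous breathing power.
  The smoothed channels are binarized; the high-pass filtered half-sum of
  the binary signals oscillates during synchronous breathing and vanishes
  during paradoxical breathing, and vice versa for the half-difference.
* ``f_resp`` — instantaneous respiratory frequency by zero-crossing
  demodulation of the binary signal (NaN where undefined).
* ``phi`` — thoracoabdominal phase as the moving fraction of time the two
  binary signals disagree; 0 maps to 0° (synchronous), 1 to 180°
  (paradoxical).

All metrics are ratio- or binary-based, hence invariant to rescaling of
the (uncalibrated) belt signals, and every output series is index-aligned
with the input record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._sliding import centered_mean, centered_mean_square, trailing_quantile
from .config import AnalysisConfig, seconds_to_odd_samples, seconds_to_samples
from .record import RIPRecord

#: Relative floor applied to variance / RMS ratios (squared-signal units,
#: relative to the record's peak value) so that all-zero calibration
#: stretches yield large negative logs, not infinities.
EPS_FLOOR = 1e-12


@dataclass
class MetricSet:
    """Per-sample metric series, index-aligned with the source record."""

    nv_rcg: np.ndarray
    nv_abd: np.ndarray
    npp_rcg: np.ndarray
    npp_abd: np.ndarray
    b_plus: np.ndarray
    b_minus: np.ndarray
    f_resp: np.ndarray
    phi: np.ndarray
    valid_mask: np.ndarray
    fs: float

    _FEATURES = ("nv_rcg", "nv_abd", "npp_rcg", "npp_abd", "b_plus", "b_minus")

    @property
    def n_samples(self) -> int:
        return self.nv_rcg.size

    def feature_matrix(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        """Stack the named metric series into an (n_samples, len(names)) array."""
        cols = []
        for name in names:
            if not hasattr(self, name):
                raise KeyError(f"metric {name!r} not present in MetricSet")
            cols.append(getattr(self, name))
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nv_rcg": self.nv_rcg,
                "nv_abd": self.nv_abd,
                "npp_rcg": self.npp_rcg,
                "npp_abd": self.npp_abd,
                "b_plus": self.b_plus,
                "b_minus": self.b_minus,
                "f_resp": self.f_resp,
                "phi": self.phi,
                "valid": self.valid_mask.astype(int),
            }
        )


def preprocess_rip(
    raw: np.ndarray, cfg: AnalysisConfig, window_s: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the mean and low-frequency components of a raw belt signal.

    Returns ``(rip, rip_lf)`` where ``rip_lf`` is the centered moving
    average over ``window_s`` seconds and ``rip = raw - rip_lf``.
    """
    raw = np.asarray(raw, dtype=float)
    width = seconds_to_odd_samples(window_s, fs)
    if raw.size < width:
        raise ValueError(
            f"series of {raw.size} samples is shorter than the "
            f"{width}-sample detrend window; need at least {width} samples"
        )
    rip_lf = centered_mean(raw, width)
    return raw - rip_lf, rip_lf


def _log_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """ln(num/den) with both floored at EPS_FLOOR relative to the record's
    own power scale, so all-zero stretches give large negative (finite)
    values and the metric stays invariant to rescaling the input."""
    scale = float(np.max(num)) if num.size else 0.0
    floor = EPS_FLOOR * scale if scale > 0 else EPS_FLOOR
    return np.log(np.maximum(num, floor) / np.maximum(den, floor))


def normalized_variance(rip: np.ndarray, cfg: AnalysisConfig, fs: float) -> np.ndarray:
    """Log of instantaneous variance over its trailing running quantile."""
    n_v = seconds_to_odd_samples(cfg.n_v, fs)
    n_qv = seconds_to_samples(cfg.n_qv, fs)
    v = centered_mean_square(rip, n_v)
    v_q = trailing_quantile(v, n_qv, cfg.q_var)
    return _log_ratio(v, v_q)


def nonperiodic_power(rip: np.ndarray, cfg: AnalysisConfig, fs: float) -> np.ndarray:
    """Log normalized RMS of the notch-filtered (moving-averaged) signal."""
    n_ma = seconds_to_odd_samples(cfg.n_ma, fs)
    n_rms = seconds_to_odd_samples(cfg.n_rms, fs)
    n_qrms = seconds_to_samples(cfg.n_qrms, fs)
    rip_ma = centered_mean(rip, n_ma)
    rms = np.sqrt(centered_mean_square(rip_ma, n_rms))
    rms_q = trailing_quantile(rms, n_qrms, cfg.q_rms)
    # floor applied in squared units for consistency with the variance metric
    return 0.5 * _log_ratio(np.square(rms), np.square(rms_q))


def smooth_and_binarize(
    rip: np.ndarray, rip_lf: np.ndarray, cfg: AnalysisConfig, fs: float
) -> np.ndarray:
    """Smooth the detrended signal and threshold it at its local baseline.

    Since ``rip`` is already detrended, a sample is above its local
    baseline exactly when the smoothed detrended signal is positive; ties
    go to 0.  Values within a relative rounding tolerance of zero count
    as ties, so the binarization is invariant to rescaling the input.
    """
    if rip.shape != rip_lf.shape:
        raise ValueError("rip and rip_lf must have identical shape")
    n_smo = seconds_to_odd_samples(cfg.n_smo, fs)
    rip_smo = centered_mean(rip, n_smo)
    tol = 1e-9 * float(np.max(np.abs(rip_smo)))
    return (rip_smo > tol).astype(float)


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all((x == 0.0) | (x == 1.0)):
        raise ValueError(f"{name} must be a binary (0/1) series")
    return x


def highpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase high-pass (5th-order Butterworth, forward-backward)."""
    sos = sps.butter(5, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def syb_asb_metrics(
    rcg_b: np.ndarray, abd_b: np.ndarray, cfg: AnalysisConfig, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Power of the high-pass filtered half-sum / half-difference signals.

    The half-sum of the binary channels oscillates at the respiratory
    frequency when breathing is synchronous and is constant when it is
    paradoxical; the half-difference behaves oppositely.  High-pass
    filtering at ``cfg.hp_cutoff`` removes the sub-0.5 Hz power associated
    with pauses and movement before the windowed power is taken.
    """
    rcg_b = _check_binary(rcg_b, "rcg_b")
    abd_b = _check_binary(abd_b, "abd_b")
    if rcg_b.size != abd_b.size:
        raise ValueError("binary channels must have equal length")
    n_b = seconds_to_odd_samples(cfg.n_b, fs)
    total = (rcg_b + abd_b) / 2.0
    diff = (rcg_b - abd_b) / 2.0
    sum_hp = highpass(total, cfg.hp_cutoff, fs)
    dif_hp = highpass(diff, cfg.hp_cutoff, fs)
    b_plus = centered_mean_square(sum_hp, n_b)
    b_minus = centered_mean_square(dif_hp, n_b)
    return b_plus, b_minus


def respiratory_frequency(rip_b: np.ndarray, fs: float) -> np.ndarray:
    """Instantaneous frequency by zero-crossing demodulation.

    Each transition of the binary signal marks a half-period.  For a sample
    lying between consecutive transitions at samples ``t_k`` and ``t_{k+1}``
    the frequency is ``fs / (2 * (t_{k+1} - t_k))``; samples before the
    first or after the last transition carry the nearest defined value.
    A series with fewer than two transitions is NaN everywhere.
    """
    rip_b = _check_binary(rip_b, "rip_b")
    n = rip_b.size
    out = np.full(n, np.nan)
    trans = np.flatnonzero(np.diff(rip_b) != 0) + 1  # index of first changed sample
    if trans.size < 2:
        return out
    half_periods = np.diff(trans).astype(float)  # samples per half-cycle
    freqs = fs / (2.0 * half_periods)
    # piecewise-constant fill between consecutive transitions
    for k in range(freqs.size):
        out[trans[k] : trans[k + 1]] = freqs[k]
    out[: trans[0]] = freqs[0]
    out[trans[-1] :] = freqs[-1]
    return out


def phase_metric(
    rcg_b: np.ndarray, abd_b: np.ndarray, cfg: AnalysisConfig
) -> np.ndarray:
    """Moving fraction of inter-channel disagreement, in [0, 1] ~ [0°, 180°]."""
    rcg_b = _check_binary(rcg_b, "rcg_b")
    abd_b = _check_binary(abd_b, "abd_b")
    if rcg_b.size != abd_b.size:
        raise ValueError("binary channels must have equal length")
    phi_b = np.logical_xor(rcg_b.astype(bool), abd_b.astype(bool)).astype(float)
    return centered_mean(phi_b, cfg.n_b_phase)


def _valid_mask(n: int, cfg: AnalysisConfig, fs: float) -> np.ndarray:
    """True where every analysis window is fully supported by real samples."""
    centered = [
        seconds_to_odd_samples(w, fs)
        for w in (cfg.n_lf, cfg.n_v, cfg.n_dt_pau_mvt, cfg.n_dt_syb_asb,
                  cfg.n_ma, cfg.n_rms, cfg.n_smo, cfg.n_b)
    ] + [cfg.n_b_phase]
    max_half = max((w - 1) // 2 for w in centered)
    trailing = max(seconds_to_samples(cfg.n_qv, fs), seconds_to_samples(cfg.n_qrms, fs))
    idx = np.arange(n)
    return (idx >= max(trailing - 1, max_half)) & (idx <= n - 1 - max_half)


def compute_metrics(record: RIPRecord, cfg: AnalysisConfig | None = None) -> MetricSet:
    """Compute the full per-sample metric set for a two-channel record.

    The pause/movement metrics are computed on signals detrended with the
    wider ``n_dt_pau_mvt`` window; the synchrony/asynchrony chain, which
    needs a faster baseline, uses ``n_dt_syb_asb``.  The respiratory
    frequency is demodulated from the binarized abdominal channel.
    """
    cfg = cfg or AnalysisConfig()
    cfg.validate_at(record.fs)
    fs = record.fs

    # pause / movement chain (slow detrend)
    rcg_slow, _ = preprocess_rip(record.rcg, cfg, cfg.n_dt_pau_mvt, fs)
    abd_slow, _ = preprocess_rip(record.abd, cfg, cfg.n_dt_pau_mvt, fs)
    nv_rcg = normalized_variance(rcg_slow, cfg, fs)
    nv_abd = normalized_variance(abd_slow, cfg, fs)
    npp_rcg = nonperiodic_power(rcg_slow, cfg, fs)
    npp_abd = nonperiodic_power(abd_slow, cfg, fs)

    # synchrony / asynchrony chain (fast detrend, then binarize)
    rcg_fast, rcg_lf = preprocess_rip(record.rcg, cfg, cfg.n_dt_syb_asb, fs)
    abd_fast, abd_lf = preprocess_rip(record.abd, cfg, cfg.n_dt_syb_asb, fs)
    rcg_b = smooth_and_binarize(rcg_fast, rcg_lf, cfg, fs)
    abd_b = smooth_and_binarize(abd_fast, abd_lf, cfg, fs)
    b_plus, b_minus = syb_asb_metrics(rcg_b, abd_b, cfg, fs)
    f_resp = respiratory_frequency(abd_b, fs)
    phi = phase_metric(rcg_b, abd_b, cfg)

    return MetricSet(
        nv_rcg=nv_rcg,
        nv_abd=nv_abd,
        npp_rcg=npp_rcg,
        npp_abd=npp_abd,
        b_plus=b_plus,
        b_minus=b_minus,
        f_resp=f_resp,
        phi=phi,
        valid_mask=_valid_mask(record.n_samples, cfg, fs),
        fs=fs,
    )
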