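"""Analysis configuration: window widths, quantiles and filter cutoff.

All sliding-window metrics are computed with rectangular windows that are
either *centered* on the current sample (symmetric, odd width) or *trailing*
(the most recent samples up to and including the current one).  Widths are
specified in seconds and converted to sample counts at a given sampling
rate; centered widths are rounded to the nearest odd count so the symmetric
half-width ``(N - 1) / 2`` is an integer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


def seconds_to_odd_samples(width_s: float, fs: float) -> int:
    """Convert a window width in seconds to the nearest odd sample count.

    The result is always >= 1.  Ties (even + 0.5) round up to the next odd.
    """
    n = int(round(width_s * fs))
    if n < 1:
        return 1
    if n % 2 == 0:
        # choose the nearer odd neighbour; exact midpoint rounds up
        lo, hi = n - 1, n + 1
        n = lo if (width_s * fs - lo) < (hi - width_s * fs) else hi
    return n


def seconds_to_samples(width_s: float, fs: float) -> int:
    """Convert a trailing-window width in seconds to samples (>= 1)."""
    return max(1, int(round(width_s * fs)))


@dataclass(frozen=True)
class AnalysisConfig:
    """Window widths (seconds unless noted), quantiles and filter cutoff.

    Parameters
    ----------
    n_lf : float
        Width of the centered moving average used to remove the mean and
        low-frequency components during preprocessing.
    n_qv : float
        Trailing window over which the normalization quantile of the
        instantaneous variance is taken (pause metric).
    n_v : float
        Centered window for the instantaneous variance estimate.
    n_dt_pau_mvt : float
        Detrend window for the pause / movement metric chains.
    n_dt_syb_asb : float
        Detrend window for the synchrony / asynchrony metric chains.
    n_ma : float
        Width of the moving-average notch filter.  The filter has spectral
        nulls at integer multiples of ``fs / N_MA``; the default of 1.42 s
        puts the first null at ~0.7 Hz, the most common infant respiratory
        frequency, so periodic respiratory power is suppressed.
    n_qrms : float
        Trailing window for the RMS normalization quantile (movement metric).
    n_rms : float
        Centered window for the RMS of the notch-filtered signal.
    n_smo : float
        Smoothing window applied before binarization.
    n_b : float
        Centered window for the power of the high-pass filtered sum and
        difference of the binary signals.
    n_b_phase : int
        Width of the phase-averaging window, in **samples**.
    q_var, q_rms : float
        Normalization quantiles in (0, 1).
    hp_cutoff : float
        High-pass cutoff (Hz) applied to the sum/difference signals to
        remove power associated with pauses and movement.
    """

    n_lf: float = 5.0
    n_qv: float = 120.0
    n_v: float = 1.0
    n_dt_pau_mvt: float = 5.0
    n_dt_syb_asb: float = 2.0
    n_ma: float = 1.42
    n_qrms: float = 600.0
    n_rms: float = 5.0
    n_smo: float = 0.42
    n_b: float = 2.0
    n_b_phase: int = 101
    q_var: float = 0.5
    q_rms: float = 0.5
    hp_cutoff: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_lf", "n_qv", "n_v", "n_dt_pau_mvt", "n_dt_syb_asb",
                     "n_ma", "n_qrms", "n_rms", "n_smo", "n_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"window width {name!r} must be > 0")
        if self.n_b_phase < 1 or self.n_b_phase % 2 == 0:
            raise ValueError("n_b_phase must be a positive odd sample count")
        for name in ("q_var", "q_rms"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.hp_cutoff <= 0:
            raise ValueError("hp_cutoff must be > 0")

    def validate_at(self, fs: float) -> None:
        """Check the strict window orderings once widths are in samples."""
        if fs <= 0:
            raise ValueError("fs must be > 0")
        if not seconds_to_odd_samples(self.n_smo, fs) < seconds_to_odd_samples(self.n_dt_syb_asb, fs):
            raise ValueError("n_smo must be smaller than n_dt_syb_asb")
        if not seconds_to_odd_samples(self.n_v, fs) < seconds_to_odd_samples(self.n_lf, fs):
            raise ValueError("n_v must be smaller than n_lf")
        if not seconds_to_odd_samples(self.n_rms, fs) < seconds_to_samples(self.n_qrms, fs):
            raise ValueError("n_rms must be smaller than n_qrms")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
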