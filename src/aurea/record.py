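"""Core containers: the two-channel RIP record and the pattern sequence."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The closed pattern vocabulary.  Predicted sequences use the first five;
#: reference (manually scored) sequences may additionally contain SIH, and
#: merged sequences contain UNKNOWN.
PATTERNS = ("PAU", "MVT", "SYB", "ASB", "UNK")
ALL_LABELS = ("PAU", "MVT", "SYB", "ASB", "UNK", "SIH", "UNKNOWN")

#: Canonical label order of the merged four-pattern vocabulary.
MERGED_PATTERNS = ("PAU", "SYB", "ASB", "UNKNOWN")


@dataclass(frozen=True)
class RIPRecord:
    """Two aligned respiratory inductance plethysmography channels.

    ``rcg`` is the ribcage excursion signal, ``abd`` the abdominal one,
    both in arbitrary (uncalibrated) RIP units and sampled at ``fs`` Hz.
    """

    rcg: np.ndarray
    abd: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        rcg = np.asarray(self.rcg, dtype=float)
        abd = np.asarray(self.abd, dtype=float)
        object.__setattr__(self, "rcg", rcg)
        object.__setattr__(self, "abd", abd)
        if rcg.ndim != 1 or abd.ndim != 1:
            raise ValueError("rcg and abd must be one-dimensional")
        if rcg.size != abd.size:
            raise ValueError(
                f"channel lengths differ: rcg has {rcg.size}, abd has {abd.size}"
            )
        if rcg.size < 1:
            raise ValueError("record must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be > 0")
        if not (np.all(np.isfinite(rcg)) and np.all(np.isfinite(abd))):
            raise ValueError("record contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.rcg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class PatternSequence:
    """One categorical breathing-pattern label per signal sample."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype="U7")
        if labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if labels.size < 1:
            raise ValueError("pattern sequence must be non-empty")
        bad = set(np.unique(labels)) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown pattern labels: {sorted(bad)}")
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def counts(self) -> dict[str, int]:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatternSequence):
            return NotImplemented
        return bool(np.array_equal(self.labels, other.labels))

    def __len__(self) -> int:
        return self.n_samples
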