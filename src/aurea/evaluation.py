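"""Sample-wise and event-wise comparison of two pattern sequences.

A predicted sequence is compared against a reference sequence on the
merged four-pattern vocabulary (PAU, SYB, ASB, UNKNOWN): sighs, movement
and unknown are pooled into UNKNOWN because, for pattern-level
evaluation, there is no clinical reason to separate them.

The per-pattern indices follow the study convention in which the
confusion matrix is row-normalized over the *reference* rows for
"precision" and column-normalized over the predicted columns for
"recall".  Note that this row/column orientation is transposed relative
to the textbook definitions (where precision normalizes over
predictions); pass ``orientation="conventional"`` to
:func:`precision` / :func:`recall` for the textbook quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .record import MERGED_PATTERNS, PatternSequence

#: merge map: sighs, movement and unknown pool into UNKNOWN
_MERGE = {"SIH": "UNKNOWN", "MVT": "UNKNOWN", "UNK": "UNKNOWN",
          "UNKNOWN": "UNKNOWN", "PAU": "PAU", "SYB": "SYB", "ASB": "ASB"}


def merge_patterns(pseq: PatternSequence) -> PatternSequence:
    """Map the six-pattern vocabulary onto {PAU, SYB, ASB, UNKNOWN}."""
    labels = pseq.labels
    out = np.empty_like(labels)
    for src, dst in _MERGE.items():
        out[labels == src] = dst
    return PatternSequence(labels=out)


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows index the reference pattern, columns the
    predicted pattern."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _index(self, pattern: str) -> int:
        try:
            return self.labels.index(pattern)
        except ValueError:
            raise KeyError(f"pattern {pattern!r} not in {self.labels}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def confusion_matrix(
    ref: PatternSequence,
    pred: PatternSequence,
    labels: tuple[str, ...] = MERGED_PATTERNS,
) -> ConfusionMatrix:
    """Count samples per (reference, predicted) label pair."""
    if ref.n_samples != pred.n_samples:
        raise ValueError(
            f"length mismatch: reference has {ref.n_samples} samples, "
            f"prediction has {pred.n_samples}"
        )
    lut = {lab: i for i, lab in enumerate(labels)}
    try:
        ri = np.array([lut[l] for l in ref.labels])
        pi = np.array([lut[l] for l in pred.labels])
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not in label set {labels}") from None
    k = len(labels)
    counts = np.bincount(ri * k + pi, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def accuracy(m: ConfusionMatrix) -> float:
    """Fraction of samples on the diagonal (multiply by 100 for percent)."""
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m.counts) / m.total)


def precision(m: ConfusionMatrix, pattern: str,
              orientation: str = "as-printed") -> float:
    """Per-pattern precision.

    With the default ``orientation="as-printed"`` this is the diagonal
    count over the *reference-row* sum; ``"conventional"`` normalizes over
    the predicted column instead.  Returns NaN when the normalizing
    marginal is zero.
    """
    i = m._index(pattern)
    if orientation == "as-printed":
        denom = m.counts[i, :].sum()
    elif orientation == "conventional":
        denom = m.counts[:, i].sum()
    else:
        raise ValueError("orientation must be 'as-printed' or 'conventional'")
    if denom == 0:
        return math.nan
    return float(m.counts[i, i] / denom)


def recall(m: ConfusionMatrix, pattern: str,
           orientation: str = "as-printed") -> float:
    """Per-pattern recall (column-normalized under the default orientation)."""
    other = "conventional" if orientation == "as-printed" else "as-printed"
    if orientation not in ("as-printed", "conventional"):
        raise ValueError("orientation must be 'as-printed' or 'conventional'")
    return precision(m, pattern, orientation=other)


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if math.isnan(p) or math.isnan(r):
        return math.nan
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p == 0.0 and r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def pattern_confusion(m: ConfusionMatrix, pattern: str) -> float:
    """Fraction of reference samples of ``pattern`` assigned elsewhere."""
    p = precision(m, pattern, orientation="as-printed")
    return math.nan if math.isnan(p) else 1.0 - p


def indices_table(m: ConfusionMatrix, orientation: str = "as-printed") -> pd.DataFrame:
    """Precision, recall and F-score for every pattern in the matrix."""
    rows = []
    for lab in m.labels:
        p = precision(m, lab, orientation)
        r = recall(m, lab, orientation)
        rows.append({"pattern": lab, "precision": p, "recall": r,
                     "f_score": f_score(p, r)})
    return pd.DataFrame(rows).set_index("pattern")


# --- event-level analysis ---------------------------------------------

@dataclass(frozen=True)
class EventSegment:
    """Maximal run of identical labels: [start, start + length)."""

    label: str
    start: int
    length: int
    duration: float  # seconds


def segment_events(pseq: PatternSequence, fs: float) -> list[EventSegment]:
    """Run-length encode a pattern sequence into maximal events."""
    labels = pseq.labels
    if fs <= 0:
        raise ValueError("fs must be > 0")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [
        EventSegment(label=str(labels[s]), start=int(s), length=int(e - s),
                     duration=(e - s) / fs)
        for s, e in zip(starts, ends)
    ]


def reconstruct(segments: list[EventSegment]) -> PatternSequence:
    """Inverse of :func:`segment_events` (segments must tile the axis)."""
    n = sum(s.length for s in segments)
    labels = np.empty(n, dtype="U7")
    for s in segments:
        labels[s.start : s.start + s.length] = s.label
    return PatternSequence(labels=labels)


def fragmentation_histogram(
    segments: list[EventSegment],
    bin_edges: np.ndarray | list[float],
) -> pd.DataFrame:
    """Count events per (pattern, length bin).

    ``bin_edges`` are event lengths in samples; bins are half-open
    ``[edge[i], edge[i+1])`` with the final bin inclusive of the right
    edge.  Rows are patterns, columns bin labels.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    patterns = sorted({s.label for s in segments})
    cols = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(edges.size - 1)]
    table = pd.DataFrame(0, index=patterns, columns=cols, dtype=int)
    for pat in patterns:
        lengths = np.array([s.length for s in segments if s.label == pat])
        hist, _ = np.histogram(lengths, bins=edges)
        table.loc[pat] = hist
    return table


def pattern_matching(
    ref_segments: list[EventSegment],
    pred_pseq: PatternSequence,
    fs: float,
    min_duration_s: float = 2.0,
    overlap_threshold: float = 0.5,
) -> dict[str, float]:
    """Fraction of long reference events the prediction substantially matches.

    For every reference event of duration >= ``min_duration_s`` the overlap
    is the fraction of its samples the prediction labels identically; the
    event counts as matched when the overlap is strictly greater than
    ``overlap_threshold``.  Returns the matched fraction per pattern plus
    an ``"overall"`` entry; patterns with no qualifying events are NaN.
    """
    n = pred_pseq.n_samples
    span = max((s.start + s.length for s in ref_segments), default=0)
    if span != n:
        raise ValueError(
            f"axis mismatch: reference segments span {span} samples, "
            f"prediction has {n}"
        )
    matched: dict[str, list[bool]] = {}
    for seg in ref_segments:
        if seg.duration < min_duration_s:
            continue
        window = pred_pseq.labels[seg.start : seg.start + seg.length]
        overlap = float(np.mean(window == seg.label))
        matched.setdefault(seg.label, []).append(overlap > overlap_threshold)
    out: dict[str, float] = {}
    all_events: list[bool] = []
    for pat, hits in sorted(matched.items()):
        out[pat] = float(np.mean(hits))
        all_events.extend(hits)
    out["overall"] = float(np.mean(all_events)) if all_events else math.nan
    return out
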