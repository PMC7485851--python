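"""Sliding-window primitives shared by the metric computations.

Centered windows are rectangular and symmetric with odd width ``N``;
at the record edges the window shrinks symmetrically so that the output
stays index-aligned with the input (the half-width at sample ``n`` is
``min((N-1)/2, n, len-1-n)``).  Trailing windows cover the most recent
``N`` samples up to and including the current one, using whatever is
available near the start of the record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _effective_half(n: int, half: int) -> np.ndarray:
    idx = np.arange(n)
    return np.minimum(half, np.minimum(idx, n - 1 - idx))


def centered_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with odd ``width``, symmetric edge shrink."""
    if width % 2 == 0 or width < 1:
        raise ValueError("centered window width must be a positive odd integer")
    x = np.asarray(x, dtype=float)
    n = x.size
    half = (width - 1) // 2
    h = _effective_half(n, half)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    return (cs[idx + h + 1] - cs[idx - h]) / (2 * h + 1)


def centered_mean_square(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average of ``x**2`` (window as in :func:`centered_mean`)."""
    return centered_mean(np.square(np.asarray(x, dtype=float)), width)


def trailing_quantile(x: np.ndarray, width: int, q: float) -> np.ndarray:
    """Quantile of the most recent ``width`` samples (inclusive of current).

    Near the start of the record the quantile is taken over all samples
    available so far.  Linear interpolation between order statistics.
    """
    if width < 1:
        raise ValueError("trailing window width must be >= 1")
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must lie strictly in (0, 1)")
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window=width, min_periods=1).quantile(q).to_numpy()
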