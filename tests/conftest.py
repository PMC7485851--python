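"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from aurea import generate_study_like_record, merge_patterns
from aurea.classifier import classify, train_aurea
from aurea.config import AnalysisConfig
from aurea.metrics import compute_metrics

# --- brute-force loop oracles for windowed statistics -----------------

def oracle_centered_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Loop recomputation of the centered mean with symmetric edge shrink."""
    n = x.size
    half = (width - 1) // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.mean(x[i - h : i + h + 1])
    return out


def oracle_trailing_quantile(x: np.ndarray, width: int, q: float) -> np.ndarray:
    """Loop recomputation of the trailing quantile over available samples."""
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - width + 1)
        out[i] = np.quantile(x[lo : i + 1], q)
    return out


# --- expensive end-to-end fixture, computed once per session ----------

ROUNDTRIP_SEED = 7       # record generation
TRAIN_SEED = 0           # k-means initialization
ROUNDTRIP_DURATION_S = 1200.0


@pytest.fixture(scope="session")
def study_roundtrip():
    """Default study-like record -> metrics -> trained model -> prediction.

    Returned as a dict so the classifier, synthetic-data and acceptance
    tests can share one (relatively costly) pipeline run.
    """
    synth = generate_study_like_record(
        total_duration_s=ROUNDTRIP_DURATION_S, fs=50.0, seed=ROUNDTRIP_SEED
    )
    cfg = AnalysisConfig()
    metrics = compute_metrics(synth.record, cfg)
    model = train_aurea(metrics, cfg=cfg, seed=TRAIN_SEED)
    pred = classify(metrics, model)
    return {
        "synth": synth,
        "metrics": metrics,
        "model": model,
        "pred": pred,
        "ref_merged": merge_patterns(synth.truth),
        "pred_merged": merge_patterns(pred),
    }
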