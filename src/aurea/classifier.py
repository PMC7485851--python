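"""Four-stage cascade of binary k-means pattern detectors.

Training clusters the pooled metric samples in two groups per stage and
identifies the target cluster by a fixed polarity rule (pauses have the
lower normalized variance, movement the higher nonperiodic power,
synchronous breathing the higher half-sum power, asynchronous breathing
the higher half-difference power).  Because the patterns are heavily
unbalanced — pauses are rare, synchronous breathing covers most of a
record — the conventional midpoint decision boundary misassigns samples
of the prevalent cluster; after convergence the boundary is re-anchored
at the fraction ``w = n_target / (n_target + n_anti)`` along the
inter-centroid vector, so that the cluster holding more training samples
covers more of the metric space.

Classification walks each sample down the fixed stage order
PAU -> MVT -> SYB -> ASB; the first detector that claims the sample ends
the walk, and samples rejected by all four are labeled UNK.  Pauses are
tested first because their near-zero power makes every other metric
unreliable; movement is tested next because its low-frequency power
biases the synchrony metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .config import AnalysisConfig
from .metrics import MetricSet
from .record import PatternSequence

MODEL_SCHEMA_VERSION = 1

#: stage name -> (feature names, polarity sign).  polarity +1 means the
#: target cluster has the HIGHER centroid mean over its features, -1 lower.
STAGE_DEFS: dict[str, tuple[tuple[str, ...], int]] = {
    "PAU": (("nv_rcg", "nv_abd"), -1),
    "MVT": (("npp_rcg", "npp_abd"), +1),
    "SYB": (("b_plus",), +1),
    "ASB": (("b_minus",), +1),
}

STAGE_ORDER = ("PAU", "MVT", "SYB", "ASB")


@dataclass
class KMeansStage:
    """One trained binary detector: centroids, counts and boundary weight."""

    name: str
    features: tuple[str, ...]
    c_target: np.ndarray
    c_anti: np.ndarray
    n_target: int
    n_anti: int
    w: float = 0.5

    def __post_init__(self) -> None:
        self.c_target = np.asarray(self.c_target, dtype=float)
        self.c_anti = np.asarray(self.c_anti, dtype=float)
        if self.c_target.shape != self.c_anti.shape:
            raise ValueError("centroids must have identical dimensionality")
        if np.allclose(self.c_target, self.c_anti):
            raise ValueError(f"degenerate training for stage {self.name}: "
                             "target and anti centroids coincide")
        if not 0.0 < self.w < 1.0:
            raise ValueError("boundary weighting factor must lie in (0, 1)")

    @property
    def normal(self) -> np.ndarray:
        """Hyperplane normal, pointing from target to anti centroid."""
        return self.c_anti - self.c_target

    @property
    def anchor(self) -> np.ndarray:
        """Point on the decision hyperplane."""
        return self.w * self.normal + self.c_target


def assign(x: np.ndarray, stage: KMeansStage) -> np.ndarray:
    """Assign points to the stage's target class (True) or anti class.

    A point belongs to the target class iff the signed projection onto the
    inter-centroid direction falls strictly on the target side of the
    boundary anchor; points exactly on the hyperplane go to the anti class.
    Accepts a single point or an (n, p) array.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != stage.c_target.size:
        raise ValueError(
            f"stage {stage.name} expects {stage.c_target.size} features, "
            f"got {x.shape[1]}"
        )
    proj = (x - stage.anchor) @ stage.normal
    return proj < 0.0


def adjust_boundary(stage: KMeansStage) -> KMeansStage:
    """Re-anchor the boundary at the cluster-size fraction; centroids fixed."""
    total = stage.n_target + stage.n_anti
    if total == 0:
        raise ValueError("cannot adjust boundary with zero training samples")
    return replace(stage, w=stage.n_target / total)


def train_stage(
    data: np.ndarray,
    name: str,
    features: tuple[str, ...],
    polarity: int,
    seed: int | None = None,
) -> KMeansStage:
    """Fit a two-cluster k-means and orient/adjust it for one detector.

    The cluster whose centroid mean over the stage features matches the
    polarity (lower for pauses, higher otherwise) becomes the target class.
    The boundary is then shifted to reflect the relative cluster sizes.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError(f"stage {name}: need at least 2 training points")
    if np.allclose(data, data[0]):
        raise ValueError(f"stage {name}: degenerate training, all points identical")
    km = KMeans(
        n_clusters=2,
        n_init=10,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(data)
    means = km.cluster_centers_.mean(axis=1)
    target_idx = int(np.argmin(means)) if polarity < 0 else int(np.argmax(means))
    anti_idx = 1 - target_idx
    counts = np.bincount(km.labels_, minlength=2)
    stage = KMeansStage(
        name=name,
        features=features,
        c_target=km.cluster_centers_[target_idx],
        c_anti=km.cluster_centers_[anti_idx],
        n_target=int(counts[target_idx]),
        n_anti=int(counts[anti_idx]),
    )
    return adjust_boundary(stage)


@dataclass
class AureaModel:
    """Frozen parameters of the four-stage cascade."""

    stages: list[KMeansStage]
    cfg: AnalysisConfig
    fs: float
    seed: int | None = None

    def __post_init__(self) -> None:
        names = tuple(s.name for s in self.stages)
        if names != STAGE_ORDER:
            raise ValueError(f"stage order must be {STAGE_ORDER}, got {names}")

    def stage(self, name: str) -> KMeansStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    # --- serialization (versioned JSON schema) -------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "fs": self.fs,
            "seed": self.seed,
            "cfg": self.cfg.to_dict(),
            "stages": [
                {
                    "name": s.name,
                    "features": list(s.features),
                    "c_target": s.c_target.tolist(),
                    "c_anti": s.c_anti.tolist(),
                    "n_target": s.n_target,
                    "n_anti": s.n_anti,
                    "w": s.w,
                }
                for s in self.stages
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "AureaModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version: {d.get('schema_version')!r}"
            )
        stages = [
            KMeansStage(
                name=s["name"],
                features=tuple(s["features"]),
                c_target=np.array(s["c_target"], dtype=float),
                c_anti=np.array(s["c_anti"], dtype=float),
                n_target=int(s["n_target"]),
                n_anti=int(s["n_anti"]),
                w=float(s["w"]),
            )
            for s in d["stages"]
        ]
        return cls(
            stages=stages,
            cfg=AnalysisConfig.from_dict(d["cfg"]),
            fs=float(d["fs"]),
            seed=d.get("seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "AureaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_aurea(
    metrics: MetricSet | list[MetricSet],
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
    use_valid_only: bool = True,
) -> AureaModel:
    """Train the cascade on one or more metric sets (pooled).

    Each stage is fit on the samples every earlier stage rejected: the
    pause detector sees everything, the movement detector sees everything
    that is not a pause, and so on.  Samples whose analysis windows are
    not fully supported are excluded from training by default (they still
    receive labels at classification time).
    """
    metric_sets = metrics if isinstance(metrics, list) else [metrics]
    if not metric_sets:
        raise ValueError("no training metrics supplied")
    cfg = cfg or AnalysisConfig()
    fs = metric_sets[0].fs

    pooled: dict[str, np.ndarray] = {}
    for name in MetricSet._FEATURES:
        pooled[name] = np.concatenate([getattr(m, name) for m in metric_sets])
    if use_valid_only:
        mask = np.concatenate([m.valid_mask for m in metric_sets])
        if not mask.any():
            raise ValueError("no fully-supported samples available for training")
        pooled = {k: v[mask] for k, v in pooled.items()}

    remaining = np.ones(next(iter(pooled.values())).size, dtype=bool)
    stages: list[KMeansStage] = []
    for name in STAGE_ORDER:
        features, polarity = STAGE_DEFS[name]
        data = np.column_stack([pooled[f] for f in features])[remaining]
        if data.shape[0] < 2:
            raise ValueError(
                f"stage {name}: fewer than 2 samples left to train on "
                "(an earlier stage consumed the training set)"
            )
        stage = train_stage(data, name, features, polarity, seed=seed)
        stages.append(stage)
        # remove target-assigned samples from the pool for later stages
        idx = np.flatnonzero(remaining)
        hit = assign(data, stage)
        remaining[idx[hit]] = False
        if not remaining.any() and name != STAGE_ORDER[-1]:
            raise ValueError(
                f"stage {name} consumed every remaining training sample"
            )

    return AureaModel(stages=stages, cfg=cfg, fs=fs, seed=seed)


def classify(metrics: MetricSet, model: AureaModel) -> PatternSequence:
    """Label every sample by the first cascade stage that claims it."""
    n = metrics.n_samples
    labels = np.full(n, "UNK", dtype="U7")
    unassigned = np.ones(n, dtype=bool)
    for stage in model.stages:
        if not unassigned.any():
            break
        x = metrics.feature_matrix(stage.features)[unassigned]
        hit = assign(x, stage)
        idx = np.flatnonzero(unassigned)
        labels[idx[hit]] = stage.name
        unassigned[idx[hit]] = False
    return PatternSequence(labels=labels)
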