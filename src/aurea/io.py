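"""Readers and writers for signals, metrics, pattern sequences and configs.

Delimited files are comma-separated UTF-8 with one header row; the sample
index is implicit in row order and 0-based everywhere.  EDF records are
read through :mod:`mne` (imported lazily so the dependency stays optional).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig
from .metrics import MetricSet
from .record import ALL_LABELS, PatternSequence, RIPRecord


class ValidationError(ValueError):
    """Input failed a semantic check (CLI exit code 2)."""


class InputError(OSError):
    """File missing or unparseable (CLI exit code 3)."""


# --- signals -----------------------------------------------------------

def read_signals(
    path: str | Path,
    fmt: str = "delimited",
    channel_map: dict[str, str] | None = None,
    fs: float | None = None,
) -> RIPRecord:
    """Read a two-channel RIP record.

    ``channel_map`` maps the roles ``"rcg"`` / ``"abd"`` to column names
    (delimited) or channel labels (EDF); defaults to ``rcg`` / ``abd``.
    ``fs`` overrides file metadata; delimited files without a ``time``
    column require it.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    channel_map = channel_map or {"rcg": "rcg", "abd": "abd"}
    if fmt == "delimited":
        return _read_delimited(path, channel_map, fs)
    if fmt == "edf":
        return _read_edf(path, channel_map, fs)
    raise ValidationError(f"unsupported signal format {fmt!r}")


def _read_delimited(path: Path, channel_map: dict[str, str],
                    fs: float | None) -> RIPRecord:
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise InputError(f"cannot parse {path}: {e}") from e
    for role in ("rcg", "abd"):
        col = channel_map.get(role, role)
        if col not in df.columns:
            raise ValidationError(
                f"missing channel: column {col!r} (role {role}) "
                f"not in {list(df.columns)}"
            )
    if fs is None:
        if "time" not in df.columns or len(df) < 2:
            raise ValidationError(
                "sampling rate unknown: provide fs or a 'time' column"
            )
        dt = np.diff(df["time"].to_numpy())
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValidationError("'time' column is not uniformly increasing")
        fs = 1.0 / float(dt[0])
    try:
        return RIPRecord(
            rcg=df[channel_map.get("rcg", "rcg")].to_numpy(dtype=float),
            abd=df[channel_map.get("abd", "abd")].to_numpy(dtype=float),
            fs=fs,
        )
    except ValueError as e:
        raise ValidationError(str(e)) from e


def _read_edf(path: Path, channel_map: dict[str, str],
              fs: float | None) -> RIPRecord:
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise InputError("EDF support requires the 'mne' package") from e
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as e:
        raise InputError(f"cannot parse EDF file {path}: {e}") from e
    channels = {}
    for role in ("rcg", "abd"):
        label = channel_map.get(role, role)
        if label not in raw.ch_names:
            raise ValidationError(
                f"missing channel: EDF label {label!r} (role {role}) "
                f"not in {raw.ch_names}"
            )
        channels[role] = raw.get_data(picks=[label])[0]
    try:
        return RIPRecord(rcg=channels["rcg"], abd=channels["abd"],
                         fs=fs if fs is not None else float(raw.info["sfreq"]))
    except ValueError as e:
        raise ValidationError(str(e)) from e


def write_signals(path: str | Path, record: RIPRecord) -> None:
    df = pd.DataFrame({
        "time": record.time,
        "rcg": record.rcg,
        "abd": record.abd,
    })
    df.to_csv(path, index=False)


# --- pattern sequences -------------------------------------------------

def read_pseq(path: str | Path) -> PatternSequence:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValidationError(f"{path}: empty pattern-sequence file")
        cols = [c.strip() for c in header.strip().split(",")]
        if "label" not in cols:
            raise ValidationError(f"{path}: header must contain a 'label' column")
        li = cols.index("label")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [c.strip() for c in line.strip().split(",")]
            if len(fields) <= li:
                raise ValidationError(f"{path}:{lineno}: too few columns")
            token = fields[li]
            if token not in ALL_LABELS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown pattern label {token!r}"
                )
            labels.append(token)
    if not labels:
        raise ValidationError(f"{path}: no samples in pattern-sequence file")
    return PatternSequence(labels=np.array(labels, dtype="U7"))


def write_pseq(path: str | Path, pseq: PatternSequence) -> None:
    df = pd.DataFrame({
        "sample_index": np.arange(pseq.n_samples),
        "label": pseq.labels,
    })
    df.to_csv(path, index=False)


# --- metrics and config ------------------------------------------------

def write_metrics(path: str | Path, metrics: MetricSet) -> None:
    metrics.to_frame().to_csv(path, index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        raise InputError(f"cannot parse config {path}: {e}") from e
    try:
        return AnalysisConfig.from_dict(data)
    except (TypeError, ValueError) as e:
        raise ValidationError(f"invalid config {path}: {e}") from e


def write_config(path: str | Path, cfg: AnalysisConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
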