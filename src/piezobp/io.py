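"""File formats: delimited-text waveforms with structured-text sidecars.

A recording is stored as a CSV of (t_s, ch1_V, ch2_V) plus a YAML
sidecar (same stem, ``.yaml``) holding the sampling rate, sensor
spacing, subject metadata, seed and — for synthetic recordings — the
scalar ground-truth block.  Feature tables are plain CSV; trained
models are serialized with joblib (the one binary format used).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import joblib
import pandas as pd
import yaml

from .errors import DataError
from .simkit import PiezoRecording, SubjectRecord

__all__ = [
    "write_recording",
    "read_recording",
    "write_features",
    "read_features",
    "save_model",
    "load_model",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".yaml")


def write_recording(rec: PiezoRecording, csv_path: str | Path) -> Path:
    """Write the two-channel recording and its metadata sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"t_s": rec.t, "ch1_V": rec.ch1, "ch2_V": rec.ch2}).to_csv(
        csv_path, index=False, float_format="%.8g"
    )
    truth_scalars = {
        k: v for k, v in rec.truth.items() if isinstance(v, (int, float, dict))
    }
    sidecar = {
        "fs_hz": float(rec.fs),
        "spacing_m": float(rec.spacing_m),
        "seed": int(rec.seed),
        "subject": asdict(rec.subject),
        "ground_truth": truth_scalars,
    }
    _sidecar_path(csv_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return csv_path


def read_recording(csv_path: str | Path) -> PiezoRecording:
    """Load a recording written by :func:`write_recording`."""
    csv_path = Path(csv_path)
    sidecar_file = _sidecar_path(csv_path)
    if not sidecar_file.exists():
        raise DataError(f"missing metadata sidecar {sidecar_file}")
    meta = yaml.safe_load(sidecar_file.read_text())
    df = pd.read_csv(csv_path)
    for col in ("ch1_V", "ch2_V"):
        if col not in df.columns:
            raise DataError(f"recording file lacks column {col!r}")
    subject = SubjectRecord(**meta["subject"])
    return PiezoRecording(
        ch1=df["ch1_V"].to_numpy(float),
        ch2=df["ch2_V"].to_numpy(float),
        fs=float(meta["fs_hz"]),
        spacing_m=float(meta["spacing_m"]),
        subject=subject,
        seed=int(meta["seed"]),
        truth=meta.get("ground_truth", {}),
    )


def write_features(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.8g")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump(model, path)
    return path


def load_model(path: str | Path):
    return joblib.load(path)
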