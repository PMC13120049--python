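"""Serialization: recording bundles (CSV + JSON sidecar), window sets
(NPZ + JSON), feature matrices (CSV with provenance-encoding header), and
result/summary tables (headered CSV)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .preprocess import WindowSet
from .synth import GeneratorConfig, Recording


def _bundle_name(recording: Recording) -> str:
    return f"{recording.subject_id}_{recording.session_id}"


def save_recording_bundle(
    recording: Recording, out_dir: str | Path, config: GeneratorConfig | None = None
) -> Path:
    """One CSV per recording (sample, ch1..chN, label) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _bundle_name(recording)
    df = pd.DataFrame(recording.signal.T, columns=recording.channel_names)
    df.insert(0, "sample", np.arange(recording.n_samples))
    df["label"] = recording.label_stream
    df.to_csv(out_dir / f"{stem}.csv", index=False)
    meta = {
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "fs": recording.fs,
        "channel_names": recording.channel_names,
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["gesture_labels"] = list(cfg["gesture_labels"])
        cfg["band"] = list(cfg["band"])
        meta["generator_config"] = cfg
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return out_dir / f"{stem}.csv"


def load_recording_bundle(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    channels = meta["channel_names"]
    return Recording(
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        fs=meta["fs"],
        signal=df[channels].to_numpy().T,
        label_stream=df["label"].to_numpy(),
        channel_names=list(channels),
    )


def save_cohort(
    recordings: list[Recording], out_dir: str | Path, config: GeneratorConfig | None = None
) -> list[Path]:
    return [save_recording_bundle(r, out_dir, config) for r in recordings]


def load_cohort(in_dir: str | Path) -> list[Recording]:
    paths = sorted(Path(in_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recording bundles under {in_dir}")
    return [load_recording_bundle(p) for p in paths]


def save_window_set(ws: WindowSet, path: str | Path) -> None:
    """NPZ container with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, windows=ws.windows, labels=ws.labels)
    meta = {
        "L": ws.L,
        "H": ws.H,
        "fs": ws.fs,
        "provenance": ws.provenance.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_window_set(path: str | Path) -> WindowSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    return WindowSet(
        windows=data["windows"],
        labels=data["labels"],
        L=meta["L"],
        H=meta["H"],
        fs=meta["fs"],
        provenance=pd.DataFrame(meta["provenance"]),
    )


def _encode_column(col: tuple[int, str, int]) -> str:
    ch, feat, comp = col
    return f"ch{ch}:{feat}:{comp}"


def _decode_column(name: str) -> tuple[int, str, int]:
    ch, feat, comp = name.split(":")
    return int(ch[2:]), feat, int(comp)


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV whose header encodes (channel, feature, component) per column."""
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=[_encode_column(c) for c in fm.column_names])
    df["label"] = fm.labels
    if len(fm.groups):
        df["subject"] = fm.groups["subject"].to_numpy()
        df["session"] = fm.groups["session"].to_numpy()
    df.to_csv(path, index=False)


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("ch") and ":" in c]
    groups = (
        df[["subject", "session"]].reset_index(drop=True)
        if "subject" in df.columns
        else pd.DataFrame()
    )
    return FeatureMatrix(
        values=df[feat_cols].to_numpy(),
        column_names=[_decode_column(c) for c in feat_cols],
        labels=df["label"].to_numpy(),
        groups=groups,
    )
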