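"""Recording-bundle reader/writer and raw-sample normalization.

A bundle is a directory with a ``manifest.json`` and one CSV per
repetition (header ``ch1..ch8``, one row per sample, floats in
[-1, 1]).  The manifest lists, per repetition, the sample file, gesture
label, ground-truth interval and sampling rate, plus per-user metadata.
File naming is deterministic (``<user_id>/<repetition_id>.csv``) and no
timestamps are stored, so writing the same recordings twice produces
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import N_PODS, EmgRecording, GestureClass

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"
RAW_MIN, RAW_MAX = -128, 127


class BundleFormatError(ValueError):
    """Malformed recording bundle (missing files, wrong shapes...)."""


def normalize_samples(raw: np.ndarray) -> np.ndarray:
    """Scale signed 8-bit ADC counts in [-128, 127] to floats in [-1, 1].

    Division by 128 keeps -1 attainable; the maximum output is
    127/128 ~= 0.9922.
    """
    raw = np.asarray(raw)
    if raw.size and (raw.min() < RAW_MIN or raw.max() > RAW_MAX):
        raise ValueError(f"raw samples outside [{RAW_MIN}, {RAW_MAX}]")
    return raw / 128.0


def write_recording_bundle(
    recordings: Iterable[EmgRecording], path: str | Path
) -> dict:
    """Write recordings to ``path`` and return the manifest dict."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    recordings = list(recordings)
    users: dict[str, dict] = {}
    for rec in recordings:
        rec.validate()
        entry = users.setdefault(rec.user_id, {"user_id": rec.user_id, "repetitions": []})
        rel = f"{rec.user_id}/{rec.repetition_id}.csv"
        file_path = path / rel
        file_path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            rec.samples.T, columns=[f"ch{i}" for i in range(1, N_PODS + 1)]
        )
        df.to_csv(file_path, index=False, float_format="%.17g", lineterminator="\n")
        entry["repetitions"].append(
            {
                "file": rel,
                "label": rec.label.value,
                "gt_on": rec.ground_truth[0],
                "gt_off": rec.ground_truth[1],
                "rate": rec.rate,
            }
        )
    manifest = {"users": [users[k] for k in sorted(users)]}
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    n = sum(len(u["repetitions"]) for u in manifest["users"])
    log.info("wrote bundle %s: %d users, %d repetitions", path, len(users), n)
    return manifest


def read_recording_bundle(path: str | Path) -> list[EmgRecording]:
    """Read every repetition of a bundle, validating shapes and ranges."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.is_file():
        raise BundleFormatError(f"missing {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    recordings: list[EmgRecording] = []
    for user in manifest.get("users", []):
        user_id = user["user_id"]
        for rep in user["repetitions"]:
            file_path = path / rep["file"]
            if not file_path.is_file():
                raise BundleFormatError(f"manifest references missing file {rep['file']}")
            df = pd.read_csv(file_path, float_precision="round_trip")
            if df.shape[1] != N_PODS:
                raise BundleFormatError(
                    f"{rep['file']}: expected {N_PODS} channel columns, got {df.shape[1]}"
                )
            samples = df.to_numpy(dtype=float).T
            if samples.size and (samples.min() < -1.0 or samples.max() > 1.0):
                raise BundleFormatError(f"{rep['file']}: samples outside [-1, 1]")
            recordings.append(
                EmgRecording(
                    samples=samples,
                    label=GestureClass(rep["label"]),
                    ground_truth=(rep["gt_on"], rep["gt_off"]),
                    user_id=user_id,
                    repetition_id=Path(rep["file"]).stem,
                    rate=rep.get("rate", 200),
                )
            )
    log.info("read bundle %s: %d repetitions", path, len(recordings))
    return recordings


def group_by_user(recordings: Sequence[EmgRecording]) -> dict[str, list[EmgRecording]]:
    out: dict[str, list[EmgRecording]] = {}
    for rec in recordings:
        out.setdefault(rec.user_id, []).append(rec)
    return out
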