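"""Plain-text readers and writers for pipeline artifacts.

Recordings are stored one per CSV file: ``# key=value`` comment headers for
the metadata, then one velocity sample (cm/s) per line.  Generator ground
truth, when present, goes to a sibling ``<stem>.truth.json``.  Normalized
beats and features travel as flat CSV tables; clustering output as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureMatrix
from .pipeline import N_SAMPLES, NormalizedBeat, Provenance, RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_beats",
    "read_beats",
    "write_features",
    "read_features",
]

_SAMPLE_COLS = [f"s{i:03d}" for i in range(N_SAMPLES)]


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write one recording CSV (+ ``.truth.json`` sidecar if ground truth)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# subject_id={rec.subject_id} group={rec.group} "
            f"hemisphere={rec.hemisphere} depth_mm={rec.depth_mm:.2f} "
            f"fs_hz={rec.fs:g}\n"
        )
        for v in rec.samples:
            fh.write(f"{v:.6f}\n")
    if rec.ground_truth is not None:
        truth_path = path.with_suffix(".truth.json")
        with open(truth_path, "w") as fh:
            json.dump(rec.ground_truth, fh)
    return path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        samples = np.array([float(line) for line in fh if line.strip()])
    truth_path = path.with_suffix(".truth.json")
    truth = None
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return RawRecording(
        samples=samples,
        fs=float(meta["fs_hz"]),
        subject_id=meta["subject_id"],
        group=meta["group"],
        hemisphere=meta["hemisphere"],
        depth_mm=float(meta["depth_mm"]),
        ground_truth=truth,
    )


def write_beats(beats: list[NormalizedBeat], path: str | Path) -> Path:
    """Normalized beats as one CSV row each: provenance + 100 sample columns."""
    rows = []
    for b in beats:
        p = b.provenance or Provenance("anon", "", "", float("nan"))
        row = p.as_dict()
        row.update(dict(zip(_SAMPLE_COLS, b.samples)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_beats(path: str | Path) -> list[NormalizedBeat]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        nb = row.get("n_beats_used")
        prov = Provenance(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            hemisphere=str(row["hemisphere"]),
            depth_mm=float(row["depth_mm"]),
            n_beats_used=None if pd.isna(nb) else int(nb),
        )
        out.append(
            NormalizedBeat(samples=row[_SAMPLE_COLS].to_numpy(float), provenance=prov)
        )
    return out


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    fm.to_frame().to_csv(path, index=False)
    return Path(path)


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    values = df[list(FEATURE_NAMES)].to_numpy(float)
    prov = df.drop(columns=list(FEATURE_NAMES))
    return FeatureMatrix(values=values, provenance=prov)
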