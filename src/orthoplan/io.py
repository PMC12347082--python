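"""Readers and writers for landmark files, cohort tables and manifests.

Landmark files are plain CSV with the header
``patient_id,timepoint,segment,landmark,x_mm,y_mm,z_mm`` preceded by a
frame comment line declaring the canonical patient frame; a JSON twin
with the same schema is emitted alongside.  Coordinates are always in
millimetres.  Readers refuse files whose frame tag does not match, since
all downstream sign conventions depend on it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .triangles import LandmarkSet, SchemaError

__all__ = [
    "FRAME_TAG",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_landmarks_json",
    "read_landmarks_json",
    "write_cohort_csv",
    "read_cohort_csv",
]

FRAME_TAG = "canonical_patient(+X=left,+Y=anterior,+Z=cranial);units=mm"
_HEADER = ["patient_id", "timepoint", "segment", "landmark", "x_mm", "y_mm", "z_mm"]


def _landmark_rows(landmark_sets) -> pd.DataFrame:
    rows = []
    for ls in landmark_sets:
        for name, p in ls.landmarks.items():
            rows.append({
                "patient_id": ls.patient_id, "timepoint": ls.timepoint,
                "segment": ls.segment, "landmark": name,
                "x_mm": p[0], "y_mm": p[1], "z_mm": p[2],
            })
    return pd.DataFrame(rows, columns=_HEADER)


def _sets_from_frame(df: pd.DataFrame) -> list[LandmarkSet]:
    missing = set(_HEADER) - set(df.columns)
    if missing:
        raise SchemaError(f"landmark table missing columns: {sorted(missing)}")
    out = []
    for (pid, tp, seg), grp in df.groupby(
        ["patient_id", "timepoint", "segment"], sort=True
    ):
        landmarks = {
            str(r.landmark): np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float)
            for r in grp.itertuples()
        }
        out.append(LandmarkSet(str(pid), str(tp), str(seg), landmarks))
    return out


def write_landmarks_csv(landmark_sets, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# frame: {FRAME_TAG}\n")
        _landmark_rows(landmark_sets).to_csv(fh, index=False, lineterminator="\n")


def read_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# frame:") or FRAME_TAG not in first.replace(" ", ""):
            raise SchemaError(
                f"{path}: missing or mismatched frame tag; expected '# frame: {FRAME_TAG}'"
            )
        df = pd.read_csv(fh)
    return _sets_from_frame(df)


def write_landmarks_json(landmark_sets, path: str | Path) -> None:
    payload = {
        "frame": FRAME_TAG,
        "landmarks": _landmark_rows(landmark_sets).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_landmarks_json(path: str | Path) -> list[LandmarkSet]:
    payload = json.loads(Path(path).read_text())
    if payload.get("frame", "").replace(" ", "") != FRAME_TAG:
        raise SchemaError(f"{path}: missing or mismatched frame tag")
    return _sets_from_frame(pd.DataFrame(payload["landmarks"]))


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("sarme", "extraction_maxilla", "extraction_mandible"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df
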