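"""Virtual landmark triangles and the six clinical metrics per segment.

Each osteotomized segment is represented by a triangle spanned by three
named anatomical landmarks:

======================  =======================================  ==============
segment                 landmarks (right, midline, left)          meaning
======================  =======================================  ==============
``dental_maxilla``      16, UI, 26                               upper arch
``dental_mandible``     46, LI, 36                               lower arch
``bony_mandible``       MF_R, Pog, MF_L                          distal segment
======================  =======================================  ==============

16/26/36/46 are FDI first-molar numbers (mesio-buccal cusps), UI/LI the
midline incisor points, Pog the pogonion and MF_R/MF_L the mental
foramina.  The triangle is a rigid proxy for the segment: the rigid
transform that superimposes the pretreatment (T0) triangle onto the
presurgical (T1) triangle captures the segment's full 6-DOF plan
difference, which is then expressed as pitch/roll/yaw (degrees) and
left-right / antero-posterior / cranio-caudal translations (mm) of the
T0 triangle centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    GeometryError,
    RigidTransform,
    decompose_to_clinical_angles,
    kabsch_rigid,
)

__all__ = [
    "SEGMENTS",
    "SEGMENT_LANDMARKS",
    "PARAMETERS",
    "SchemaError",
    "LandmarkSet",
    "Triangle",
    "ClinicalMetrics",
    "build_triangle",
    "triangle_transform",
    "to_clinical_metrics",
    "measure_patient",
]

#: Canonical landmark order per segment: right-side, midline, left-side.
SEGMENT_LANDMARKS: dict[str, tuple[str, str, str]] = {
    "dental_maxilla": ("16", "UI", "26"),
    "dental_mandible": ("46", "LI", "36"),
    "bony_mandible": ("MF_R", "Pog", "MF_L"),
}

SEGMENTS: tuple[str, ...] = tuple(SEGMENT_LANDMARKS)

#: Metric column order used throughout reports: rotations then translations.
PARAMETERS: tuple[str, ...] = ("pitch", "roll", "yaw", "trans_lr", "trans_ap", "trans_ud")

ROTATION_PARAMETERS: tuple[str, ...] = PARAMETERS[:3]
TRANSLATION_PARAMETERS: tuple[str, ...] = PARAMETERS[3:]

TIMEPOINTS = ("T0", "T1")

#: Triangles with area at or below this (mm^2) are degenerate.
MIN_TRIANGLE_AREA = 1e-6


class SchemaError(ValueError):
    """Landmark data does not match the required segment schema."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D landmarks for one patient / timepoint / segment (mm)."""

    patient_id: str
    timepoint: str
    segment: str
    landmarks: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise SchemaError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if self.segment not in SEGMENT_LANDMARKS:
            raise SchemaError(
                f"unknown segment {self.segment!r}; expected one of {sorted(SEGMENT_LANDMARKS)}"
            )
        required = set(SEGMENT_LANDMARKS[self.segment])
        got = set(self.landmarks)
        if got != required:
            raise SchemaError(
                f"segment {self.segment!r} requires landmarks {sorted(required)}, got {sorted(got)}"
            )
        clean = {}
        for name, p in self.landmarks.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = arr
        object.__setattr__(self, "landmarks", clean)

    def ordered_points(self) -> np.ndarray:
        """Landmarks as a (3, 3) array in canonical (right, mid, left) order."""
        return np.array([self.landmarks[n] for n in SEGMENT_LANDMARKS[self.segment]])

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            self.patient_id,
            self.timepoint,
            self.segment,
            {n: transform.apply(p) for n, p in self.landmarks.items()},
        )


@dataclass(frozen=True)
class Triangle:
    """Ordered landmark triangle standing in for a rigid segment."""

    vertices: np.ndarray  # (3, 3), rows in canonical order
    segment: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (3, 3) or not np.all(np.isfinite(v)):
            raise GeometryError("triangle needs a finite (3, 3) vertex array")
        object.__setattr__(self, "vertices", v)
        if self.area <= MIN_TRIANGLE_AREA:
            raise DegenerateGeometryError(
                f"triangle for {self.segment!r} is degenerate (area {self.area:.3e} mm^2)"
            )

    @property
    def area(self) -> float:
        a, b, c = self.vertices
        return float(np.linalg.norm(np.cross(b - a, c - a)) / 2.0)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def build_triangle(landmarks: LandmarkSet) -> Triangle:
    """Build the segment's virtual triangle from its landmark set."""
    return Triangle(landmarks.ordered_points(), landmarks.segment)


def triangle_transform(t0: Triangle, t1: Triangle) -> RigidTransform:
    """Rigid transform superimposing the T0 triangle onto the T1 triangle.

    The Kabsch solution over the three ordered vertex pairs; exact
    (zero residual) when the triangles are congruent, least-squares
    otherwise.  Both triangles must describe the same segment and be
    expressed in the common registered frame.
    """
    if t0.segment != t1.segment:
        raise GeometryError(
            f"segment mismatch: {t0.segment!r} vs {t1.segment!r}"
        )
    return kabsch_rigid(t0.vertices, t1.vertices)


@dataclass(frozen=True)
class ClinicalMetrics:
    """Six per-segment plan-difference values with clinical signs.

    Angles in degrees, translations in mm.  Signs (T1 relative to T0):
    positive pitch/roll/yaw = anti-clockwise about +X/+Y/+Z; positive
    ``trans_lr`` = shifted towards the patient's left, positive
    ``trans_ap`` = more anterior, positive ``trans_ud`` = more cranial.
    """

    pitch: float
    roll: float
    yaw: float
    trans_lr: float
    trans_ap: float
    trans_ud: float
    segment: str = ""
    patient_id: str = ""
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAMETERS])

    def as_dict(self) -> dict[str, float]:
        return {p: float(getattr(self, p)) for p in PARAMETERS}


def to_clinical_metrics(
    transform: RigidTransform,
    reference: Triangle,
    patient_id: str = "",
) -> ClinicalMetrics:
    """Express a segment's T0→T1 rigid transform as the six clinical values.

    Angles come from the fixed Euler factorisation of the rotation; the
    translation is the displacement of the *reference* (T0) triangle
    centroid under the transform, reported on the canonical axes.  The
    centroid is used as the anchor point because for a rotating rigid
    body the reported translation depends on where on the body it is
    evaluated; the centroid is symmetric in the three landmarks and
    reproducible across observers.
    """
    angles = decompose_to_clinical_angles(transform.rotation)
    disp = transform.apply(reference.centroid) - reference.centroid
    return ClinicalMetrics(
        pitch=angles.pitch,
        roll=angles.roll,
        yaw=angles.yaw,
        trans_lr=float(disp[0]),
        trans_ap=float(disp[1]),
        trans_ud=float(disp[2]),
        segment=reference.segment,
        patient_id=patient_id,
        gimbal_lock=angles.gimbal_lock,
    )


def measure_patient(
    t0_landmarks: Mapping[str, LandmarkSet],
    t1_landmarks: Mapping[str, LandmarkSet],
    registration: RigidTransform | None = None,
) -> dict[str, ClinicalMetrics]:
    """Compute the three segments' clinical metrics for one patient.

    Parameters
    ----------
    t0_landmarks, t1_landmarks
        Segment name → :class:`LandmarkSet` for the pretreatment (T0)
        and presurgical (T1) plans; all three segments must be present
        at both timepoints.
    registration
        Optional rigid transform bringing the T0 data into the T1
        frame (e.g. from surface registration of the bony maxilla,
        which serves as the common reference); applied to every T0
        landmark set before triangle comparison.

    Returns
    -------
    dict mapping segment name to :class:`ClinicalMetrics`.
    """
    for name, sets in (("T0", t0_landmarks), ("T1", t1_landmarks)):
        missing = set(SEGMENTS) - set(sets)
        if missing:
            raise SchemaError(f"{name} landmark sets missing segments: {sorted(missing)}")
    out: dict[str, ClinicalMetrics] = {}
    for segment in SEGMENTS:
        lm0 = t0_landmarks[segment]
        if registration is not None:
            lm0 = lm0.transformed(registration)
        tri0 = build_triangle(lm0)
        tri1 = build_triangle(t1_landmarks[segment])
        transform = triangle_transform(tri0, tri1)
        out[segment] = to_clinical_metrics(transform, tri0, patient_id=lm0.patient_id)
    return out
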