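"""Synthetic landmark cohorts with known ground-truth displacements.

The generator emulates the measurement situation of a two-timepoint
surgical-planning study: for each patient, each of the three segments
(dental maxilla, dental mandible, bony mandibular distal segment) is
displaced between the pretreatment plan (T0) and the presurgical plan
(T1) by a rigid 6-DOF motion whose components are drawn independently
from per-parameter Gaussians.  Defaults are patterned on the published
26-patient cohort: component means equal the published means and SDs are
derived from the published SEMs (sd = sem · √n).  Optional isotropic
Gaussian landmark noise emulates landmark-indication error; optional
covariate shifts (SARME, extraction site) emulate subgroup effects.

Displacements are composed in the same Euler factorisation the
measurement pipeline decomposes with, and rotations pivot about the
segment's T0 triangle centroid — the same anchor the pipeline reports
translations at — so generated ground truth and recovered metrics are
directly comparable, exactly for noiseless cohorts.

Reproducibility: one root seed; patient *i*, segment *j* draws from the
substream ``SeedSequence(seed, spawn_key=(1 + i, j))`` and covariate
assignment from ``spawn_key=(0,)``, so regeneration (including partial
regeneration of a single patient) is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .geometry import RigidTransform, compose_clinical_rotation
from .registration import SegmentMesh
from .triangles import (
    PARAMETERS,
    SEGMENT_LANDMARKS,
    SEGMENTS,
    ClinicalMetrics,
    LandmarkSet,
    build_triangle,
    measure_patient,
)

__all__ = [
    "EffectSpec",
    "PatientRecord",
    "SyntheticCohort",
    "template_anatomy",
    "template_landmarks",
    "generate_cohort",
    "recovery_report",
]

#: Template landmark coordinates (mm) in the canonical patient frame
#: (+X = patient left, +Y = anterior, +Z = cranial), origin near the
#: maxillary occlusal plane.  Bilaterally symmetric about X = 0.
TEMPLATE_LANDMARKS: dict[str, dict[str, tuple[float, float, float]]] = {
    "dental_maxilla": {
        "16": (-25.0, 0.0, 0.0),
        "UI": (0.0, 30.0, -2.0),
        "26": (25.0, 0.0, 0.0),
    },
    "dental_mandible": {
        "46": (-24.0, 1.0, -30.0),
        "LI": (0.0, 28.0, -33.0),
        "36": (24.0, 1.0, -30.0),
    },
    "bony_mandible": {
        "MF_R": (-23.0, 8.0, -45.0),
        "Pog": (0.0, 18.0, -58.0),
        "MF_L": (23.0, 8.0, -45.0),
    },
}


def _arch_mesh(
    half_width: float,
    depth: float,
    z_base: float,
    height: float,
    thickness: float = 6.0,
    n_u: int = 60,
    n_v: int = 14,
    label: str = "",
) -> SegmentMesh:
    """Parametric U-shaped arch band standing in for a dental arch / chin.

    A parabolic arch swept vertically with a mild asymmetric undulation
    so that the surface has no rotational self-similarity (the ICP
    optimum is unique).
    """
    u = np.linspace(-1.0, 1.0, n_u)
    v = np.linspace(0.0, 1.0, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = half_width * uu
    y = depth * (1.0 - uu**2) + thickness * (vv - 0.5) * (0.4 + 0.3 * uu)
    z = z_base + height * vv + 1.5 * np.sin(2.5 * np.pi * uu) * (1.0 + 0.3 * uu)
    verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            a = i * n_v + j
            b = (i + 1) * n_v + j
            faces.append((a, b, a + 1))
            faces.append((b, b + 1, a + 1))
    return SegmentMesh(verts, np.array(faces, dtype=np.int64), label=label)


def template_landmarks(scale: float = 1.0, patient_id: str = "template",
                       timepoint: str = "T0") -> dict[str, LandmarkSet]:
    """Template T0 landmark sets for all three segments."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return {
        seg: LandmarkSet(
            patient_id, timepoint, seg,
            {n: scale * np.asarray(p) for n, p in TEMPLATE_LANDMARKS[seg].items()},
        )
        for seg in SEGMENTS
    }


def template_anatomy(
    scale: float = 1.0,
) -> tuple[dict[str, LandmarkSet], dict[str, SegmentMesh]]:
    """Deterministic template landmarks and segment meshes.

    Returns one landmark set and one arch-like mesh per segment, at the
    given isotropic scale (1.0 ≈ adult dimensions in mm).
    """
    landmarks = template_landmarks(scale)
    meshes = {
        "dental_maxilla": _arch_mesh(26 * scale, 31 * scale, -6 * scale, 10 * scale,
                                     label="dental_maxilla"),
        "dental_mandible": _arch_mesh(25 * scale, 29 * scale, -36 * scale, 10 * scale,
                                      label="dental_mandible"),
        "bony_mandible": _arch_mesh(24 * scale, 20 * scale, -56 * scale, 12 * scale,
                                    label="bony_mandible"),
    }
    return landmarks, meshes


def _default_effects() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        seg: {
            p: (mean, sem * np.sqrt(reference.N_PATIENTS))
            for p, (mean, sem) in reference.COHORT_MEAN_SEM[seg].items()
        }
        for seg in SEGMENTS
    }


@dataclass(frozen=True)
class EffectSpec:
    """Distributional specification of a synthetic cohort.

    ``effects[segment][parameter] = (mean, sd)`` of the Gaussian each
    patient's true displacement component is drawn from (degrees for
    rotations, mm for translations).  ``covariate_effects`` maps
    ``(covariate, segment, parameter)`` to an additive shift applied to
    patients carrying that flag.  ``noise_sd`` is the isotropic landmark
    indication noise (mm) added independently to every T1 landmark
    coordinate.
    """

    n_patients: int = reference.N_PATIENTS
    seed: int = 0
    effects: dict = field(default_factory=_default_effects)
    covariate_effects: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    scale: float = 1.0
    n_sarme: int | None = None
    n_extraction_maxilla: int | None = None
    n_extraction_mandible: int | None = None
    with_meshes: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for seg, params in self.effects.items():
            if seg not in SEGMENTS:
                raise ValueError(f"unknown segment {seg!r} in effects")
            for p, (_, sd) in params.items():
                if p not in PARAMETERS:
                    raise ValueError(f"unknown parameter {p!r} in effects")
                if sd < 0:
                    raise ValueError(f"negative sd for {seg}/{p}")
        # Covariate counts default to the published cohort's composition,
        # scaled to n_patients (15/26 SARME, 4/26 maxillary and 13/26
        # mandibular extractions).
        defaults = {
            "n_sarme": reference.N_SARME,
            "n_extraction_maxilla": reference.N_EXTRACTION_MAXILLA,
            "n_extraction_mandible": reference.N_EXTRACTION_MANDIBLE,
        }
        for name, published in defaults.items():
            count = getattr(self, name)
            if count is None:
                count = round(self.n_patients * published / reference.N_PATIENTS)
                object.__setattr__(self, name, count)
            if not (0 <= count <= self.n_patients):
                raise ValueError(f"{name} must be in [0, n_patients]")

    def null(self) -> "EffectSpec":
        """Copy of this spec with all effect means and SDs set to zero."""
        zero = {seg: {p: (0.0, 0.0) for p in PARAMETERS} for seg in SEGMENTS}
        return replace(self, effects=zero, covariate_effects={})


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    t0: dict[str, LandmarkSet]
    t1: dict[str, LandmarkSet]
    covariates: dict[str, bool]
    truth: dict[str, ClinicalMetrics]
    t1_meshes: dict[str, SegmentMesh] | None = None


@dataclass(frozen=True)
class SyntheticCohort:
    spec: EffectSpec
    patients: tuple[PatientRecord, ...]
    template_meshes: dict[str, SegmentMesh] | None = None

    def covariate_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {p.patient_id: p.covariates for p in self.patients}
        ).T.rename_axis("patient_id")

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for seg, m in p.truth.items():
                rows.append({"patient_id": p.patient_id, "segment": seg, **m.as_dict()})
        return pd.DataFrame(rows)


def _assign_covariates(spec: EffectSpec) -> list[dict[str, bool]]:
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    n = spec.n_patients
    sarme = np.zeros(n, dtype=bool)
    sarme[rng.permutation(n)[: spec.n_sarme]] = True
    ext_mand = np.zeros(n, dtype=bool)
    ext_mand[rng.permutation(n)[: spec.n_extraction_mandible]] = True
    # Maxillary extractions occur in patients who also had mandibular
    # extractions, mirroring the published cohort's composition.
    ext_max = np.zeros(n, dtype=bool)
    pool = np.flatnonzero(ext_mand) if spec.n_extraction_maxilla <= spec.n_extraction_mandible else np.arange(n)
    ext_max[rng.permutation(pool)[: spec.n_extraction_maxilla]] = True
    return [
        {"sarme": bool(sarme[i]),
         "extraction_maxilla": bool(ext_max[i]),
         "extraction_mandible": bool(ext_mand[i])}
        for i in range(n)
    ]


def displacement_transform(metrics_values: np.ndarray, pivot: np.ndarray) -> RigidTransform:
    """Rigid transform realising a 6-DOF displacement about a pivot point.

    ``metrics_values`` is (pitch, roll, yaw, LR, AP, UD); the rotation
    acts about ``pivot`` and the translation moves the pivot by exactly
    (LR, AP, UD), so measuring the displacement of the pivot recovers
    the translations and decomposing the rotation recovers the angles.
    """
    pitch, roll, yaw, lr, ap, ud = (float(v) for v in metrics_values)
    rot = compose_clinical_rotation(pitch, roll, yaw)
    t = np.array([lr, ap, ud]) + pivot - rot @ pivot
    return RigidTransform(rot, t)


def generate_cohort(spec: EffectSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort from an :class:`EffectSpec`."""
    base_landmarks = template_landmarks(spec.scale)
    template_meshes = None
    if spec.with_meshes:
        _, template_meshes = template_anatomy(spec.scale)
    covariates = _assign_covariates(spec)
    width = max(3, len(str(spec.n_patients)))
    patients = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:0{width}d}"
        t0: dict[str, LandmarkSet] = {}
        t1: dict[str, LandmarkSet] = {}
        truth: dict[str, ClinicalMetrics] = {}
        t1_meshes: dict[str, SegmentMesh] = {}
        for j, seg in enumerate(SEGMENTS):
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(1 + i, j))
            )
            params = spec.effects.get(seg, {})
            values = np.zeros(6)
            for k, p in enumerate(PARAMETERS):
                mean, sd = params.get(p, (0.0, 0.0))
                for (cov, cseg, cpar), shift in spec.covariate_effects.items():
                    if cseg == seg and cpar == p and covariates[i][cov]:
                        mean = mean + shift
                values[k] = rng.normal(mean, sd) if sd > 0 else mean
            lm0 = LandmarkSet(pid, "T0", seg, dict(base_landmarks[seg].landmarks))
            pivot = build_triangle(lm0).centroid
            transform = displacement_transform(values, pivot)
            moved = {n: transform.apply(pt) for n, pt in lm0.landmarks.items()}
            if spec.noise_sd > 0:
                moved = {
                    n: pt + rng.normal(0.0, spec.noise_sd, size=3)
                    for n, pt in moved.items()
                }
            t0[seg] = lm0
            t1[seg] = LandmarkSet(pid, "T1", seg, moved)
            truth[seg] = ClinicalMetrics(
                *(float(v) for v in values), segment=seg, patient_id=pid
            )
            if spec.with_meshes:
                t1_meshes[seg] = template_meshes[seg].transformed(transform)
        patients.append(
            PatientRecord(pid, t0, t1, covariates[i], truth,
                          t1_meshes or None)
        )
    return SyntheticCohort(spec, tuple(patients), template_meshes)


def recovery_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Measure the cohort end-to-end and tabulate estimator error.

    Runs the triangle pipeline on every patient and compares the
    recovered per-patient metrics against the stored ground truth.
    Returns one row per (segment, parameter) with the truth mean, the
    estimated mean, bias, RMSE and the maximum absolute per-patient
    error.
    """
    records: dict[tuple[str, str], list[tuple[float, float]]] = {
        (seg, p): [] for seg in SEGMENTS for p in PARAMETERS
    }
    for patient in cohort.patients:
        measured = measure_patient(patient.t0, patient.t1)
        for seg in SEGMENTS:
            est = measured[seg].as_array()
            tru = patient.truth[seg].as_array()
            for k, p in enumerate(PARAMETERS):
                records[(seg, p)].append((float(tru[k]), float(est[k])))
    rows = []
    for (seg, p), pairs in records.items():
        tru = np.array([a for a, _ in pairs])
        est = np.array([b for _, b in pairs])
        err = est - tru
        rows.append({
            "segment": seg,
            "parameter": p,
            "truth_mean": tru.mean(),
            "est_mean": est.mean(),
            "bias": err.mean(),
            "rmse": float(np.sqrt((err**2).mean())),
            "max_abs_error": float(np.abs(err).max()),
        })
    return pd.DataFrame(rows)
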