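"""Rigid-body mathematics for segment-displacement analysis.

All computation happens in a single canonical patient frame:

* ``+X`` — towards the patient's left (transverse axis),
* ``+Y`` — anterior (sagittal axis),
* ``+Z`` — cranial (vertical axis),

with coordinates in millimetres.  Rotations are decomposed into the three
clinical angles

* **pitch** — rotation about the transverse (left–right, X) axis,
* **roll**  — rotation about the sagittal (antero-posterior, Y) axis,
* **yaw**   — rotation about the vertical (Z) axis,

using the fixed factorisation ``R = Rz(yaw) @ Rx(pitch) @ Ry(roll)``.
Positive angles are anti-clockwise about the *positive* axis by the
right-hand rule, which matches the clinical sign convention (positive
pitch = anti-clockwise as seen from the patient's right, positive yaw =
anti-clockwise as seen from above).  For the small displacements that
occur between two surgical plans of the same patient the choice of
factorisation order is a second-order effect, but it is fixed here so
that composition and decomposition are exact inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "RigidTransform",
    "EulerAngles",
    "kabsch_rigid",
    "compose_clinical_rotation",
    "decompose_to_clinical_angles",
]

#: Orthonormality / determinant tolerance for valid rotations.
ROTATION_TOL = 1e-9

#: A centered point configuration whose second singular value falls below
#: this (in mm) is treated as collinear / degenerate.
DEGENERACY_TOL = 1e-6

#: Axis semantics of the canonical patient frame, exported for reuse.
AXIS_LABELS = {"x": "patient left (+)", "y": "anterior (+)", "z": "cranial (+)"}


class GeometryError(ValueError):
    """Invalid geometric input (length mismatch, bad matrix, ...)."""


class DegenerateGeometryError(GeometryError):
    """Point configuration is collinear or otherwise rank-deficient."""


def _check_rotation(matrix: np.ndarray, tol: float = ROTATION_TOL) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise GeometryError(f"rotation must be 3x3, got shape {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise GeometryError("rotation contains non-finite entries")
    err = np.abs(matrix.T @ matrix - np.eye(3)).max()
    if err > tol:
        raise GeometryError(f"rotation is not orthonormal (max deviation {err:.3e})")
    det = np.linalg.det(matrix)
    if abs(det - 1.0) > tol:
        raise GeometryError(f"rotation determinant {det!r} != +1 (reflection?)")
    return matrix


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise GeometryError("translation contains non-finite entries")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point (3,) or a stack of points (n, 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Functional alias for ``a.compose(b)`` (apply ``b`` first)."""
    return a.compose(b)


def invert(a: RigidTransform) -> RigidTransform:
    """Functional alias for ``a.invert()``."""
    return a.invert()


@dataclass(frozen=True)
class EulerAngles:
    """Clinical rotation angles in degrees, each in (−180, 180].

    ``gimbal_lock`` is set when |pitch| is within numerical tolerance of
    90°; in that configuration yaw and roll are not separable and the
    convention ``roll = 0`` is applied, with the whole residual rotation
    reported as yaw.
    """

    pitch: float
    roll: float
    yaw: float
    gimbal_lock: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.pitch, self.roll, self.yaw])


def _normalize_deg(angle: float) -> float:
    """Map an angle in degrees onto (−180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _rx(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def compose_clinical_rotation(
    pitch: float, roll: float, yaw: float
) -> np.ndarray:
    """Build a rotation from clinical angles (degrees).

    Factorisation: ``R = Rz(yaw) @ Rx(pitch) @ Ry(roll)`` — the exact
    inverse of :func:`decompose_to_clinical_angles`.
    """
    return _rz(yaw) @ _rx(pitch) @ _ry(roll)


def decompose_to_clinical_angles(rotation: np.ndarray) -> EulerAngles:
    """Decompose a proper rotation into clinical pitch / roll / yaw.

    For ``R = Rz(yaw) @ Rx(pitch) @ Ry(roll)`` the matrix entries give

    .. code-block:: text

        R[2,1] =  sin(pitch)
        R[2,0] = -cos(pitch) sin(roll)     R[2,2] = cos(pitch) cos(roll)
        R[0,1] = -sin(yaw) cos(pitch)      R[1,1] = cos(yaw) cos(pitch)

    At gimbal lock (|pitch| = 90°) only yaw ± roll is determined; the
    returned angles use the documented convention roll = 0.
    """
    r = _check_rotation(rotation)
    sp = float(np.clip(r[2, 1], -1.0, 1.0))
    pitch = np.degrees(np.arcsin(sp))
    if abs(abs(sp) - 1.0) <= ROTATION_TOL:
        # cos(pitch) ~ 0: yaw and roll act about the same axis.
        # sp=+1: R[0,0]=cos(yaw+roll), R[1,0]=sin(yaw+roll)
        # sp=-1: R[0,0]=cos(yaw-roll), R[1,0]=sin(yaw-roll)
        yaw = np.degrees(np.arctan2(r[1, 0], r[0, 0]))
        return EulerAngles(
            pitch=_normalize_deg(pitch),
            roll=0.0,
            yaw=_normalize_deg(yaw),
            gimbal_lock=True,
        )
    roll = np.degrees(np.arctan2(-r[2, 0], r[2, 2]))
    yaw = np.degrees(np.arctan2(-r[0, 1], r[1, 1]))
    return EulerAngles(
        pitch=_normalize_deg(pitch),
        roll=_normalize_deg(roll),
        yaw=_normalize_deg(yaw),
    )


def _as_point_array(points, name: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"{name} must be an (n, 3) array of points")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{name} contains non-finite coordinates")
    return arr


def kabsch_rigid(source, target) -> RigidTransform:
    """Least-squares rigid superimposition of ordered point sets.

    Finds the proper rigid transform (rotation + translation, no scaling,
    no reflection) minimising the sum of squared distances between the
    transformed ``source`` points and the corresponding ``target`` points
    — the rigid variant of Procrustes superimposition, solved in closed
    form via the SVD of the cross-covariance matrix with the usual sign
    correction that forbids reflections.

    Parameters
    ----------
    source, target
        Corresponding points, each ``(n, 3)`` with ``n >= 3``; the
        ``source`` configuration must not be collinear.

    Raises
    ------
    GeometryError
        If the lists differ in length or have fewer than 3 points.
    DegenerateGeometryError
        If the centered source configuration is collinear (its second
        singular value is below ``DEGENERACY_TOL``).
    """
    src = _as_point_array(source, "source")
    tgt = _as_point_array(target, "target")
    if src.shape != tgt.shape:
        raise GeometryError(
            f"source and target must match: {src.shape[0]} vs {tgt.shape[0]} points"
        )
    if src.shape[0] < 3:
        raise GeometryError("need at least 3 point pairs")

    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    p = src - c_src
    q = tgt - c_tgt

    sv = np.linalg.svd(p, compute_uv=False)
    if sv[1] < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "source points are collinear (rank < 2); rotation is not identifiable"
        )

    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # Numerical clean-up: re-project onto SO(3) to honour the 1e-9 invariant.
    uu, _, vvt = np.linalg.svd(rot)
    rot = uu @ vvt
    if np.linalg.det(rot) < 0:  # pragma: no cover - d above prevents this
        rot = uu @ np.diag([1.0, 1.0, -1.0]) @ vvt
    return RigidTransform(rot, c_tgt - rot @ c_src)
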