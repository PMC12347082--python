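"""Surface-based registration of osteotomized segments.

The pretreatment (T0) segments must be expressed in the presurgical (T1)
frame before triangle comparison.  In the clinical workflow this is done
by surface matching of the bony, non-dental parts of the maxilla, which
is unaffected by orthodontic tooth movement and therefore serves as the
common reference.  Here that step is a landmark-initialized trimmed
iterative-closest-point (ICP) alignment:

1. :func:`landmark_initialize` — rigid Kabsch fit on name-matched
   landmarks gives a coarse starting transform (a surrogate for the
   upstream voxel-based cranial-base registration, which needs the CBCT
   volumes and is out of scope);
2. :func:`icp_register` — point-to-point ICP with nearest-neighbour
   correspondences, discarding the largest ``trim_fraction`` of squared
   residuals at each iteration so that outlier vertices (dental regions,
   segmentation artefacts) cannot drag the fit.

An optional region mask on the source mesh restricts matching to the
"bony non-dental" vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import GeometryError, RigidTransform, kabsch_rigid
from .triangles import LandmarkSet

__all__ = [
    "SegmentMesh",
    "RegistrationResult",
    "landmark_initialize",
    "icp_register",
    "load_stl",
    "save_stl",
]

DEFAULT_TRIM_FRACTION = 0.1
DEFAULT_TOL_MM = 1e-6
DEFAULT_MAX_ITER = 200
#: Correspondence gate: registration fails diagnostically when the median
#: nearest-neighbour distance exceeds this multiple of the target's median
#: vertex spacing.
GATE_SPACING_MULTIPLE = 10.0
#: Default vertex-subsampling budget before ICP.
DEFAULT_SUBSAMPLE = 5000


@dataclass(frozen=True)
class SegmentMesh:
    """Triangle mesh (or point cloud) of one osteotomized segment, in mm."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) int; may be empty for a bare point cloud
    label: str = ""
    mask: np.ndarray | None = None  # vertex indices of the matching region

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise GeometryError("mesh needs an (n >= 3, 3) vertex array")
        if not np.all(np.isfinite(v)):
            raise GeometryError("mesh vertices contain non-finite values")
        sv = np.linalg.svd(v - v.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-6:
            raise GeometryError("mesh vertices are collinear")
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise GeometryError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.mask is not None:
            m = np.unique(np.asarray(self.mask, dtype=np.int64))
            if m.size == 0:
                raise GeometryError("region mask must be non-empty")
            if m.min() < 0 or m.max() >= v.shape[0]:
                raise GeometryError("mask indices out of range")
            object.__setattr__(self, "mask", m)

    @property
    def matching_vertices(self) -> np.ndarray:
        """Vertices participating in surface matching (masked subset or all)."""
        if self.mask is not None:
            return self.vertices[self.mask]
        return self.vertices

    def transformed(self, transform: RigidTransform) -> "SegmentMesh":
        return SegmentMesh(transform.apply(self.vertices), self.faces, self.label, self.mask)

    def subsampled(self, max_vertices: int = DEFAULT_SUBSAMPLE) -> "SegmentMesh":
        """Uniform deterministic vertex subsample (drops faces and mask)."""
        n = self.vertices.shape[0]
        if n <= max_vertices:
            return self
        idx = np.unique(np.linspace(0, n - 1, max_vertices).round().astype(np.int64))
        return SegmentMesh(self.vertices[idx], np.empty((0, 3), dtype=np.int64), self.label)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one surface registration."""

    transform: RigidTransform
    rms_residual: float
    n_iterations: int
    converged: bool
    trimmed_fraction_used: float
    success: bool = True
    message: str = ""
    residual_history: tuple[float, ...] = field(default=(), compare=False)


def load_stl(path: str | Path, label: str = "") -> SegmentMesh:
    """Read an STL file (binary or ASCII) into a :class:`SegmentMesh`."""
    mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) < 3:
        raise GeometryError(f"{path}: not a readable triangle mesh")
    return SegmentMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces),
                       label=label or Path(path).stem)


def save_stl(mesh: SegmentMesh, path: str | Path, ascii_format: bool = True) -> None:
    """Write a :class:`SegmentMesh` to STL (ASCII by default)."""
    tm = mesh.to_trimesh()
    path = Path(path)
    data = trimesh.exchange.stl.export_stl_ascii(tm) if ascii_format else trimesh.exchange.stl.export_stl(tm)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def landmark_initialize(
    source_landmarks: LandmarkSet | dict,
    target_landmarks: LandmarkSet | dict,
) -> RigidTransform:
    """Coarse rigid alignment from name-matched landmarks.

    Runs the Kabsch fit on the landmarks shared by name between the two
    sets (which may be :class:`LandmarkSet` objects or plain name→point
    mappings).  At least three non-collinear shared landmarks are
    required.
    """
    src = source_landmarks.landmarks if isinstance(source_landmarks, LandmarkSet) else source_landmarks
    tgt = target_landmarks.landmarks if isinstance(target_landmarks, LandmarkSet) else target_landmarks
    shared = sorted(set(src) & set(tgt))
    if len(shared) < 3:
        raise GeometryError(
            f"need at least 3 shared landmark names, got {len(shared)}: {shared}"
        )
    return kabsch_rigid([src[n] for n in shared], [tgt[n] for n in shared])


def _trimmed_rms(sq_residuals: np.ndarray, keep: int) -> float:
    kept = np.partition(sq_residuals, keep - 1)[:keep]
    return float(np.sqrt(kept.mean()))


def icp_register(
    source: SegmentMesh,
    target: SegmentMesh,
    init: RigidTransform | None = None,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    tol: float = DEFAULT_TOL_MM,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RegistrationResult:
    """Trimmed point-to-point ICP of a source segment onto a target.

    At each iteration the (optionally masked) source vertices are paired
    with their nearest target vertices, the largest ``trim_fraction`` of
    squared residuals is discarded, and the Kabsch solution on the kept
    pairs updates the transform.  The trimmed RMS residual is monotone
    non-increasing; iteration stops when its change falls below ``tol``
    (converged) or at ``max_iter``.

    If the clouds do not overlap under the initial transform (median
    nearest-neighbour distance above ``GATE_SPACING_MULTIPLE`` times the
    target's median vertex spacing) a diagnostic failure result is
    returned instead of raising.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise GeometryError("trim_fraction must be in [0, 0.5)")
    if max_iter < 1:
        raise GeometryError("max_iter must be >= 1")
    transform = RigidTransform.identity() if init is None else init

    src_pts = source.matching_vertices
    tgt_pts = target.vertices
    tree = cKDTree(tgt_pts)

    # Overlap gate, relative to the target's own sampling density.
    spacing = cKDTree(tgt_pts).query(tgt_pts, k=2)[0][:, 1]
    gate = GATE_SPACING_MULTIPLE * float(np.median(spacing))
    d0, _ = tree.query(transform.apply(src_pts))
    if float(np.median(d0)) > gate:
        return RegistrationResult(
            transform=transform,
            rms_residual=float(np.sqrt(np.mean(d0**2))),
            n_iterations=0,
            converged=False,
            trimmed_fraction_used=trim_fraction,
            success=False,
            message=(
                f"clouds do not overlap: median nearest-neighbour distance "
                f"{np.median(d0):.2f} mm exceeds gate {gate:.2f} mm"
            ),
        )

    n = src_pts.shape[0]
    keep = max(3, int(np.ceil(n * (1.0 - trim_fraction))))
    history: list[float] = []
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = transform.apply(src_pts)
        dists, idx = tree.query(moved)
        sq = dists**2
        if keep < n:
            kept_idx = np.argpartition(sq, keep - 1)[:keep]
        else:
            kept_idx = np.arange(n)
        rms = float(np.sqrt(sq[kept_idx].mean()))
        history.append(rms)
        # Converge on a vanishing residual or a vanishing improvement.
        if rms <= tol or prev_rms - rms < tol:
            converged = True
            break
        prev_rms = rms
        transform = kabsch_rigid(src_pts[kept_idx], tgt_pts[idx[kept_idx]])
    return RegistrationResult(
        transform=transform,
        rms_residual=history[-1],
        n_iterations=it,
        converged=converged,
        trimmed_fraction_used=trim_fraction,
        residual_history=tuple(history),
    )
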