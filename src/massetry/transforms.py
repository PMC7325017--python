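"""Rigid-body superimposition of paired craniofacial scans.

Post-treatment geometry is aligned to the pre-treatment scan by a rigid
(rotation + translation) transform estimated from treatment-stable cranial
structures: a closed-form least-squares fit on paired landmarks (Kabsch),
optionally refined by iterative closest point (ICP) on a bone surface.
Soft tissue is never used as a registration basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RigidTransform",
    "kabsch",
    "icp_refine",
    "apply_transform",
    "save_transform",
    "load_transform",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in mm.

    ``rotation`` is a 3x3 orthonormal matrix with det +1 (no reflection);
    ``translation`` is in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation has det != +1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (through the origin)."""
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major, mm)."""
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def kabsch(source_points, target_points) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Closed-form orthogonal Procrustes solution via SVD of the cross-covariance
    of the centered point sets, with the reflection guard (sign-correct the
    smallest singular vector) so anatomical chirality is preserved.

    Requires at least 3 non-collinear point pairs.
    """
    src = np.asarray(source_points, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=float).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError("source and target point sets differ in shape")
    if src.shape[0] < 3:
        raise ValueError("kabsch needs >= 3 paired points")
    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    H = (src - c_src).T @ (tgt - c_tgt)
    U, S, Vt = np.linalg.svd(H)
    # Collinear configurations leave the rotation about the line unconstrained.
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = c_tgt - R @ c_src
    return RigidTransform(R, t)


def apply_transform(geometry, transform: RigidTransform):
    """Map points, a mesh or a landmark set through a rigid transform.

    Accepts an (n, 3) array, a ``trimesh.Trimesh``, or any object exposing
    ``transformed(fn)`` (e.g. :class:`massetry.anatomy.LandmarkSet`).
    Returns a new object of the same kind.
    """
    import trimesh

    if isinstance(geometry, trimesh.Trimesh):
        out = geometry.copy()
        out.vertices = transform.apply(out.vertices)
        return out
    if hasattr(geometry, "transformed"):
        return geometry.transformed(transform.apply)
    return transform.apply(np.asarray(geometry, dtype=float))


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iter: int
    converged: bool
    rms_history: list = field(default_factory=list)


def icp_refine(
    source_mesh,
    target_mesh,
    init: RigidTransform | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> ICPResult:
    """Refine a rigid alignment of ``source_mesh`` onto ``target_mesh``.

    Point-to-point ICP: nearest target vertex per source vertex via a k-d
    tree, Kabsch update, iterated until the RMS improvement drops below
    ``tol`` (mm) or ``max_iter`` is reached. RMS never increases between
    accepted iterations; non-convergence returns the best transform with
    ``converged=False``.

    When no ``init`` is given the vertex centroids are aligned first, which
    removes the translational part of the misalignment and substantially
    widens the convergence basin; pass an explicit transform (e.g. a
    landmark Kabsch fit) to start from it instead.
    """
    from scipy.spatial import cKDTree

    if tol <= 0:
        raise ValueError("tol must be > 0")
    src = np.asarray(source_mesh.vertices, dtype=float)
    tgt = np.asarray(target_mesh.vertices, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("empty mesh passed to icp_refine")
    if init is None:
        init = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    tree = cKDTree(tgt)
    T = init
    moved = T.apply(src)
    d, idx = tree.query(moved)
    rms = float(np.sqrt(np.mean(d**2)))
    history = [rms]
    converged = False
    for it in range(max_iter):
        step = kabsch(moved, tgt[idx])
        T_new = step.compose(T)
        moved_new = T_new.apply(src)
        d, idx_new = tree.query(moved_new)
        rms_new = float(np.sqrt(np.mean(d**2)))
        if rms_new > rms:  # step made things worse; keep previous best
            converged = True
            break
        improved = rms - rms_new
        T, moved, idx, rms = T_new, moved_new, idx_new, rms_new
        history.append(rms)
        if improved < tol:
            converged = True
            break
    return ICPResult(T, rms, len(history) - 1, converged, history)


def save_transform(transform: RigidTransform, path) -> None:
    """Write as a 4x4 homogeneous matrix (row-major, mm) in JSON."""
    Path(path).write_text(
        json.dumps({"matrix": transform.matrix().tolist(), "units": "mm"}, indent=2)
    )


def load_transform(path) -> RigidTransform:
    H = np.asarray(json.loads(Path(path).read_text())["matrix"], dtype=float)
    return RigidTransform(H[:3, :3], H[:3, 3])
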