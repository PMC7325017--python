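"""Masseter-area thickness measurement on registered surface pairs.

The measured quantities, all in mm with positive = thickness decrease
(pre minus post):

* MAS change — signed average deviation between the pre- and post-treatment
  masseter area of the facial surface, the skin patch cut from the face
  model by four reference planes perpendicular to the sagittal plane
  (upper: tangent at the lower margin of the zygomatic arch; lower: tangent
  at the lower margin of the mandibular body; anterior: tangent at the
  anterior margin of the masseter muscle; posterior: the line through the
  articular-tubercle midpoint and the posterior gonial-angle point).
* MM change — signed average deviation between the pre- and post-treatment
  lateral half surfaces of the masseter muscle, the muscle cut by the plane
  through its centroid spanned by its own superoinferior and anteroposterior
  principal axes (PCA of the vertex cloud, labeled anatomically).
* ST — total soft-tissue thickness: unsigned average deviation from the
  muscle's lateral surface to the facial surface; FT change = ST_pre −
  ST_post is the fat-layer change.

"Average deviation" is the area-weighted mean of exact nearest-point
distances sampled at the reference-surface vertices, signed by the
reference normal so that medial displacement of the moved surface
(thickness decrease) is positive. Left and right sides are averaged per
patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .anatomy import AnatomicalFrame, LandmarkSet, Plane
from .proximity import MeshDistance

__all__ = [
    "RegionBoundary",
    "MasseterAxes",
    "PatientChanges",
    "TimepointData",
    "build_mas_boundary",
    "clip_region",
    "average_deviation",
    "masseter_axes",
    "lateral_half",
    "st_thickness",
    "patient_changes",
]

_PLANE_ORDER = ("upper", "lower", "anterior", "posterior")


@dataclass(frozen=True)
class RegionBoundary:
    """Four clipping planes bounding the masseter area, one hemiface.

    Normals point into the kept region and are perpendicular to the sagittal
    normal (the planes are 2D reference lines extruded laterally).
    """

    upper: Plane
    lower: Plane
    anterior: Plane
    posterior: Plane
    side: str

    def planes(self):
        return [(name, getattr(self, name)) for name in _PLANE_ORDER]


@dataclass(frozen=True)
class MasseterAxes:
    """Anatomically labeled principal axes of a masseter mesh."""

    centroid: np.ndarray
    si_axis: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    explained_variance: Dict[str, float]
    degenerate: bool = False


@dataclass
class PatientChanges:
    """Per-patient thickness changes (mm, positive = decrease).

    Combined values are the mean of left and right; ``per_side`` holds the
    raw per-side measurements.
    """

    mas_change_mm: float
    mm_change_mm: float
    ft_change_mm: float
    st_pre_mm: float
    per_side: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class TimepointData:
    """One timepoint's registered surfaces: face + per-side masseters."""

    face: trimesh.Trimesh
    masseters: Dict[str, trimesh.Trimesh]
    landmarks: Optional[LandmarkSet] = None


def _lift_2d(frame: AnatomicalFrame, pt2: np.ndarray) -> np.ndarray:
    """Embed sagittal-projection coordinates back into 3D (on the plane)."""
    return frame.sagittal.point + pt2[0] * frame.ap + pt2[1] * frame.si


def build_mas_boundary(
    frame: AnatomicalFrame,
    landmarks: LandmarkSet,
    masseter_mesh: trimesh.Trimesh,
    side: str,
) -> RegionBoundary:
    """Construct the four MAS clipping planes for one side.

    Upper and lower planes are FH-parallel supporting lines of the
    zygomatic-arch and mandibular-body lower-margin contours (touching from
    below); the anterior plane is the FH-perpendicular supporting line at
    the most anterior projected point of the masseter mesh; the posterior
    plane passes through the projected articular-tubercle midpoint and
    posterior gonial point. All are extruded along the sagittal normal.
    """
    if masseter_mesh is None or len(masseter_mesh.faces) == 0:
        raise ValueError("masseter mesh is empty; cannot place anterior tangent")

    zyg = landmarks.contour("zygomatic_lower", side)
    try:
        mand = landmarks.contour("mandible_lower", side)
    except KeyError:
        mand = landmarks.contour("mandible_lower")
    if len(zyg) < 1 or len(mand) < 1:
        raise ValueError("boundary contours must contain at least one sample")

    z_upper = float(frame.to_sagittal_2d(zyg)[:, 1].min())
    z_lower = float(frame.to_sagittal_2d(mand)[:, 1].min())
    upper = Plane(_lift_2d(frame, np.array([0.0, z_upper])), -frame.si)
    lower = Plane(_lift_2d(frame, np.array([0.0, z_lower])), frame.si)

    muscle2 = frame.to_sagittal_2d(np.asarray(masseter_mesh.vertices))
    y_ant = float(muscle2[:, 0].max())
    anterior = Plane(_lift_2d(frame, np.array([y_ant, 0.0])), -frame.ap)

    art2 = frame.to_sagittal_2d(landmarks.point("articular_tubercle_mid", side))[0]
    gon2 = frame.to_sagittal_2d(landmarks.point("gonial_posterior", side))[0]
    d = gon2 - art2
    if np.linalg.norm(d) < 1e-9:
        raise ValueError("articular tubercle and gonial point coincide")
    n2 = np.array([d[1], -d[0]])
    if n2[0] < 0 or (n2[0] == 0 and n2[1] < 0):
        n2 = -n2  # keep the anterior side of the posterior line
    normal3 = n2[0] * frame.ap + n2[1] * frame.si
    posterior = Plane(_lift_2d(frame, art2), normal3)

    return RegionBoundary(
        upper=upper, lower=lower, anterior=anterior, posterior=posterior, side=side
    )


def clip_region(mesh: trimesh.Trimesh, boundary: RegionBoundary) -> trimesh.Trimesh:
    """Sub-mesh inside all four half-spaces, crossing triangles split.

    Raises with the name of the first plane whose half-space empties the
    mesh.
    """
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("cannot clip an empty mesh")
    out = mesh
    for name, plane in boundary.planes():
        out = slice_mesh_plane(out, plane.normal, plane.point)
        if out is None or len(out.faces) == 0:
            raise ValueError(f"clip by {name!r} plane removed the whole mesh")
    return out


def _vertex_area_weights(mesh: trimesh.Trimesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle."""
    w = np.zeros(len(mesh.vertices))
    np.add.at(w, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return w


def average_deviation(
    reference: trimesh.Trimesh, moved: trimesh.Trimesh, signed: bool = True
) -> float:
    """Area-weighted mean nearest-point distance from reference to moved.

    Sampled at reference vertices, weighted by barycentric vertex area. For
    the signed variant each distance carries ``-sign(n_ref . (q - x))``, so
    a moved surface displaced medially (against the reference's outward
    normal — a thickness decrease) contributes positively.
    """
    if reference is None or len(reference.faces) == 0:
        raise ValueError("reference mesh is empty")
    if moved is None or len(moved.faces) == 0:
        raise ValueError("moved mesh is empty")
    pts = np.asarray(reference.vertices, dtype=float)
    dist, closest, _ = MeshDistance(moved).query(pts)
    if signed:
        normals = np.asarray(reference.vertex_normals, dtype=float)
        inner = np.einsum("ij,ij->i", normals, closest - pts)
        dist = np.where(inner > 0, -dist, dist)
    w = _vertex_area_weights(reference)
    return float(np.average(dist, weights=w))


def masseter_axes(
    mm_mesh: trimesh.Trimesh, frame: AnatomicalFrame
) -> MasseterAxes:
    """PCA of the muscle vertex cloud, labeled by the anatomical frame.

    Principal components are assigned bijectively to the superoinferior,
    anteroposterior and mediolateral roles by maximum |cosine| with the
    frame axes, then sign-aligned with them; the mediolateral axis is
    recomputed as ap x si so the triad is exactly orthonormal. A near-equal
    leading eigenvalue pair (within 1e-9 relative) sets ``degenerate`` —
    the frame alignment then is the tie-break.
    """
    verts = np.asarray(mm_mesh.vertices, dtype=float)
    if len(verts) < 3:
        raise ValueError("need >= 3 vertices for principal axes")
    centroid = verts.mean(axis=0)
    cov = np.cov((verts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if np.linalg.matrix_rank(cov, tol=1e-12) < 2:
        raise ValueError("degenerate (collinear) vertex covariance")
    degenerate = bool(
        np.any(np.abs(np.diff(evals)) <= 1e-9 * max(evals[-1], 1.0))
    )

    anatomical = {"si": frame.si, "ap": frame.ap, "ml": frame.lateral_R}
    roles = list(anatomical)
    score = np.abs(
        np.array([[np.dot(evecs[:, j], anatomical[r]) for j in range(3)] for r in roles])
    )
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-score)
    chosen = {}
    for r_i, c_i in zip(rows, cols):
        axis = evecs[:, c_i]
        if np.dot(axis, anatomical[roles[r_i]]) < 0:
            axis = -axis
        chosen[roles[r_i]] = (axis, float(evals[c_i]))

    si_axis, si_var = chosen["si"]
    ap_axis, ap_var = chosen["ap"]
    _, ml_var = chosen["ml"]
    ml_axis = np.cross(ap_axis, si_axis)
    if np.dot(ml_axis, frame.lateral_R) < 0:
        ml_axis = -ml_axis
    return MasseterAxes(
        centroid=centroid,
        si_axis=si_axis,
        ap_axis=ap_axis,
        ml_axis=ml_axis,
        explained_variance={"si": si_var, "ap": ap_var, "ml": ml_var},
        degenerate=degenerate,
    )


def lateral_half(
    mm_mesh: trimesh.Trimesh,
    axes: MasseterAxes,
    frame: AnatomicalFrame,
    side: str,
) -> trimesh.Trimesh:
    """Lateral half of the muscle surface.

    Cut plane through the centroid spanned by the superoinferior and
    anteroposterior principal axes; the kept half lies on the lateral side
    (away from the midsagittal plane) for the requested side.
    """
    lat = axes.ml_axis if np.dot(axes.ml_axis, frame.lateral(side)) > 0 else -axes.ml_axis
    half = slice_mesh_plane(mm_mesh, lat, axes.centroid)
    if half is None or len(half.faces) == 0:
        raise ValueError(f"lateral half of side {side!r} is empty")
    return half


def st_thickness(mm_lateral: trimesh.Trimesh, face_mesh: trimesh.Trimesh) -> float:
    """Total soft-tissue thickness: muscle lateral surface → face, unsigned."""
    return average_deviation(mm_lateral, face_mesh, signed=False)


def _restrict_to_side(
    mesh: trimesh.Trimesh, frame: AnatomicalFrame, side: str
) -> trimesh.Trimesh:
    out = slice_mesh_plane(mesh, frame.lateral(side), frame.sagittal.point)
    if out is None or len(out.faces) == 0:
        raise ValueError(f"no facial surface on side {side!r}")
    return out


def patient_changes(
    pre: TimepointData,
    post: TimepointData,
    frame: AnatomicalFrame | None = None,
    landmarks: LandmarkSet | None = None,
    sides=("L", "R"),
):
    """Full per-patient measurement on registered pre/post surfaces.

    The anatomical frame and boundary landmarks default to the
    pre-treatment landmark set; the MAS boundary is built once per side
    from the pre-treatment masseter and applied to both timepoints, so pre
    and post are cut by the identical region. Returns
    ``(PatientChanges, provenance)`` where provenance records planes, axes
    and sample counts per side.
    """
    if landmarks is None:
        landmarks = pre.landmarks
    if landmarks is None:
        raise ValueError("no landmark set available")
    if frame is None:
        from .anatomy import build_frame

        frame = build_frame(landmarks)

    per_side: Dict[str, Dict[str, float]] = {}
    provenance: Dict[str, dict] = {}
    for side in sides:
        if side not in pre.masseters or side not in post.masseters:
            raise ValueError(f"masseter mesh missing for side {side!r}")
        boundary = build_mas_boundary(frame, landmarks, pre.masseters[side], side)
        pre_face = _restrict_to_side(pre.face, frame, side)
        post_face = _restrict_to_side(post.face, frame, side)
        pre_mas = clip_region(pre_face, boundary)
        post_mas = clip_region(post_face, boundary)
        mas = average_deviation(pre_mas, post_mas, signed=True)

        axes_pre = masseter_axes(pre.masseters[side], frame)
        axes_post = masseter_axes(post.masseters[side], frame)
        lat_pre = lateral_half(pre.masseters[side], axes_pre, frame, side)
        lat_post = lateral_half(post.masseters[side], axes_post, frame, side)
        mm = average_deviation(lat_pre, lat_post, signed=True)

        st_pre = st_thickness(lat_pre, pre.face)
        st_post = st_thickness(lat_post, post.face)
        ft = st_pre - st_post

        per_side[side] = {
            "mas_change_mm": mas,
            "mm_change_mm": mm,
            "ft_change_mm": ft,
            "st_pre_mm": st_pre,
            "st_post_mm": st_post,
        }
        provenance[side] = {
            "boundary_planes": {
                name: {"point": pl.point.tolist(), "normal": pl.normal.tolist()}
                for name, pl in boundary.planes()
            },
            "pre_axes": {
                "centroid": axes_pre.centroid.tolist(),
                "si": axes_pre.si_axis.tolist(),
                "ap": axes_pre.ap_axis.tolist(),
                "ml": axes_pre.ml_axis.tolist(),
                "degenerate": axes_pre.degenerate,
            },
            "n_mas_samples": len(pre_mas.vertices),
            "n_mm_samples": len(lat_pre.vertices),
        }

    def combined(key: str) -> float:
        return float(np.mean([per_side[s][key] for s in per_side]))

    changes = PatientChanges(
        mas_change_mm=combined("mas_change_mm"),
        mm_change_mm=combined("mm_change_mm"),
        ft_change_mm=combined("ft_change_mm"),
        st_pre_mm=combined("st_pre_mm"),
        per_side=per_side,
    )
    return changes, provenance
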