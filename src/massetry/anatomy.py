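"""Cephalometric reference frames and angles from named 3D landmarks.

The coordinate scaffold for every measurement is built from classical
cephalometric landmarks: the Frankfort horizontal (FH) plane is the
total-least-squares plane of bilateral Orbitale and Porion; the midsagittal
plane is perpendicular to FH and passes through ANS and PNS. From these two
planes come the anteroposterior, superoinferior and per-side lateral axes,
and the two skeletal-pattern angles used as cohort covariates:

* FMA — angle between FH and the mandibular plane, the tangent line through
  Menton supporting the lower margin of the mandibular body from below
  (vertical skeletal pattern).
* ANB — signed angle between the N→A and N→B rays in sagittal projection,
  positive when A is anterior to B (sagittal jaw relationship, positive =
  Class II direction).

All constructions are equivariant under a rigid transform of the full
landmark set, so the angles are rigid invariants.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterable, List

import numpy as np

__all__ = [
    "LandmarkSet",
    "Plane",
    "AnatomicalFrame",
    "fit_fh_plane",
    "build_frame",
    "fma",
    "anb",
]

REQUIRED_FRAME_LANDMARKS = ("Or_L", "Or_R", "Po_L", "Po_R", "ANS", "PNS")


@dataclass
class LandmarkSet:
    """Named anatomical points in mm.

    Sided landmarks use an ``_L`` / ``_R`` suffix; indexed contour samples
    append ``_<i>`` (e.g. ``zygomatic_lower_R_0``).
    """

    points: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = arr
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, *names: str) -> List[np.ndarray]:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(f"missing landmarks: {missing}")
        return [self.points[n] for n in names]

    def point(self, base: str, side: str | None = None) -> np.ndarray:
        name = f"{base}_{side}" if side else base
        return self.require(name)[0]

    def contour(self, base: str, side: str | None = None) -> np.ndarray:
        """All samples ``{base}[_{side}]_<i>`` as an (n, 3) array, index order."""
        prefix = f"{base}_{side}_" if side else f"{base}_"
        pat = re.compile(re.escape(prefix) + r"(\d+)$")
        hits = sorted(
            (int(m.group(1)), name)
            for name, m in ((n, pat.match(n)) for n in self.points)
            if m
        )
        if not hits:
            raise KeyError(f"no contour samples named {prefix}<i>")
        return np.array([self.points[name] for _, name in hits])

    def transformed(self, fn: Callable[[np.ndarray], np.ndarray]) -> "LandmarkSet":
        stacked = np.array(list(self.points.values()))
        moved = fn(stacked)
        return LandmarkSet(dict(zip(self.points.keys(), moved)))

    # --- I/O: JSON {name: [x, y, z]} or CSV name,x,y,z (mm) ---

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({k: v.tolist() for k, v in self.points.items()}, indent=2)
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        return cls({k: v for k, v in json.loads(Path(path).read_text()).items()})

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x_mm", "y_mm", "z_mm"])
            for k, v in self.points.items():
                w.writerow([k, *v.tolist()])

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        pts = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pts[row["name"]] = [row["x_mm"], row["y_mm"], row["z_mm"]]
        return cls(pts)


@dataclass(frozen=True)
class Plane:
    """Point-normal plane; the normal is unit length."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal is zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.point) @ self.normal


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal anatomical axes derived from the FH and sagittal planes.

    ``ap`` points anteriorly (PNS→ANS projected into FH), ``si`` cranially
    (FH normal), and ``lateral_R`` to the patient's right; ``lateral_L`` is
    its negation. The sagittal plane contains ANS and PNS.
    """

    fh: Plane
    sagittal: Plane
    ap: np.ndarray
    si: np.ndarray
    lateral_R: np.ndarray

    def lateral(self, side: str) -> np.ndarray:
        if side.upper() in ("R", "RIGHT"):
            return self.lateral_R
        if side.upper() in ("L", "LEFT"):
            return -self.lateral_R
        raise ValueError(f"unknown side {side!r}")

    def to_sagittal_2d(self, points) -> np.ndarray:
        """Project to (anteroposterior, superoinferior) coordinates in mm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        origin = self.sagittal.point
        return np.column_stack(
            [(pts - origin) @ self.ap, (pts - origin) @ self.si]
        )


def _tls_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane: centroid + smallest covariance eigenvector."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane fit is degenerate")
    return centroid, vt[-1]


def fit_fh_plane(landmarks: LandmarkSet, up_hint=None) -> Plane:
    """Frankfort horizontal: TLS plane of Or_L, Or_R, Po_L, Po_R.

    The normal is oriented cranially. By default the up-reference is the
    Menton→Nasion direction (rigid-equivariant); pass ``up_hint`` to
    override, e.g. for landmark files without N/Me.
    """
    pts = np.array(landmarks.require("Or_L", "Or_R", "Po_L", "Po_R"))
    centroid, normal = _tls_plane(pts)
    if up_hint is None:
        if "N" in landmarks and "Me" in landmarks:
            up_hint = landmarks["N"] - landmarks["Me"]
        else:
            up_hint = np.array([0.0, 0.0, 1.0])
    if np.dot(normal, np.asarray(up_hint, dtype=float)) < 0:
        normal = -normal
    return Plane(centroid, normal)


def build_frame(landmarks: LandmarkSet, up_hint=None) -> AnatomicalFrame:
    """Construct the full anatomical frame from the six frame landmarks.

    The sagittal plane is perpendicular to FH and contains ANS and PNS; its
    normal (the lateral axis) is oriented toward the patient's right using
    the Or_R − Or_L direction.
    """
    fh = fit_fh_plane(landmarks, up_hint=up_hint)
    ans, pns = landmarks.require("ANS", "PNS")
    v = ans - pns
    if np.linalg.norm(v) < 1e-9:
        raise ValueError("ANS and PNS coincide; sagittal plane is degenerate")
    si = fh.normal
    ap = v - np.dot(v, si) * si
    ap_norm = np.linalg.norm(ap)
    if ap_norm < 1e-9:
        raise ValueError("ANS→PNS is parallel to the FH normal")
    ap = ap / ap_norm
    lateral = np.cross(ap, si)
    or_l, or_r = landmarks.require("Or_L", "Or_R")
    if np.dot(lateral, or_r - or_l) < 0:
        lateral = -lateral
    sagittal = Plane(ans, lateral)
    return AnatomicalFrame(fh=fh, sagittal=sagittal, ap=ap, si=si, lateral_R=lateral)


def fma(frame: AnatomicalFrame, landmarks: LandmarkSet) -> float:
    """Frankfort-mandibular plane angle in degrees, in [0, 90].

    The mandibular plane is the line through projected Menton supporting the
    projected lower-margin contour of the mandibular body from below: among
    lines through Me, the one of smallest inclination to FH with every
    contour sample on or above it.
    """
    me = landmarks.point("Me")
    contour = landmarks.contour("mandible_lower")
    me2 = frame.to_sagittal_2d(me)[0]
    c2 = frame.to_sagittal_2d(contour)
    rel = c2 - me2
    keep = np.linalg.norm(rel, axis=1) > 1e-9
    rel = rel[keep]
    if len(rel) == 0:
        raise ValueError("mandibular contour collapses onto Menton")
    # inclination of each Me→sample ray above the FH direction, folded so
    # anterior- and posterior-going branches measure the same geometric angle
    angles = np.degrees(np.arctan2(rel[:, 1], np.abs(rel[:, 0])))
    # supporting line from below: the shallowest ray — rotating the line any
    # further up through Me would put that sample beneath it
    ang = float(np.min(angles))
    return min(abs(ang), 90.0)


def anb(landmarks: LandmarkSet, frame: AnatomicalFrame) -> float:
    """Signed ANB angle (degrees): positive when A is anterior to B."""
    n, a, b = landmarks.require("N", "A", "B")
    if np.linalg.norm(a - n) < 1e-9 or np.linalg.norm(b - n) < 1e-9:
        raise ValueError("N coincides with A or B")
    n2 = frame.to_sagittal_2d(n)[0]
    u = frame.to_sagittal_2d(a)[0] - n2
    v = frame.to_sagittal_2d(b)[0] - n2
    cross = u[1] * v[0] - u[0] * v[1]  # positive when A anterior to B
    dot = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(cross, dot)))
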