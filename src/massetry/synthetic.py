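"""Synthetic phantoms and cohorts with known ground truth.

No patient CBCT data accompany the measurement procedure this package
implements, so validation rests on parameter recovery from two synthetic
sources:

* **Hemiface phantoms** — per side, the masseter muscle is a superellipsoid
  slab (half-extents superoinferior > anteroposterior > mediolateral, the
  proportions of an adult masseter) lateral to a box "skull"; the facial
  skin surface is the muscle surface offset outward along its analytic
  normals by a fat-thickness field. The post-treatment state displaces the
  muscle surface inward along the local outward normal by δ_MM and changes
  the fat layer by δ_FT — exact parallel offsets, so the signed average
  deviation of every measured region has a closed-form ground truth
  (MM → δ_MM, MAS → δ_MM + δ_FT, FT → δ_FT). All post geometry and
  landmarks then undergo a known rigid misalignment, which registration
  must undo. Landmarks are generated consistently on both states,
  including the cephalometric set that makes FMA and ANB come out at the
  requested angles.

* **Cohort tables** — a Gaussian copula draws per-patient covariates and
  thickness changes with group-specific means/SDs and a target Spearman
  rank-correlation structure (the copula's latent Pearson correlation is
  2·sin(πρ/6), the exact bivariate-normal inverse). Defaults reproduce the
  published group structure of a 42-patient extraction/nonextraction
  sample.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import trimesh

from .anatomy import LandmarkSet
from .transforms import RigidTransform

__all__ = [
    "PhantomParams",
    "PhantomState",
    "PhantomCase",
    "GroupSpec",
    "CohortSpec",
    "make_phantom",
    "simulate_cohort",
    "default_cohort_spec",
    "write_case",
    "COHORT_VARIABLES",
]

SIDES = ("L", "R")


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters; defaults emulate an extraction-group patient.

    Extents and deltas in mm. ``muscle_half_extents`` orders
    (superoinferior, anteroposterior, mediolateral) and must be strictly
    decreasing. ``delta_mm`` thins the muscle laterally pre→post;
    ``delta_ft`` changes the fat layer (positive = decrease). The true
    rigid transform is applied to every post-state coordinate.
    """

    muscle_half_extents: tuple = (28.0, 18.0, 7.0)
    muscle_center: tuple = (45.0, 0.0, -30.0)  # right side; left mirrors x
    superellipse_power: float = 4.0
    fat_base_mm: float = 8.3
    fat_variation_mm: float = 0.5
    skull_extents: tuple = (70.0, 50.0, 20.0)
    skull_center: tuple = (0.0, 25.0, 22.0)
    delta_mm: float = 1.284
    delta_ft: float = 0.006
    true_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    resolution_mm: float = 2.0
    voxel_mm: float = 1.0
    noise_sd_mm: float = 0.0
    fma_deg: float = 25.0
    anb_deg: float = 4.0
    with_volumes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        si, ap, ml = self.muscle_half_extents
        if not (si > ap > ml > 0):
            raise ValueError(
                "muscle half-extents must satisfy superoinferior > "
                "anteroposterior > mediolateral > 0"
            )
        if any(e <= 0 for e in self.skull_extents):
            raise ValueError("skull extents must be positive")
        if self.resolution_mm <= 0 or self.voxel_mm <= 0:
            raise ValueError("resolution must be positive")
        if abs(self.delta_mm) >= ml:
            raise ValueError("|delta_mm| must be smaller than the muscle thickness")
        if abs(self.delta_ft) >= self.fat_base_mm - self.fat_variation_mm:
            raise ValueError("|delta_ft| must be smaller than the fat thickness")
        if self.fat_variation_mm < 0 or self.fat_variation_mm >= self.fat_base_mm:
            raise ValueError("fat variation must be in [0, fat_base)")
        if self.noise_sd_mm < 0:
            raise ValueError("noise SD must be >= 0")

    @property
    def delta_mas(self) -> float:
        return self.delta_mm + self.delta_ft


@dataclass
class PhantomState:
    face: trimesh.Trimesh
    masseters: Dict[str, trimesh.Trimesh]
    skull: trimesh.Trimesh
    landmarks: LandmarkSet
    volumes: Dict[str, "object"] = field(default_factory=dict)


@dataclass
class GroundTruth:
    delta_mm: float
    delta_ft: float
    delta_mas: float
    transform: RigidTransform
    st_pre_mm: float
    fma_deg: float
    anb_deg: float


@dataclass
class PhantomCase:
    pre: PhantomState
    post: PhantomState
    truth: GroundTruth
    params: PhantomParams


def _icosphere_subdivisions(params: PhantomParams) -> int:
    # unit icosahedron edge ~1.05; scaled by the largest half-extent and
    # halved per subdivision until the target edge length is met
    si = params.muscle_half_extents[0]
    target = params.resolution_mm
    subs = int(np.ceil(np.log2(max(1.05 * si / target, 1.0))))
    return int(np.clip(subs, 2, 6))


def _superellipsoid(params: PhantomParams, side: str, subdivisions: int):
    """Muscle mesh + analytic outward unit normals in world coordinates.

    Local axes: x = mediolateral (outward positive), y = anteroposterior,
    z = superoinferior. The left side mirrors x (winding fixed so normals
    stay outward).
    """
    si, ap, ml = params.muscle_half_extents
    radii = np.array([ml, ap, si])
    p = params.superellipse_power
    sigma = 1.0 if side == "R" else -1.0
    center = np.array(params.muscle_center) * np.array([sigma, 1.0, 1.0])

    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(base.vertices)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    r = (np.abs(u / radii) ** p).sum(axis=1) ** (-1.0 / p)
    local = r[:, None] * u
    # implicit gradient of sum |w_i / a_i|^p gives the exact outward normal
    grad = p * np.abs(local / radii) ** (p - 1) * np.sign(local) / radii
    normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)

    flip = np.array([sigma, 1.0, 1.0])
    verts = local * flip + center
    normals = normals * flip
    faces = np.asarray(base.faces)
    if sigma < 0:
        faces = faces[:, ::-1]  # mirroring reverses orientation
    return verts, faces, normals


def _skull_mesh(params: PhantomParams) -> trimesh.Trimesh:
    box = trimesh.creation.box(extents=params.skull_extents)
    box = box.subdivide().subdivide()
    box.vertices = np.asarray(box.vertices) + np.array(params.skull_center)
    return box


def _skull_corner_landmarks(params: PhantomParams) -> Dict[str, np.ndarray]:
    ex = np.array(params.skull_extents) / 2.0
    c = np.array(params.skull_center)
    corners = c + ex * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    return {f"skull_{i}": corners[i] for i in range(8)}


def _cephalometric_landmarks(params: PhantomParams) -> Dict[str, np.ndarray]:
    """Frame, jaw and boundary landmarks consistent with the target angles."""
    si_ext, ap_ext, _ = params.muscle_half_extents
    cx, cy, cz = params.muscle_center
    pts: Dict[str, np.ndarray] = {
        "Or_L": np.array([-32.0, 38.0, 0.0]),
        "Or_R": np.array([32.0, 38.0, 0.0]),
        "Po_L": np.array([-45.0, -35.0, 0.0]),
        "Po_R": np.array([45.0, -35.0, 0.0]),
        "ANS": np.array([0.0, 48.0, -12.0]),
        "PNS": np.array([0.0, 2.0, -12.0]),
        "N": np.array([0.0, 52.0, 18.0]),
        "Me": np.array([0.0, 38.0, -64.0]),
    }
    # A/B rays from N at phi and phi - ANB off the vertical, in-plane
    length = 70.0
    phi_a = np.deg2rad(10.0)
    phi_b = phi_a - np.deg2rad(params.anb_deg)
    pts["A"] = pts["N"] + length * np.array([0.0, np.sin(phi_a), -np.cos(phi_a)])
    pts["B"] = pts["N"] + length * np.array([0.0, np.sin(phi_b), -np.cos(phi_b)])
    # mandibular lower-margin contour rising posteriorly from Me at FMA
    theta = np.deg2rad(params.fma_deg)
    for i, t in enumerate((15.0, 30.0, 45.0, 60.0)):
        pts[f"mandible_lower_{i}"] = pts["Me"] + t * np.array(
            [0.0, -np.cos(theta), np.sin(theta)]
        )
    z_zyg = cz + 0.55 * si_ext
    for side, sigma in (("L", -1.0), ("R", 1.0)):
        for i, y in enumerate((-8.0, 4.0, 12.0)):
            pts[f"zygomatic_lower_{side}_{i}"] = np.array(
                [sigma * (cx + 2.0), y, z_zyg]
            )
        pts[f"articular_tubercle_mid_{side}"] = np.array(
            [sigma * (cx + 3.0), -14.0, -8.0]
        )
        pts[f"gonial_posterior_{side}"] = np.array(
            [sigma * (cx + 1.0), -14.0, -55.0]
        )
        for i, dz in enumerate((-10.0, 0.0, 10.0)):
            pts[f"masseter_anterior_{side}_{i}"] = np.array(
                [sigma * cx, cy + ap_ext, cz + dz]
            )
    return pts


def _fat_field(params: PhantomParams, local_like: np.ndarray) -> np.ndarray:
    """Smooth fat-thickness field evaluated at muscle-surface points."""
    si_ext, ap_ext, _ = params.muscle_half_extents
    z = local_like[:, 2]
    y = local_like[:, 1]
    return params.fat_base_mm + params.fat_variation_mm * np.sin(
        np.pi * z / (2.0 * si_ext)
    ) * np.cos(np.pi * y / (2.0 * ap_ext))


def _jitter(mesh: trimesh.Trimesh, sd: float, rng: np.random.Generator) -> None:
    if sd > 0:
        mesh.vertices = np.asarray(mesh.vertices) + sd * rng.standard_normal(
            (len(mesh.vertices), 1)
        ) * np.asarray(mesh.vertex_normals)


def _voxelize_superellipsoid(params: PhantomParams, side: str, delta: float):
    """Binary intensity volume (two-level, 1000 inside) of one muscle."""
    from .volume import VoxelVolume

    si, ap, ml = params.muscle_half_extents
    radii = np.array([ml, ap, si]) - delta
    sigma = 1.0 if side == "R" else -1.0
    center = np.array(params.muscle_center) * np.array([sigma, 1.0, 1.0])
    margin = 4.0
    lo = center - radii[[0, 1, 2]] - margin
    hi = center + radii[[0, 1, 2]] + margin
    h = params.voxel_mm
    axes = [np.arange(lo[i], hi[i] + h, h) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    w = np.stack([X - center[0], Y - center[1], Z - center[2]], axis=-1)
    val = (np.abs(w / radii) ** params.superellipse_power).sum(axis=-1)
    grid = np.where(val <= 1.0, 1000.0, 0.0)
    return VoxelVolume(grid, (h, h, h), lo)


def make_phantom(params: PhantomParams) -> PhantomCase:
    """Generate a paired pre/post phantom with known ground truth.

    With zero deltas, zero noise and an identity transform, the pre and
    post states are identical by construction.
    """
    rng = np.random.default_rng(params.seed)
    subs = _icosphere_subdivisions(params)

    pre_masseters: Dict[str, trimesh.Trimesh] = {}
    post_masseters: Dict[str, trimesh.Trimesh] = {}
    pre_face_parts: List[trimesh.Trimesh] = []
    post_face_parts: List[trimesh.Trimesh] = []
    st_true_num = st_true_den = 0.0

    for side in SIDES:
        verts, faces, normals = _superellipsoid(params, side, subs)
        sigma = 1.0 if side == "R" else -1.0
        center = np.array(params.muscle_center) * np.array([sigma, 1.0, 1.0])
        local = (verts - center) * np.array([sigma, 1.0, 1.0])
        fat = _fat_field(params, local)

        pre_m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        post_m = trimesh.Trimesh(
            vertices=verts - params.delta_mm * normals, faces=faces, process=False
        )
        pre_f = trimesh.Trimesh(
            vertices=verts + fat[:, None] * normals, faces=faces, process=False
        )
        post_f = trimesh.Trimesh(
            vertices=verts + (fat - params.delta_mas)[:, None] * normals,
            faces=faces,
            process=False,
        )

        # analytic ST ground truth: area-weighted fat over the lateral half
        lateral = sigma * (verts[:, 0] - center[0]) > 0
        areas = np.zeros(len(verts))
        np.add.at(areas, faces.ravel(), np.repeat(pre_m.area_faces / 3.0, 3))
        st_true_num += float(np.sum(fat[lateral] * areas[lateral]))
        st_true_den += float(np.sum(areas[lateral]))

        for m in (pre_m, post_m, pre_f, post_f):
            _jitter(m, params.noise_sd_mm, rng)

        pre_masseters[side] = pre_m
        post_masseters[side] = post_m
        pre_face_parts.append(pre_f)
        post_face_parts.append(post_f)

    pre_face = trimesh.util.concatenate(pre_face_parts)
    post_face = trimesh.util.concatenate(post_face_parts)
    skull = _skull_mesh(params)
    landmarks = LandmarkSet(
        {**_cephalometric_landmarks(params), **_skull_corner_landmarks(params)}
    )

    T = params.true_transform
    post = PhantomState(
        face=trimesh.Trimesh(
            vertices=T.apply(post_face.vertices), faces=post_face.faces, process=False
        ),
        masseters={
            s: trimesh.Trimesh(
                vertices=T.apply(m.vertices), faces=m.faces, process=False
            )
            for s, m in post_masseters.items()
        },
        skull=trimesh.Trimesh(
            vertices=T.apply(skull.vertices), faces=skull.faces, process=False
        ),
        landmarks=landmarks.transformed(T.apply),
    )
    pre = PhantomState(
        face=pre_face, masseters=pre_masseters, skull=skull.copy(), landmarks=landmarks
    )

    if params.with_volumes:
        for side in SIDES:
            pre.volumes[f"masseter_{side}"] = _voxelize_superellipsoid(
                params, side, 0.0
            )

    truth = GroundTruth(
        delta_mm=params.delta_mm,
        delta_ft=params.delta_ft,
        delta_mas=params.delta_mas,
        transform=T,
        st_pre_mm=st_true_num / st_true_den,
        fma_deg=params.fma_deg,
        anb_deg=params.anb_deg,
    )
    return PhantomCase(pre=pre, post=post, truth=truth, params=params)


def write_case(case: PhantomCase, out_dir) -> None:
    """Write STL surfaces, landmark JSON and a ground-truth sidecar."""
    import json

    out = Path(out_dir)
    for state_name, state in (("pre", case.pre), ("post", case.post)):
        d = out / state_name
        d.mkdir(parents=True, exist_ok=True)
        state.face.export(d / "face.stl")
        state.skull.export(d / "skull.stl")
        for side, m in state.masseters.items():
            m.export(d / f"masseter_{side}.stl")
        state.landmarks.to_json(d / "landmarks.json")
        for name, vol in state.volumes.items():
            vol.save_npz(d / f"{name}.npz")
    truth = {
        "delta_mm": case.truth.delta_mm,
        "delta_ft": case.truth.delta_ft,
        "delta_mas": case.truth.delta_mas,
        "st_pre_mm": case.truth.st_pre_mm,
        "fma_deg": case.truth.fma_deg,
        "anb_deg": case.truth.anb_deg,
        "transform_matrix": case.truth.transform.matrix().tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

COHORT_VARIABLES = [
    "duration_d",
    "age_y",
    "FMA_deg",
    "ANB_deg",
    "MM_change_mm",
    "MAS_change_mm",
    "FT_change_mm",
    "ST_pre_mm",
]


@dataclass
class GroupSpec:
    name: str
    label: int  # dummy coding: extraction = 1, nonextraction = 0
    size: int
    means: Dict[str, float]
    sds: Dict[str, float]

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("group size must be >= 0")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("SDs must be >= 0")


@dataclass
class CohortSpec:
    """Generating model for a synthetic patient table.

    ``spearman`` is the target rank-correlation matrix over ``variables``
    (shared across groups); marginals are Gaussian with group-specific
    means/SDs, so ranks — and hence Spearman — are untouched by the
    marginal transform. ``response_models`` optionally overwrites response
    columns with an explicit linear model
    ``response = intercept + Σ coef·column (+ group effect) + noise``.
    """

    groups: List[GroupSpec]
    variables: List[str] = field(default_factory=lambda: list(COHORT_VARIABLES))
    spearman: Optional[np.ndarray] = None
    response_models: Dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.variables)
        if self.spearman is None:
            self.spearman = np.eye(p)
        self.spearman = np.asarray(self.spearman, dtype=float)
        if self.spearman.shape != (p, p):
            raise ValueError("spearman matrix shape does not match variables")
        if not np.allclose(self.spearman, self.spearman.T, atol=1e-12):
            raise ValueError("spearman target must be symmetric")
        if np.linalg.eigvalsh(self.spearman).min() < -1e-10:
            raise ValueError("spearman target is not positive semi-definite")


def _latent_correlation(spearman: np.ndarray) -> np.ndarray:
    """Gaussian-copula latent Pearson matrix hitting a Spearman target.

    Uses the exact bivariate-normal relation r = 2·sin(πρ/6). The
    entrywise map can leave PSD; if so the matrix is projected to the
    nearest correlation matrix (eigenvalue clipping + renormalization).
    """
    lat = 2.0 * np.sin(np.pi * spearman / 6.0)
    np.fill_diagonal(lat, 1.0)
    evals, evecs = np.linalg.eigh(lat)
    if evals.min() < 1e-10:
        evals = np.clip(evals, 1e-10, None)
        lat = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(lat))
        lat = lat / np.outer(d, d)
    return lat


def _allocate(sizes: np.ndarray, n_total: int) -> np.ndarray:
    """Largest-remainder allocation of n_total across groups."""
    if sizes.sum() == 0:
        raise ValueError("all group sizes are zero")
    quota = sizes / sizes.sum() * n_total
    alloc = np.floor(quota).astype(int)
    rem = n_total - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:rem]] += 1
    return alloc


def simulate_cohort(spec: CohortSpec, n_total: Optional[int] = None) -> pd.DataFrame:
    """Draw a synthetic patient table from the generating model.

    ``n_total`` defaults to the sum of the group sizes; otherwise patients
    are allocated proportionally (largest remainder). Reproducible under
    the spec's seed.
    """
    sizes = np.array([g.size for g in spec.groups])
    if n_total is None:
        n_total = int(sizes.sum())
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    alloc = _allocate(sizes, n_total)

    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(
        _latent_correlation(spec.spearman) + 1e-12 * np.eye(len(spec.variables))
    )
    rows = []
    pid = 0
    for g, n_g in zip(spec.groups, alloc):
        if n_g == 0:
            continue
        z = rng.standard_normal((n_g, len(spec.variables))) @ chol.T
        data = {}
        for j, var in enumerate(spec.variables):
            data[var] = g.means[var] + g.sds[var] * z[:, j]
        df_g = pd.DataFrame(data)
        df_g.insert(0, "group", g.name)
        df_g.insert(1, "extraction", g.label)
        df_g.insert(0, "patient_id", [f"P{pid + i:04d}" for i in range(n_g)])
        pid += n_g
        rows.append(df_g)
    table = pd.concat(rows, ignore_index=True)

    for resp, model in spec.response_models.items():
        y = np.full(len(table), float(model.get("intercept", 0.0)))
        for col, coef in model.get("coefficients", {}).items():
            y = y + coef * table[col].to_numpy(dtype=float)
        sd = float(model.get("noise_sd", 0.0))
        if sd > 0:
            y = y + sd * rng.standard_normal(len(table))
        table[resp] = y
    return table


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Two-group cohort matching the published sample structure.

    Group sizes 22 (extraction) / 20 (nonextraction); per-group means/SDs
    for treatment duration, age, FMA, ANB, the three thickness changes and
    pre-treatment soft-tissue thickness; a shared whole-sample Spearman
    target over the same variables. The target matrix is positive
    definite as given.
    """
    rho = np.eye(8)
    pairs = {
        (0, 1): -0.192, (0, 2): -0.115, (0, 3): -0.038, (0, 4): 0.010,
        (0, 5): -0.066, (0, 6): -0.158, (0, 7): -0.203,
        (1, 2): -0.219, (1, 3): -0.005, (1, 4): 0.108, (1, 5): 0.090,
        (1, 6): -0.070, (1, 7): -0.065,
        (2, 3): 0.275, (2, 4): -0.309, (2, 5): -0.312, (2, 6): -0.013,
        (2, 7): 0.236,
        (3, 4): -0.005, (3, 5): -0.198, (3, 6): -0.276, (3, 7): -0.118,
        (4, 5): 0.784, (4, 6): -0.031, (4, 7): -0.059,
        (5, 6): 0.533, (5, 7): 0.182,
        (6, 7): 0.308,
    }
    for (i, j), v in pairs.items():
        rho[i, j] = rho[j, i] = v

    extraction = GroupSpec(
        name="extraction",
        label=1,
        size=22,
        means={
            "duration_d": 903.545, "age_y": 24.591, "FMA_deg": 25.091,
            "ANB_deg": 3.759, "MM_change_mm": 1.284, "MAS_change_mm": 1.270,
            "FT_change_mm": 0.006, "ST_pre_mm": 8.291,
        },
        sds={
            "duration_d": 170.390, "age_y": 4.043, "FMA_deg": 5.246,
            "ANB_deg": 2.426, "MM_change_mm": 0.586, "MAS_change_mm": 0.780,
            "FT_change_mm": 0.491, "ST_pre_mm": 1.291,
        },
    )
    nonextraction = GroupSpec(
        name="nonextraction",
        label=0,
        size=20,
        means={
            "duration_d": 679.909, "age_y": 27.227, "FMA_deg": 24.000,
            "ANB_deg": 4.265, "MM_change_mm": 0.931, "MAS_change_mm": 0.675,
            "FT_change_mm": -0.302, "ST_pre_mm": 8.406,
        },
        sds={
            "duration_d": 265.823, "age_y": 6.339, "FMA_deg": 5.561,
            "ANB_deg": 3.374, "MM_change_mm": 0.658, "MAS_change_mm": 0.822,
            "FT_change_mm": 0.458, "ST_pre_mm": 1.024,
        },
    )
    return CohortSpec(groups=[extraction, nonextraction], spearman=rho, seed=seed)
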