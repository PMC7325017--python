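"""Region clipping, deviation analysis and the thickness decomposition."""

import numpy as np
import pytest
import trimesh

from massetry import (
    PhantomParams,
    apply_transform,
    average_deviation,
    build_frame,
    build_mas_boundary,
    clip_region,
    lateral_half,
    make_phantom,
    masseter_axes,
    patient_changes,
    st_thickness,
)
from massetry.anatomy import Plane
from massetry.regions import RegionBoundary, TimepointData
from conftest import random_rigid, register_case


def square_patch():
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    return trimesh.Trimesh(vertices=v, faces=[[0, 1, 2], [0, 2, 3]], process=False)


def box_boundary(x_cut=None):
    """All-permissive boundary, optionally keeping x <= x_cut."""
    far = 100.0
    upper = (
        Plane((x_cut, 0, 0), (-1, 0, 0))
        if x_cut is not None
        else Plane((far, 0, 0), (-1, 0, 0))
    )
    return RegionBoundary(
        upper=upper,
        lower=Plane((-far, 0, 0), (1, 0, 0)),
        anterior=Plane((0, far, 0), (0, -1, 0)),
        posterior=Plane((0, -far, 0), (0, 1, 0)),
        side="R",
    )


class TestClipRegion:
    def test_fully_inside_mesh_unchanged(self):
        patch = square_patch()
        out = clip_region(patch, box_boundary())
        assert out.area == pytest.approx(patch.area, abs=1e-12)

    def test_midplane_split_halves_area(self):
        out = clip_region(square_patch(), box_boundary(x_cut=0.5))
        assert out.area == pytest.approx(0.5, abs=1e-9)

    def test_full_exclusion_names_offending_plane(self):
        with pytest.raises(ValueError, match="upper"):
            clip_region(square_patch(), box_boundary(x_cut=-1.0))


class TestAverageDeviation:
    def test_identical_surfaces_give_zero(self):
        s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        assert average_deviation(s, s, signed=True) == 0.0

    def test_uniform_inward_offset_is_positive(self):
        s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        moved = s.copy()
        moved.vertices = moved.vertices - 1.0 * np.asarray(s.vertex_normals)
        assert average_deviation(s, moved, signed=True) == pytest.approx(1.0, abs=1e-6)

    def test_concentric_spheres_analytic_distance(self):
        outer = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        inner = trimesh.creation.icosphere(subdivisions=4, radius=9.0)
        assert average_deviation(outer, inner, signed=True) == pytest.approx(
            1.0, rel=0.02
        )

    def test_outward_motion_is_negative(self):
        outer = trimesh.creation.icosphere(subdivisions=3, radius=9.0)
        bigger = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        assert average_deviation(outer, bigger, signed=True) < 0

    def test_empty_mesh_rejected(self):
        s = trimesh.creation.icosphere(subdivisions=1)
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            average_deviation(s, empty)
        with pytest.raises(ValueError):
            average_deviation(empty, s)


class TestMasseterAxes:
    def slab(self, extents=(10.0, 25.0, 40.0)):
        # ml x, ap y, si z — slab proportions of a masseter
        return trimesh.creation.box(extents=extents).subdivide()

    def test_axis_aligned_slab_recovers_axes(self, coarse_frame):
        axes = masseter_axes(self.slab(), coarse_frame)
        assert abs(axes.si_axis @ [0, 0, 1]) > 1 - 1e-6
        assert abs(axes.ap_axis @ [0, 1, 0]) > 1 - 1e-6
        assert abs(axes.ml_axis @ [1, 0, 0]) > 1 - 1e-6
        ev = axes.explained_variance
        assert ev["si"] >= ev["ap"] >= ev["ml"]
        assert not axes.degenerate

    def test_eigenvalues_match_analytic_box_covariance(self, coarse_frame):
        """Labeled PCA eigenvalues match the closed-form second moment of
        the box vertex lattice (equal vertex count per face: the two
        h-faces contribute h^2, the four side faces h^2/3 each, so
        E[x^2] = 5 h^2 / 9 along every half-extent h)."""
        ex = np.array([10.0, 25.0, 40.0])
        mesh = trimesh.creation.box(extents=ex)
        for _ in range(4):  # dense per-face vertex lattice
            mesh = mesh.subdivide()
        a, b, c = ex / 2.0
        expected = {"ml": 5 * a**2 / 9, "ap": 5 * b**2 / 9, "si": 5 * c**2 / 9}
        axes = masseter_axes(mesh, coarse_frame)
        for key in expected:
            assert axes.explained_variance[key] == pytest.approx(
                expected[key], rel=0.02
            )

    def test_equivariance_up_to_sign(self, coarse_frame, coarse_phantom):
        mesh = coarse_phantom.pre.masseters["R"]
        axes0 = masseter_axes(mesh, coarse_frame)
        rng = np.random.default_rng(5)
        for _ in range(5):
            T = random_rigid(rng, max_deg=30)  # keep labels stable
            fr1 = build_frame(coarse_phantom.pre.landmarks.transformed(T.apply))
            axes1 = masseter_axes(apply_transform(mesh, T), fr1)
            for a0, a1 in [
                (axes0.si_axis, axes1.si_axis),
                (axes0.ap_axis, axes1.ap_axis),
            ]:
                assert abs((T.rotation @ a0) @ a1) > 1 - 1e-6

    def test_sphere_flags_degenerate(self, coarse_frame):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        axes = masseter_axes(sph, coarse_frame)
        assert axes.degenerate


class TestLateralHalf:
    def test_slab_half_area(self, coarse_frame):
        slab = trimesh.creation.box(extents=(10.0, 25.0, 40.0)).subdivide()
        axes = masseter_axes(slab, coarse_frame)
        half = lateral_half(slab, axes, coarse_frame, "R")
        assert half.area == pytest.approx(slab.area / 2.0, rel=0.02)

    def test_retained_vertices_on_lateral_side(self, coarse_frame, coarse_phantom):
        mesh = coarse_phantom.pre.masseters["R"]
        axes = masseter_axes(mesh, coarse_frame)
        half = lateral_half(mesh, axes, coarse_frame, "R")
        proj = (np.asarray(half.vertices) - axes.centroid) @ axes.ml_axis
        assert np.all(proj >= -1e-9)

    def test_side_flip_swaps_halves(self, coarse_frame):
        slab = trimesh.creation.box(extents=(10.0, 25.0, 40.0)).subdivide()
        axes = masseter_axes(slab, coarse_frame)
        right = lateral_half(slab, axes, coarse_frame, "R")
        left = lateral_half(slab, axes, coarse_frame, "L")
        assert right.area + left.area == pytest.approx(slab.area, rel=1e-6)
        assert right.bounds[1][0] > left.bounds[1][0] - 1e-9


class TestBoundary:
    def test_upper_plane_at_zygomatic_margin(self, coarse_phantom, coarse_frame):
        lm = coarse_phantom.pre.landmarks
        b = build_mas_boundary(coarse_frame, lm, coarse_phantom.pre.masseters["R"], "R")
        z0 = lm.contour("zygomatic_lower", "R")[:, 2].min()
        # the upper plane contains the supporting height z = z0
        assert abs(b.upper.signed_distance([0.0, 0.0, z0])) < 1e-9

    def test_normals_perpendicular_to_sagittal(self, coarse_phantom, coarse_frame):
        b = build_mas_boundary(
            coarse_frame,
            coarse_phantom.pre.landmarks,
            coarse_phantom.pre.masseters["R"],
            "R",
        )
        for _, plane in b.planes():
            assert abs(plane.normal @ coarse_frame.sagittal.normal) < 1e-9

    def test_equivariance_under_rigid_transforms(self, coarse_phantom):
        lm = coarse_phantom.pre.landmarks
        muscle = coarse_phantom.pre.masseters["R"]
        fr0 = build_frame(lm)
        b0 = build_mas_boundary(fr0, lm, muscle, "R")
        rng = np.random.default_rng(17)
        for _ in range(20):
            T = random_rigid(rng)
            lm1 = lm.transformed(T.apply)
            b1 = build_mas_boundary(
                build_frame(lm1), lm1, apply_transform(muscle, T), "R"
            )
            for (_, p0), (_, p1) in zip(b0.planes(), b1.planes()):
                assert np.allclose(T.rotation @ p0.normal, p1.normal, atol=1e-6)
                assert abs(p1.signed_distance(T.apply(p0.point))) < 1e-6

    def test_empty_muscle_rejected(self, coarse_phantom, coarse_frame):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            build_mas_boundary(
                coarse_frame, coarse_phantom.pre.landmarks, empty, "R"
            )


class TestThicknessPipeline:
    def test_st_uniform_offset(self, coarse_frame):
        """Face = muscle lateral surface offset outward 8 mm along the
        analytic normals; tessellated finely enough that the chordal
        (faceting) bias of the offset surface is below the 1% band."""
        from massetry.synthetic import PhantomParams, _superellipsoid

        v, f, n = _superellipsoid(PhantomParams(), "R", 5)
        muscle = trimesh.Trimesh(v, f, process=False)
        axes = masseter_axes(muscle, coarse_frame)
        lat = lateral_half(muscle, axes, coarse_frame, "R")
        face = trimesh.Trimesh(v + 8.0 * n, f, process=False)
        assert st_thickness(lat, face) == pytest.approx(8.0, rel=0.01)

    def test_st_recovers_phantom_fat_field(self, fine_phantom, coarse_frame):
        muscle = fine_phantom.pre.masseters["R"]
        axes = masseter_axes(muscle, coarse_frame)
        lat = lateral_half(muscle, axes, coarse_frame, "R")
        st = st_thickness(lat, fine_phantom.pre.face)
        assert st == pytest.approx(fine_phantom.truth.st_pre_mm, rel=0.02)

    def test_no_change_phantom_measures_zero(self):
        case = make_phantom(
            PhantomParams(delta_mm=0.0, delta_ft=0.0, resolution_mm=5.0)
        )
        ch, _ = patient_changes(case.pre, case.post)
        assert abs(ch.mas_change_mm) < 0.01
        assert abs(ch.mm_change_mm) < 0.01
        assert abs(ch.ft_change_mm) < 0.01

    def test_parameter_recovery(self):
        case = make_phantom(
            PhantomParams(delta_mm=1.0, delta_ft=0.3, resolution_mm=5.0)
        )
        ch, prov = patient_changes(case.pre, case.post)
        assert ch.mm_change_mm == pytest.approx(1.0, rel=0.05)
        assert ch.ft_change_mm == pytest.approx(0.3, abs=0.05 + 0.3 * 0.05)
        assert ch.mas_change_mm == pytest.approx(1.3, rel=0.05)
        assert set(prov) == {"L", "R"}

    def test_combined_is_mean_of_sides(self, coarse_phantom):
        ch, _ = patient_changes(coarse_phantom.pre, coarse_phantom.post)
        for key, val in [
            ("mas_change_mm", ch.mas_change_mm),
            ("mm_change_mm", ch.mm_change_mm),
            ("ft_change_mm", ch.ft_change_mm),
        ]:
            assert val == pytest.approx(
                np.mean([ch.per_side[s][key] for s in ("L", "R")]), abs=1e-12
            )

    def test_ft_is_exact_st_difference(self, coarse_phantom):
        ch, _ = patient_changes(coarse_phantom.pre, coarse_phantom.post)
        for s in ("L", "R"):
            ps = ch.per_side[s]
            assert ps["ft_change_mm"] == ps["st_pre_mm"] - ps["st_post_mm"]

    def test_decomposition_closure(self, coarse_phantom):
        ch, _ = patient_changes(coarse_phantom.pre, coarse_phantom.post)
        assert abs(ch.mas_change_mm - (ch.mm_change_mm + ch.ft_change_mm)) < 0.05

    def test_sign_conventions(self):
        shrink = make_phantom(PhantomParams(delta_mm=1.0, delta_ft=0.2, resolution_mm=5.0))
        ch, _ = patient_changes(shrink.pre, shrink.post)
        assert ch.mm_change_mm > 0 and ch.mas_change_mm > 0 and ch.ft_change_mm > 0
        fatten = make_phantom(
            PhantomParams(delta_mm=-0.5, delta_ft=-0.4, resolution_mm=5.0)
        )
        ch, _ = patient_changes(fatten.pre, fatten.post)
        assert ch.mm_change_mm < 0 and ch.ft_change_mm < 0

    def test_rigid_invariance_of_all_outputs(self, coarse_phantom):
        ch0, _ = patient_changes(coarse_phantom.pre, coarse_phantom.post)
        T = random_rigid(np.random.default_rng(23), max_deg=60)

        def move(tp):
            return TimepointData(
                face=apply_transform(tp.face, T),
                masseters={s: apply_transform(m, T) for s, m in tp.masseters.items()},
                landmarks=tp.landmarks.transformed(T.apply),
            )

        ch1, _ = patient_changes(move(coarse_phantom.pre), move(coarse_phantom.post))
        assert ch1.mas_change_mm == pytest.approx(ch0.mas_change_mm, abs=1e-6)
        assert ch1.mm_change_mm == pytest.approx(ch0.mm_change_mm, abs=1e-6)
        assert ch1.ft_change_mm == pytest.approx(ch0.ft_change_mm, abs=1e-6)

    def test_resolution_convergence(self):
        """Halving the target edge length moves each estimate by < 1% of
        the scale it is measured on: MAS/MM relative to themselves, FT and
        ST relative to the soft-tissue thickness (FT is a small difference
        of two ~8 mm distances, so its discretization error lives on the
        ST scale)."""
        vals = []
        for res in (4.0, 2.0):
            case = make_phantom(
                PhantomParams(delta_mm=1.0, delta_ft=0.3, resolution_mm=res)
            )
            ch, _ = patient_changes(case.pre, case.post)
            vals.append(ch)
        a, b = vals
        assert abs(a.mas_change_mm - b.mas_change_mm) < 0.01 * abs(b.mas_change_mm)
        assert abs(a.mm_change_mm - b.mm_change_mm) < 0.01 * abs(b.mm_change_mm)
        assert abs(a.ft_change_mm - b.ft_change_mm) < 0.01 * b.st_pre_mm
        assert abs(a.st_pre_mm - b.st_pre_mm) < 0.05 * b.st_pre_mm

    def test_registered_misaligned_phantom(self):
        from massetry.transforms import RigidTransform

        T = RigidTransform.from_axis_angle((0.1, 0.2, 0.97), 2.0, (2.0, -1.0, 0.5))
        case = make_phantom(
            PhantomParams(delta_mm=1.0, delta_ft=0.3, true_transform=T, resolution_mm=5.0)
        )
        _, post = register_case(case)
        ch, _ = patient_changes(case.pre, post)
        assert ch.mm_change_mm == pytest.approx(1.0, rel=0.05)
        assert ch.ft_change_mm == pytest.approx(0.3, abs=0.065)
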