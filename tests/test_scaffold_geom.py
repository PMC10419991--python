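import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from periograft.meshing import (
    MeshError,
    SurfaceMesh,
    boundary_loops,
    report,
    signed_volume,
    surface_area,
)
from periograft.scaffold_geom import (
    WHOLE_SPACE,
    RegionSpec,
    RigidScale,
    bridge,
    crop_by_region,
    extend_patch,
    fill_holes,
    invert_normals,
    stitch_loops,
    transform,
    translate,
    trim_against,
)


def icosphere(radius=1.0, subdivisions=4) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def open_cube(unit_cube) -> SurfaceMesh:
    """Unit cube missing its top (+z) face; one square boundary loop."""
    keep = np.ones(12, dtype=bool)
    keep[2] = keep[3] = False
    return SurfaceMesh(unit_cube.vertices, unit_cube.faces[keep])


class TestRegions:
    def test_whole_space_crop_is_identity(self, unit_cube):
        out = crop_by_region(unit_cube, WHOLE_SPACE)
        assert out.n_faces == unit_cube.n_faces

    def test_half_space_keeps_hand_counted_area(self, unit_cube):
        # For the frozen cube triangulation: the -x face (area 1) plus one
        # triangle (area 0.5) of each of the four side faces have centroid
        # x <= 0.5, totalling 3.0 of 6.0
        r = RegionSpec("half_spaces", half_spaces=(((0.5, 0, 0), (1.0, 0, 0)),))
        out = crop_by_region(unit_cube, r)
        assert surface_area(out) == pytest.approx(3.0)

    def test_region_missing_mesh_errors(self, unit_cube):
        r = RegionSpec("box", box=((10, 10, 10), (11, 11, 11)))
        with pytest.raises(MeshError, match="no faces"):
            crop_by_region(unit_cube, r)

    def test_lasso_selects_projected_interior(self, unit_cube):
        # square lasso over the center of the top face, projected along z
        poly = np.array(
            [[0.25, 0.25, 5], [0.75, 0.25, 5], [0.75, 0.75, 5], [0.25, 0.75, 5]]
        )
        r = RegionSpec("surface_lasso", lasso=(poly, (0, 0, 1)))
        out = crop_by_region(unit_cube, r)
        cent = out.vertices[out.faces].mean(axis=1)
        assert ((cent[:, :2] > 0.25) & (cent[:, :2] < 0.75)).all()

    def test_region_dict_roundtrip(self):
        for r in (
            RegionSpec("box", box=((0, 0, 0), (1, 2, 3))),
            RegionSpec("half_spaces", half_spaces=(((0, 0, 0), (0, 0, 1)),)),
        ):
            assert RegionSpec.from_dict(r.to_dict()) == r


class TestInvertNormals:
    def test_involution(self, unit_cube):
        twice = invert_normals(invert_normals(unit_cube))
        assert np.array_equal(twice.faces, unit_cube.faces)

    def test_cube_volume_flips_sign(self, unit_cube):
        assert signed_volume(invert_normals(unit_cube)) == pytest.approx(-1.0)


class TestTransform:
    def test_identity_is_bit_identical(self, unit_cube):
        out = transform(unit_cube, RigidScale())
        assert np.array_equal(out.vertices, unit_cube.vertices)

    def test_scale_098_shrinks_every_bbox_edge_exactly(self, unit_cube):
        center = tuple(unit_cube.vertices.mean(axis=0))
        out = transform(unit_cube, RigidScale(scale=0.98, scale_center_mm=center))
        dims = out.bounds[1] - out.bounds[0]
        assert np.allclose(dims, 0.98, atol=1e-12)

    def test_scale_098_volume_ratio_is_cubed(self, unit_cube):
        center = tuple(unit_cube.vertices.mean(axis=0))
        out = transform(unit_cube, RigidScale(scale=0.98, scale_center_mm=center))
        assert abs(signed_volume(out) - 0.98**3) < 1e-9

    @given(
        angle=st.floats(-180, 180),
        axis=st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
            lambda a: np.linalg.norm(a) > 1e-3
        ),
        tr=st.tuples(*[st.floats(-5, 5) for _ in range(3)]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rigid_transform_preserves_pairwise_distances(self, angle, axis, tr):
        from tests.conftest import CUBE_FACES, CUBE_VERTS

        unit_cube = SurfaceMesh(CUBE_VERTS.copy(), CUBE_FACES.copy())
        axis = tuple(np.asarray(axis) / np.linalg.norm(axis))
        t = RigidScale(rotation_axis=axis, angle_deg=angle, translation_mm=tr,
                       pivot_mm=(0.3, -0.2, 0.1))
        out = transform(unit_cube, t)
        d0 = np.linalg.norm(unit_cube.vertices[:, None] - unit_cube.vertices[None], axis=2)
        d1 = np.linalg.norm(out.vertices[:, None] - out.vertices[None], axis=2)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)

    def test_zero_axis_with_angle_rejected(self):
        with pytest.raises(ValueError, match="zero rotation axis"):
            RigidScale(rotation_axis=(0, 0, 0), angle_deg=10)


class TestTrimAgainst:
    def limiter_plane(self, z=0.0, half=3.0):
        v = np.array(
            [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]]
        )
        return SurfaceMesh(v, np.array([[0, 1, 2], [0, 2, 3]]))

    def test_far_limiter_on_kept_side_is_identity(self, unit_cube):
        out = trim_against(unit_cube, self.limiter_plane(z=-50), "above", (0, 0, 1))
        assert out.n_faces == unit_cube.n_faces

    def test_sphere_equator_trim_keeps_half_the_area(self):
        sph = icosphere()
        out = trim_against(sph, self.limiter_plane(0.0), "above", (0, 0, 1))
        assert surface_area(out) == pytest.approx(surface_area(sph) / 2, rel=0.02)

    def test_everything_beyond_limiter_errors(self, unit_cube):
        with pytest.raises(MeshError, match="every face"):
            trim_against(unit_cube, self.limiter_plane(z=50), "above", (0, 0, 1))

    def test_crop_and_trim_by_independent_half_spaces_commute(self, unit_cube):
        r = RegionSpec("half_spaces", half_spaces=(((0.5, 0, 0), (1.0, 0, 0)),))
        limiter = self.limiter_plane(0.6)
        a = trim_against(crop_by_region(unit_cube, r), limiter, "below", (0, 0, 1))
        b = crop_by_region(trim_against(unit_cube, limiter, "below", (0, 0, 1)), r)
        assert np.allclose(np.sort(a.vertices[a.faces].reshape(-1, 9), axis=0),
                           np.sort(b.vertices[b.faces].reshape(-1, 9), axis=0))


class TestFillHoles:
    def test_watertight_input_unchanged(self, unit_cube):
        out = fill_holes(unit_cube, max_boundary_len_mm=100.0)
        assert out.n_faces == unit_cube.n_faces

    def test_cube_missing_face_closed_exactly(self, unit_cube):
        out = fill_holes(open_cube(unit_cube), max_boundary_len_mm=10.0)
        rep = report(out)
        assert rep.watertight
        assert abs(rep.signed_volume_mm3 - 1.0) < 1e-6

    def test_threshold_respected(self, unit_cube):
        opened = open_cube(unit_cube)
        out = fill_holes(opened, max_boundary_len_mm=1.0)  # rim length is 4
        assert out.n_faces == opened.n_faces

    def test_nonmanifold_boundary_errors_listing_edges(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float
        )
        bowtie = SurfaceMesh(verts, np.array([[0, 1, 2], [0, 3, 4]]))
        with pytest.raises(MeshError, match="non-manifold"):
            fill_holes(bowtie, 100.0)


class TestBridge:
    def test_square_hole_splits_into_two_loops(self, unit_cube):
        opened = open_cube(unit_cube)
        assert len(boundary_loops(opened)) == 1
        out = bridge(opened, (0.5, 0.0, 1.0), (0.5, 1.0, 1.0))
        assert len(boundary_loops(out)) == 2

    def test_bridge_then_fill_is_watertight_with_unit_volume(self, unit_cube):
        out = bridge(open_cube(unit_cube), (0.5, 0.0, 1.0), (0.5, 1.0, 1.0))
        closed = fill_holes(out, max_boundary_len_mm=10.0)
        rep = report(closed)
        assert rep.watertight
        assert abs(rep.signed_volume_mm3 - 1.0) < 1e-6

    def test_degenerate_endpoints_error(self, unit_cube):
        opened = open_cube(unit_cube)
        with pytest.raises(MeshError, match="degenerate"):
            bridge(opened, (0.5, 0.0, 1.0), (0.5, 0.0, 1.0))


class TestExtendPatch:
    def test_zero_translation_changes_nothing(self, unit_cube):
        out = extend_patch(unit_cube, WHOLE_SPACE, (0, 0, 0))
        assert out.n_faces == unit_cube.n_faces
        assert surface_area(out) == pytest.approx(6.0)

    def test_flat_strip_raised_by_1mm(self):
        strip = SurfaceMesh(
            np.array([[0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]], dtype=float),
            np.array([[0, 1, 2], [0, 2, 3]]),
        )
        out = extend_patch(strip, WHOLE_SPACE, (0, 0, 1.0))
        assert out.bounds[1][2] - out.bounds[0][2] == pytest.approx(1.0)


class TestStitchLoops:
    def test_stitching_offset_copies_closes_a_prism(self, unit_cube):
        bottom = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:2])  # -z face
        top = invert_normals(translate(bottom, (0, 0, 2.0)))
        merged = SurfaceMesh(
            np.vstack([bottom.vertices, top.vertices]),
            np.vstack([invert_normals(bottom).faces, top.faces[:, ::-1] + 8]),
        )
        # orient both patches as a solid's bottom/top: bottom -z, top +z
        loops = boundary_loops(merged)
        assert len(loops) == 2
        out = stitch_loops(merged, loops[0], loops[1])
        rep = report(out)
        assert rep.boundary_edge_count == 0
        assert abs(rep.signed_volume_mm3) == pytest.approx(2.0)


class TestPurity:
    def test_operators_do_not_mutate_inputs(self, unit_cube):
        v, f = unit_cube.vertices.copy(), unit_cube.faces.copy()
        crop_by_region(unit_cube, WHOLE_SPACE)
        invert_normals(unit_cube)
        translate(unit_cube, (1, 2, 3))
        fill_holes(open_cube(unit_cube), 10.0)
        assert np.array_equal(unit_cube.vertices, v)
        assert np.array_equal(unit_cube.faces, f)
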