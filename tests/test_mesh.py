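import math

import numpy as np
import pytest
import trimesh

import aneuwall as aw
from aneuwall.mesh import MeshError, TriangleMesh


def signed_volume_zflux(mesh: TriangleMesh) -> float:
    """Independent volume formula: divergence theorem with F = (0, 0, z)."""
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    zbar = v[f][:, :, 2].mean(axis=1)
    return float(0.5 * (zbar * cross[:, 2]).sum())


class TestSurfaceArea:
    def test_unit_cube(self, unit_cube):
        assert aw.surface_area(unit_cube) == pytest.approx(6.0, rel=1e-12)

    def test_single_triangle(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert aw.surface_area(m) == pytest.approx(0.5, rel=1e-12)

    def test_icosphere_converges_to_sphere(self, icosphere):
        assert aw.surface_area(icosphere) == pytest.approx(4 * math.pi, rel=0.01)

    def test_orientation_independent(self, unit_cube):
        flipped = TriangleMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        assert aw.surface_area(flipped) == aw.surface_area(unit_cube)


class TestEnclosedVolume:
    def test_unit_cube(self, unit_cube):
        assert aw.enclosed_volume(unit_cube) == pytest.approx(1.0, rel=1e-12)

    def test_icosphere(self, icosphere):
        assert aw.enclosed_volume(icosphere) == pytest.approx(4 * math.pi / 3, rel=0.01)

    def test_inverted_cube_raises_orientation_error(self, unit_cube):
        inv = TriangleMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
        with pytest.raises(MeshError, match="orient"):
            aw.enclosed_volume(inv)

    def test_open_mesh_error_names_loops(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(MeshError, match="1 boundary loop"):
            aw.enclosed_volume(m)

    def test_divergence_matches_tetrahedron_sum(self, unit_cube, icosphere,
                                                default_pair):
        capped = aw.cap_all_ports(default_pair.model_a)
        for mesh in (unit_cube, icosphere, capped):
            vol = aw.enclosed_volume(mesh)
            assert abs(vol - signed_volume_zflux(mesh)) / vol < 1e-12

    def test_rigid_motion_invariance(self, icosphere):
        rng = np.random.default_rng(42)
        vol0 = aw.enclosed_volume(icosphere)
        area0 = aw.surface_area(icosphere)
        for _ in range(5):
            q = rng.normal(size=4)
            rot = trimesh.transformations.quaternion_matrix(q / np.linalg.norm(q))[:3, :3]
            shift = rng.uniform(-5, 5, size=3)
            moved = TriangleMesh(icosphere.vertices @ rot.T + shift, icosphere.faces)
            assert abs(aw.surface_area(moved) - area0) / area0 < 1e-10
            assert abs(aw.enclosed_volume(moved) - vol0) / vol0 < 1e-10


class TestBoundaryLoops:
    def test_closed_sphere_has_none(self, icosphere):
        assert aw.boundary_loops(icosphere) == []

    def test_flat_disk_has_one(self):
        disk = aw.make_grid_mesh(5, 5)
        assert len(aw.boundary_loops(disk)) == 1

    def test_open_cylinder_has_two(self):
        pair = aw.make_coaxial_cylinder_case(1.0, 2.0, 4.0)
        assert len(aw.boundary_loops(pair.model_b)) == 2

    def test_nonmanifold_edge_rejected(self):
        verts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]]
        faces = [[0, 1, 2], [0, 1, 3], [0, 1, 4]]
        with pytest.raises(MeshError, match="non-manifold"):
            TriangleMesh(verts, faces)


class TestCapPort:
    def test_capped_hemisphere_volume(self):
        pair = aw.make_disk_hemisphere_case(1.0)
        hemi = pair.model_a
        loop = aw.boundary_loops(hemi)[0]
        closed = aw.cap_port(hemi, loop)
        assert not aw.boundary_loops(closed)
        assert aw.enclosed_volume(closed) == pytest.approx(2 * math.pi / 3, rel=0.01)

    def test_planar_square_hole_area(self):
        # open box without its top: capping restores the missing unit square
        grid = aw.make_grid_mesh(2, 2)  # unit square, 2 triangles
        box = trimesh.creation.box(extents=(1, 1, 1))
        verts = np.asarray(box.vertices, float) + 0.5
        faces = np.asarray(box.faces, np.int64)
        top = [i for i, f in enumerate(faces) if np.all(verts[f][:, 2] > 0.99)]
        open_box = TriangleMesh(verts, np.delete(faces, top, axis=0))
        area0 = aw.surface_area(open_box)
        capped = aw.cap_port(open_box, aw.boundary_loops(open_box)[0])
        assert aw.surface_area(capped) - area0 == pytest.approx(1.0, rel=1e-9)

    def test_foreign_loop_rejected(self, unit_cube):
        disk = aw.make_grid_mesh(3, 3)
        loop = aw.boundary_loops(disk)[0]
        pair = aw.make_disk_hemisphere_case(1.0)
        with pytest.raises(MeshError, match="not a boundary loop"):
            aw.cap_port(pair.model_a, loop)


class TestVertexRing:
    def test_interior_grid_vertex_has_six_neighbors(self):
        grid = aw.make_grid_mesh(5, 5)
        interior = 2 * 5 + 2  # (2, 2)
        assert len(aw.vertex_ring(grid, interior)) == 6

    def test_triangle_corner_has_two(self):
        m = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert set(aw.vertex_ring(m, 0)) == {1, 2}

    def test_out_of_range(self, unit_cube):
        with pytest.raises(MeshError, match="out of range"):
            aw.vertex_ring(unit_cube, 10 ** 6)


def test_degenerate_face_rejected():
    with pytest.raises(MeshError, match="degenerate"):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
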