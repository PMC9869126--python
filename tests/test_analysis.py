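import math

import numpy as np
import pytest

import aneuwall as aw
from aneuwall.analysis import (CoefficientRecord, ExtremePoint, ScalarField,
                               extract_isolines, find_extreme_points,
                               isoline_regularity)
from aneuwall.mesh import MeshError


class TestCoefficients:
    @pytest.mark.parametrize("i_ba,i_s,expected", [
        # printed per-aneurysm values: ratio must reproduce the printed I_delta
        (35.23238381, 4.0406732118, 8.719434105),
        (27.85632782, 16.8198177498, 1.656161097),
    ])
    def test_idelta_reproduces_printed_records(self, i_ba, i_s, expected):
        assert aw.compute_Idelta(i_ba, i_s) == pytest.approx(expected, rel=1e-6)

    def test_idelta_unity_when_equal(self):
        assert aw.compute_Idelta(3.3, 3.3) == 1.0

    def test_is_ratio(self):
        assert aw.compute_IS(2 * math.pi, math.pi) == pytest.approx(2.0)
        assert aw.compute_IS(5.0, 5.0) == 1.0
        pair = aw.make_disk_hemisphere_case(1.0)
        ratio = aw.compute_IS(aw.surface_area(pair.model_a),
                              aw.surface_area(pair.model_b))
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_aneurysm_volume(self, unit_cube):
        assert aw.aneurysm_volume(unit_cube, unit_cube) == 0.0
        big = aw.TriangleMesh(unit_cube.vertices * 2, unit_cube.faces)
        assert aw.aneurysm_volume(big, unit_cube) == pytest.approx(7.0, rel=1e-9)
        with pytest.raises(MeshError, match="negative"):
            aw.aneurysm_volume(unit_cube, big)

    def test_record_identity_enforced(self):
        with pytest.raises(ValueError, match="I_delta"):
            CoefficientRecord(id=1, location="MCA", I_S=2.0, volume=10.0,
                              I_BA=10.0, I_delta=3.0, group="A")


class TestIsolines:
    def test_sphere_equator_length(self, icosphere):
        z = icosphere.vertices[:, 2]
        iso = extract_isolines(z, icosphere, n_levels=199)
        mid = int(np.argmin(np.abs(iso.levels)))
        assert abs(iso.levels[mid]) < 1e-9
        polys = iso.polylines[mid]
        assert len(polys) == 1 and iso.closed[mid][0]
        length = np.linalg.norm(np.diff(polys[0], axis=0), axis=1).sum()
        assert length == pytest.approx(2 * math.pi, rel=0.02)

    def test_single_level_at_midrange(self):
        grid = aw.make_grid_mesh(5, 5)
        f = grid.vertices[:, 0]
        iso = extract_isolines(f, grid, n_levels=1)
        assert len(iso.levels) == 1
        assert iso.levels[0] == pytest.approx(0.5)

    def test_constant_field_warns_and_is_empty(self):
        grid = aw.make_grid_mesh(4, 4)
        with pytest.warns(UserWarning, match="constant"):
            iso = extract_isolines(np.ones(len(grid.vertices)), grid)
        assert len(iso.levels) == 0

    def test_units_carried_by_scalar_field(self):
        f = ScalarField(np.array([1.0, 2.0]), units="mm")
        assert f.units == "mm"
        with pytest.raises(ValueError):
            ScalarField(np.array([1.0, np.nan]))


class TestExtremePoints:
    def test_single_basin(self):
        grid = aw.make_grid_mesh(21, 21)
        x, y = grid.vertices[:, 0], grid.vertices[:, 1]
        f = (x - 0.5) ** 2 + (y - 0.5) ** 2
        pts = find_extreme_points(f, grid)
        assert len(pts) == 1 and pts[0].is_global_min
        assert np.allclose(pts[0].position[:2], [0.5, 0.5])

    def test_two_wells(self):
        grid = aw.make_grid_mesh(41, 41)
        x, y = grid.vertices[:, 0], grid.vertices[:, 1]
        f = (-np.exp(-((x - 0.3) ** 2 + (y - 0.3) ** 2) / 0.01)
             - np.exp(-((x - 0.72) ** 2 + (y - 0.7) ** 2) / 0.01))
        pts = find_extreme_points(f, grid)
        assert len(pts) == 2
        assert sum(p.is_global_min for p in pts) == 1

    def test_constant_field_has_no_minima(self):
        grid = aw.make_grid_mesh(4, 4)
        assert find_extreme_points(np.ones(len(grid.vertices)), grid) == []

    def test_global_min_inside_lowest_isoline_region(self, default_inflation):
        # the predicted rupture site sits in the innermost ring: its sublevel
        # component must not touch the patch rim
        _, patch, res = default_inflation
        mesh = res.inflated_mesh
        pts = find_extreme_points(res.thickness, mesh)
        gm = next(p for p in pts if p.is_global_min)
        levels = extract_isolines(res.thickness, mesh, n_levels=200).levels
        lowest = levels[0]
        rim = {int(v) for e in mesh.boundary_edges() for v in e}
        # flood the sublevel set from the minimum
        adj = mesh.adjacency()
        seen = {gm.vertex}
        stack = [gm.vertex]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen and res.thickness[w] < lowest:
                    seen.add(w)
                    stack.append(w)
        assert not (seen & rim)


class TestIsolineRegularity:
    def test_linear_field_evenly_spaced(self):
        grid = aw.make_grid_mesh(41, 41)
        x = grid.vertices[:, 0]
        f = np.abs(x - 0.5)
        vi = int(np.flatnonzero((x == 0.5)
                                & (grid.vertices[:, 1] == 0.5))[0])
        pt = ExtremePoint(vertex=vi, position=grid.vertices[vi].copy(),
                          thickness=float(f[vi]), is_global_min=True)
        assert isoline_regularity(f, grid, pt, k_levels=8) < 1e-9

    def test_quadratic_bowl_spacing_shrinks_outward(self):
        grid = aw.make_grid_mesh(41, 41)
        x, y = grid.vertices[:, 0], grid.vertices[:, 1]
        f = (x - 0.5) ** 2 + (y - 0.5) ** 2
        gm = next(p for p in find_extreme_points(f, grid) if p.is_global_min)
        cv = isoline_regularity(f, grid, gm, k_levels=8)
        assert cv > 0.05

    def test_too_few_levels_rejected(self):
        grid = aw.make_grid_mesh(11, 11)
        x, y = grid.vertices[:, 0], grid.vertices[:, 1]
        f = (x - 0.5) ** 2 + (y - 0.5) ** 2
        gm = next(p for p in find_extreme_points(f, grid) if p.is_global_min)
        with pytest.raises(ValueError, match="k_levels"):
            isoline_regularity(f, grid, gm, k_levels=2)

    def test_boundary_extreme_point_rejected(self):
        grid = aw.make_grid_mesh(11, 11)
        f = grid.vertices[:, 0]
        pt = ExtremePoint(vertex=0, position=grid.vertices[0].copy(),
                          thickness=0.0, is_global_min=True)
        with pytest.raises(ValueError, match="boundary"):
            isoline_regularity(f, grid, pt, k_levels=3)
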