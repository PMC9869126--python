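"""Parametric saccular-aneurysm fixtures with known ground truth.

Real inputs to the thickness pipeline are patient surface meshes segmented
from 3D rotational angiography; no such meshes are deposited, so this module
generates the same *kind* of geometry analytically:

* ``make_model_pair`` — a tubular parent artery with a saccular dome
  (ellipsoidal, optional bleb) grown over a circular neck.  ``model_a`` is
  the vessel *with* the sac (the blow-molding "mold"), ``model_b`` the
  parent artery as if the sac had never formed; outside the neck region the
  two meshes are identical and they share the neck rim polyline vertex for
  vertex.
* ``make_disk_hemisphere_case`` / ``make_coaxial_cylinder_case`` — analytic
  benchmarks for the inflation surrogate (known area ratio 2 and known
  uniform stretch b/a respectively).
* ``sample_cohort`` — synthetic cohorts of per-aneurysm coefficient records
  with log-normal I_S and I_BA marginals per clinical group, emulating the
  statistical structure of the bundled 48-aneurysm table.

The neck patch of ``model_b`` is an isometric disk on the cylinder wall, so
its ground-truth area is exactly pi * r_n**2; sac area and volume ground
truth are obtained by refining the parametric surface until the quadrature
changes by less than 0.1 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .analysis import CoefficientRecord
from .mesh import BoundaryLoop, MeshError, TriangleMesh, boundary_loops, cap_all_ports

__all__ = [
    "AneurysmSpec",
    "BlebSpec",
    "ModelPair",
    "CohortSpec",
    "GroupParams",
    "make_model_pair",
    "make_disk_hemisphere_case",
    "make_coaxial_cylinder_case",
    "make_grid_mesh",
    "sample_cohort",
]

DEFAULT_SEED = 20200101


# --------------------------------------------------------------------------
# specs and containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlebSpec:
    """Secondary bulge on the dome.

    direction : azimuth (radians) of the bleb center around the neck axis
    radius : bump amplitude (mm); also sets its angular footprint
    offset : parametric latitude of the center, 0 = rim, 1 = apex
    """

    direction: float = 0.0
    radius: float = 0.5
    offset: float = 0.6


@dataclass(frozen=True)
class AneurysmSpec:
    """Geometry of one synthetic saccular aneurysm (lengths in mm)."""

    parent_radius: float = 2.0
    parent_length: float = 20.0
    neck_radius: float = 1.6
    dome_axes: tuple[float, float, float] = (2.2, 2.0, 2.4)
    bleb: Optional[BlebSpec] = None
    resolution: float = 0.35
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        a, b, c = self.dome_axes
        if min(self.parent_radius, self.parent_length, self.neck_radius,
               a, b, c, self.resolution) <= 0:
            raise ValueError("all lengths in AneurysmSpec must be positive")
        if self.neck_radius >= min(a, b):
            raise ValueError(
                f"infeasible spec: neck radius {self.neck_radius} mm is not "
                f"smaller than the dome semi-axes {min(a, b)} mm"
            )
        half_circ = math.pi * self.parent_radius
        if self.neck_radius > 0.8 * min(half_circ, self.parent_length / 2):
            raise ValueError("neck radius too large for the parent tube")


@dataclass
class ModelPair:
    """Vessel-with-sac mold (A), reconstructed parent (B), shared neck rim."""

    model_a: TriangleMesh
    model_b: TriangleMesh
    neck_curve: np.ndarray  # (n, 3) ordered closed polyline on both meshes
    truth: Optional[dict] = None


# --------------------------------------------------------------------------
# low-level mesh assembly helpers
# --------------------------------------------------------------------------

def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v = vertices
    f = faces
    return float(np.einsum("ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))) / 6.0


def weld(vertices: np.ndarray, faces: np.ndarray, tol: float = 1e-8):
    """Merge vertices closer than ``tol`` and drop collapsed faces."""
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(len(vertices))

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(vertices))])
    uniq, new_index = np.unique(roots, return_inverse=True)
    new_vertices = vertices[uniq]
    new_faces = new_index[faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 2] != new_faces[:, 0])
    )
    return new_vertices, new_faces[keep]


def orient_consistent(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Make face windings consistent and globally outward.

    Winding consistency by breadth-first propagation across shared edges;
    global sign by requiring positive enclosed volume of the port-capped
    surface.
    """
    faces = faces.copy()
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for e in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(e), max(e)), []).append(fi)

    def directed_edges(fi):
        a, b, c = faces[fi]
        return [(a, b), (b, c), (c, a)]

    visited = np.zeros(len(faces), dtype=bool)
    for start in range(len(faces)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        while stack:
            fi = stack.pop()
            for a, b in directed_edges(fi):
                for gj in edge_faces[(min(a, b), max(a, b))]:
                    if visited[gj] or gj == fi:
                        continue
                    # consistent neighbors traverse the shared edge oppositely
                    if (a, b) in directed_edges(gj):
                        faces[gj] = faces[gj][::-1]
                    visited[gj] = True
                    stack.append(gj)

    mesh = TriangleMesh(vertices, faces)
    closed = cap_all_ports(mesh) if not mesh.is_closed() else mesh
    if _signed_volume(closed.vertices, closed.faces) < 0:
        faces = faces[:, ::-1]
    return faces


def _fix_planar_winding(points2d: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip 2D triangles with negative signed area (CCW convention)."""
    p = points2d
    a = p[faces[:, 0]]
    b = p[faces[:, 1]]
    c = p[faces[:, 2]]
    s = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    out = faces.copy()
    out[s < 0] = out[s < 0][:, ::-1]
    return out


def _polar_disk_2d(radius: float, n_phi: int, n_r: int, phis: np.ndarray):
    """Structured polar disk: center vertex + n_r rings of n_phi vertices."""
    verts = [np.zeros((1, 2))]
    for i in range(1, n_r + 1):
        r = radius * i / n_r
        verts.append(np.column_stack([r * np.cos(phis), r * np.sin(phis)]))
    v = np.vstack(verts)
    faces = []
    ring = lambda i, j: 1 + (i - 1) * n_phi + (j % n_phi)
    for j in range(n_phi):
        faces.append([0, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_r):
        for j in range(n_phi):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j + 1), ring(i + 1, j)
            faces.append([a, b, c])
            faces.append([a, c, d])
    faces = np.array(faces, dtype=np.int64)
    return v, _fix_planar_winding(v, faces)


def _tube_with_hole_2d(half_width: float, half_length: float, r_n: float,
                       phis: np.ndarray, h: float):
    """Rectangle [-W/2,W/2]x[-L/2,L/2] minus the neck disk.

    O-grid layout: a structured annulus blends the rim circle onto a square
    collar, and the remaining rectangle-minus-square is triangulated from a
    regular grid by Delaunay (the square hole is convex, so dropping
    triangles with centroids inside it leaves a conforming boundary).  Grid
    lines include the rectangle edges, so the wrap-around seam columns and
    the port rows match exactly when mapped to the cylinder.
    """
    n_phi = len(phis)
    cos, sin = np.cos(phis), np.sin(phis)
    a_s = min(2.0 * r_n, 0.75 * min(half_width, half_length))
    if a_s < 1.1 * r_n:
        raise ValueError("neck radius too large for the parent tube")

    # annulus circle -> square
    square = (a_s / np.maximum(np.abs(cos), np.abs(sin)))[:, None] \
        * np.column_stack([cos, sin])
    inner = r_n * np.column_stack([cos, sin])
    n_r = max(4, math.ceil((a_s - r_n) / h))
    ts = np.linspace(0.0, 1.0, n_r + 1)
    rings = [(1 - t) * inner + t * square for t in ts]
    verts = np.vstack(rings)
    idx = lambda i, j: i * n_phi + (j % n_phi)
    faces = []
    for i in range(n_r):
        for j in range(n_phi):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j + 1), idx(i + 1, j)
            faces.append([a, b, c])
            faces.append([a, c, d])
    faces = np.array(faces, dtype=np.int64)

    # outer region grid (coarser far field; chord error stays ~1 % of r_p)
    pitch = 1.5 * h
    nx = max(4, math.ceil(2 * half_width / pitch))
    ny = max(4, math.ceil(2 * half_length / pitch))
    xs = np.linspace(-half_width, half_width, nx + 1)
    ys = np.linspace(-half_length, half_length, ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    margin = 0.45 * max((2 * half_width) / nx, (2 * half_length) / ny)
    keep = np.maximum(np.abs(grid[:, 0]), np.abs(grid[:, 1])) > a_s + margin
    outer_pts = np.vstack([square, grid[keep]])

    from scipy.spatial import Delaunay

    tri = Delaunay(outer_pts)
    cent = outer_pts[tri.simplices].mean(axis=1)
    outside = np.maximum(np.abs(cent[:, 0]), np.abs(cent[:, 1])) > a_s * (1 - 1e-9)
    outer_faces = tri.simplices[outside]

    all_verts = np.vstack([verts, outer_pts])
    all_faces = np.vstack([faces, outer_faces + len(verts)])
    all_verts, all_faces = weld(all_verts, all_faces, tol=1e-9)
    return all_verts, _fix_planar_winding(all_verts, all_faces)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


# --------------------------------------------------------------------------
# model pair construction
# --------------------------------------------------------------------------

def _cylinder_map(uv: np.ndarray, r_p: float) -> np.ndarray:
    """Isometric wrap of the unrolled plane onto the cylinder.

    u is arc length around the tube (u=0 at the neck center, outward normal
    +z), v is position along the tube axis (x).
    """
    theta = uv[:, 0] / r_p
    return np.column_stack([uv[:, 1], r_p * np.sin(theta), r_p * np.cos(theta)])


def _sac_points(t: np.ndarray, phi: np.ndarray, spec: AneurysmSpec,
                rim_fn) -> np.ndarray:
    """Parametric dome surface S(t, phi); t=0 is the rim, t=1 the apex.

    An ellipsoid cap (semi-axes a along the tube axis, b around it, c in the
    outward normal) is blended onto the exact rim curve over a collar in t
    with a smoothstep falloff, so the sac meets the rim vertex-for-vertex
    while the upper dome is exactly ellipsoidal.
    """
    a, b, c = spec.dome_axes
    r_p = spec.parent_radius
    p0 = np.array([0.0, 0.0, r_p])
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    nrm = np.array([0.0, 0.0, 1.0])

    s = np.clip(spec.neck_radius / math.sqrt(a * b), 0.05, 0.92)
    alpha0 = math.pi - math.asin(s)  # dome equator wider than the neck
    z0 = -c * math.cos(alpha0)
    center = p0 + z0 * nrm

    # the rim angle phi runs cos(phi) around the tube (e2) and sin(phi) along
    # the axis (e1); the dome fibers must follow the same convention or the
    # blend collar twists
    alpha = alpha0 * (1.0 - t)
    ell = (center[None, :]
           + np.outer(a * np.sin(alpha) * np.sin(phi), e1)
           + np.outer(b * np.sin(alpha) * np.cos(phi), e2)
           + np.outer(c * np.cos(alpha), nrm))
    ell0 = (center[None, :]
            + np.outer(a * math.sin(alpha0) * np.sin(phi), e1)
            + np.outer(b * math.sin(alpha0) * np.cos(phi), e2)
            + np.outer(np.full_like(phi, c * math.cos(alpha0)), nrm))
    w = _smoothstep(t / 0.35)
    pts = ell + (1.0 - w)[:, None] * (rim_fn(phi) - ell0)

    if spec.bleb is not None:
        bl = spec.bleb
        dphi = (phi - bl.direction + math.pi) % (2 * math.pi) - math.pi
        ang_width = max(bl.radius / math.sqrt(a * b), 0.15)
        d2 = ((t - bl.offset) / 0.18) ** 2 + (dphi / ang_width) ** 2
        radial = pts - center[None, :]
        radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-12)
        pts = pts + (bl.radius * np.exp(-d2) * _smoothstep(t / 0.35))[:, None] * radial
    return pts


def _build_sac(spec: AneurysmSpec, phis: np.ndarray, rim_points: np.ndarray,
               n_t: int):
    """Disk-topology dome mesh whose t=0 ring is exactly ``rim_points``."""
    n_phi = len(phis)

    def rim_fn(phi):
        # phi values are always the construction angles, in order
        return np.tile(rim_points, (len(phi) // n_phi, 1)) if len(phi) != n_phi else rim_points

    ts = np.linspace(0.0, 1.0, n_t + 1)
    rows = []
    for t in ts[:-1]:
        rows.append(_sac_points(np.full(n_phi, t), phis, spec, rim_fn))
    apex = _sac_points(np.array([1.0]), np.array([0.0]),
                       spec, lambda p: rim_points[:1])
    verts = np.vstack(rows + [apex])
    apex_id = len(verts) - 1
    idx = lambda k, j: k * n_phi + (j % n_phi)
    faces = []
    for k in range(n_t - 1):
        for j in range(n_phi):
            a, b = idx(k, j), idx(k, j + 1)
            c, d = idx(k + 1, j + 1), idx(k + 1, j)
            faces.append([a, b, c])
            faces.append([a, c, d])
    for j in range(n_phi):
        faces.append([idx(n_t - 1, j), idx(n_t - 1, j + 1), apex_id])
    return verts, np.array(faces, dtype=np.int64)


def _sac_truth(spec: AneurysmSpec, rtol: float = 1e-3):
    """Sac area and volume by refinement of the parametric surface.

    Doubles the parametric resolution until both quantities change by less
    than ``rtol`` (0.1 %).  Only meaningful for bleb-free domes, where the
    surface is a fixed analytic family.
    """
    prev = None
    n_phi, n_t = 64, 48
    for _ in range(6):
        phis = 2 * math.pi * (np.arange(n_phi) + 0.5) / n_phi
        rim_uv = spec.neck_radius * np.column_stack([np.cos(phis), np.sin(phis)])
        rim_points = _cylinder_map(rim_uv, spec.parent_radius)
        sv, sf = _build_sac(spec, phis, rim_points, n_t)
        # close with the isometric neck disk to measure the sac volume
        dv2, df = _polar_disk_2d(spec.neck_radius, n_phi, max(4, n_t // 3), phis)
        dv = _cylinder_map(dv2, spec.parent_radius)
        verts, faces = weld(np.vstack([sv, dv]), np.vstack([sf, df + len(sv)]))
        faces = orient_consistent(verts, faces)
        closed = TriangleMesh(verts, faces)
        sac_area = float(TriangleMesh(sv, sf).face_areas().sum())
        vol = abs(_signed_volume(closed.vertices, closed.faces))
        if prev is not None:
            da = abs(sac_area - prev[0]) / prev[0]
            dvl = abs(vol - prev[1]) / max(prev[1], 1e-12)
            if max(da, dvl) < rtol:
                return sac_area, vol
        prev = (sac_area, vol)
        n_phi *= 2
        n_t *= 2
    return prev


def make_model_pair(spec: AneurysmSpec, compute_truth: bool = True) -> ModelPair:
    """Build the mold / parent-artery pair for one synthetic aneurysm.

    Both meshes contain the identical parent-tube-with-hole region and the
    identical neck rim polyline; ``model_a`` adds the dome, ``model_b`` the
    isometric neck disk of the undisturbed tube wall.  ``compute_truth``
    controls the (more expensive) refinement of the analytic reference
    values; it is only available for bleb-free domes.
    """
    r_p, r_n, L = spec.parent_radius, spec.neck_radius, spec.parent_length
    h = spec.resolution
    half_width = math.pi * r_p
    n_phi = max(24, 4 * math.ceil(2 * math.pi * r_n / h / 4))
    phis = 2 * math.pi * (np.arange(n_phi) + 0.5) / n_phi

    tube2d, tube_faces = _tube_with_hole_2d(half_width, L / 2, r_n, phis, h)
    tube_v = _cylinder_map(tube2d, r_p)

    rim_uv = r_n * np.column_stack([np.cos(phis), np.sin(phis)])
    rim_points = _cylinder_map(rim_uv, r_p)

    # model B: tube + isometric neck disk
    n_r_disk = max(3, round(r_n / h))
    disk2d, disk_faces = _polar_disk_2d(r_n, n_phi, n_r_disk, phis)
    disk_v = _cylinder_map(disk2d, r_p)
    vb, fb = weld(np.vstack([tube_v, disk_v]),
                  np.vstack([tube_faces, disk_faces + len(tube_v)]))
    fb = orient_consistent(vb, fb)
    model_b = TriangleMesh(vb, fb)

    # model A: tube + dome
    a, b, c = spec.dome_axes
    arc = (math.pi - math.asin(min(r_n / math.sqrt(a * b), 0.92))) * max(c, math.sqrt(a * b))
    n_t = max(8, math.ceil(arc / h))
    sac_v, sac_f = _build_sac(spec, phis, rim_points, n_t)
    va, fa = weld(np.vstack([tube_v, sac_v]),
                  np.vstack([tube_faces, sac_f + len(tube_v)]))
    fa = orient_consistent(va, fa)
    model_a = TriangleMesh(va, fa)

    truth = None
    if spec.bleb is None and compute_truth:
        s_a, sac_vol = _sac_truth(spec)
        s_b = math.pi * r_n ** 2  # isometric unrolling: exact
        truth = {
            "S_A": s_a,
            "S_B": s_b,
            "sac_volume": sac_vol,
            "I_S": s_a / s_b,
        }
    return ModelPair(model_a, model_b, rim_points.copy(), truth)


# --------------------------------------------------------------------------
# analytic benchmark cases
# --------------------------------------------------------------------------

def make_disk_hemisphere_case(r: float, resolution: float = 0.08) -> ModelPair:
    """Flat disk membrane under a hemispherical mold on the same rim.

    The exact area ratio is 2, so the inflated mean thickness must be half
    the initial thickness.  ``resolution`` is the target edge length as a
    fraction of ``r``.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    h = resolution * r
    n_phi = max(24, 4 * math.ceil(2 * math.pi * r / h / 4))
    phis = 2 * math.pi * (np.arange(n_phi) + 0.5) / n_phi
    n_r = max(4, round(r / h))
    disk2d, disk_f = _polar_disk_2d(r, n_phi, n_r, phis)
    disk_v = np.column_stack([disk2d, np.zeros(len(disk2d))])
    patch = TriangleMesh(disk_v, disk_f)  # CCW in plane -> normals +z (toward mold)

    # hemisphere on the same rim circle, apex +z
    betas = np.linspace(math.pi / 2, 0.0, n_r * 2 + 1)
    rows = [np.column_stack([r * math.sin(b) * np.cos(phis),
                             r * math.sin(b) * np.sin(phis),
                             np.full(n_phi, r * math.cos(b))])
            for b in betas[:-1]]
    verts = np.vstack(rows + [np.array([[0.0, 0.0, r]])])
    apex = len(verts) - 1
    idx = lambda k, j: k * n_phi + (j % n_phi)
    faces = []
    n_rows = len(betas) - 1
    for k in range(n_rows - 1):
        for j in range(n_phi):
            aq, bq = idx(k, j), idx(k, j + 1)
            cq, dq = idx(k + 1, j + 1), idx(k + 1, j)
            faces.append([aq, bq, cq])
            faces.append([aq, cq, dq])
    for j in range(n_phi):
        faces.append([idx(n_rows - 1, j), idx(n_rows - 1, j + 1), apex])
    mold = TriangleMesh(verts, np.array(faces, dtype=np.int64))

    rim = disk_v[1 + (n_r - 1) * n_phi:1 + n_r * n_phi]
    truth = {"S_A": 2 * math.pi * r ** 2, "S_B": math.pi * r ** 2, "I_S": 2.0,
             "stretch": None}
    return ModelPair(model_a=mold, model_b=patch, neck_curve=rim.copy(), truth=truth)


def make_coaxial_cylinder_case(a: float, b: float, length: float,
                               resolution: float = 0.1) -> ModelPair:
    """Open cylinder membrane (radius a) inside a coaxial mold (radius b).

    Inflation is a pure radial dilation with uniform stretch b/a, hence a
    uniform thickness ratio a/b.  ``resolution`` is the target edge length
    as a fraction of ``a``.
    """
    if not 0 < a <= b:
        raise ValueError("require 0 < a <= b")

    def open_cylinder(radius: float, n_phi: int, n_z: int) -> TriangleMesh:
        phis = 2 * math.pi * (np.arange(n_phi) + 0.5) / n_phi
        zs = np.linspace(-length / 2, length / 2, n_z + 1)
        rows = [np.column_stack([radius * np.cos(phis), radius * np.sin(phis),
                                 np.full(n_phi, z)]) for z in zs]
        verts = np.vstack(rows)
        idx = lambda k, j: k * n_phi + (j % n_phi)
        faces = []
        for k in range(n_z):
            for j in range(n_phi):
                aq, bq = idx(k, j), idx(k, j + 1)
                cq, dq = idx(k + 1, j + 1), idx(k + 1, j)
                faces.append([aq, bq, cq])
                faces.append([aq, cq, dq])
        return TriangleMesh(verts, np.array(faces, dtype=np.int64))

    h = resolution * a
    n_phi = max(24, round(2 * math.pi * a / h))
    n_z = max(6, round(length / h))
    patch = open_cylinder(a, n_phi, n_z)
    mold = open_cylinder(b, n_phi, n_z)
    truth = {"stretch": b / a, "S_A": 2 * math.pi * b * length,
             "S_B": 2 * math.pi * a * length, "I_S": b / a}
    return ModelPair(model_a=mold, model_b=patch, neck_curve=patch.vertices[:n_phi].copy(),
                     truth=truth)


def make_grid_mesh(nx: int, ny: int, lx: float = 1.0, ly: float = 1.0) -> TriangleMesh:
    """Flat regular triangulated rectangle in z=0 (test scaffolding)."""
    xs = np.linspace(0, lx, nx)
    ys = np.linspace(0, ly, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    idx = lambda i, j: i * ny + j
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = idx(i, j), idx(i + 1, j), idx(i + 1, j + 1), idx(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


# --------------------------------------------------------------------------
# synthetic cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Log-normal marginals and volume model for one clinical group.

    log I_S ~ N(mu_log_is, sd_log_is); log I_BA ~ N(mu_log_iba, sd_log_iba);
    log V = vol_intercept + vol_slope * log I_S + N(0, vol_resid_sd).
    """

    n: int
    mu_log_is: float
    sd_log_is: float
    mu_log_iba: float
    sd_log_iba: float
    vol_intercept: float
    vol_slope: float
    vol_resid_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group count must be >= 0")
        if min(self.sd_log_is, self.sd_log_iba, self.vol_resid_sd) <= 0:
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Per-group generating distributions for a synthetic cohort."""

    groups: dict[str, GroupParams]
    seed: int = DEFAULT_SEED

    @staticmethod
    def from_table(records: list[CoefficientRecord],
                   counts: Optional[dict[str, int]] = None,
                   seed: int = DEFAULT_SEED) -> "CohortSpec":
        """Fit group marginals and volume models from a cohort table."""
        groups = {}
        for g in sorted({r.group for r in records}):
            rs = [r for r in records if r.group == g]
            lis = np.log([r.I_S for r in rs])
            liba = np.log([r.I_BA for r in rs])
            lvol = np.log([r.volume for r in rs])
            slope, intercept = np.polyfit(lis, lvol, 1)
            resid = lvol - (intercept + slope * lis)
            groups[g] = GroupParams(
                n=counts[g] if counts else len(rs),
                mu_log_is=float(lis.mean()),
                sd_log_is=float(lis.std(ddof=1)),
                mu_log_iba=float(liba.mean()),
                sd_log_iba=float(liba.std(ddof=1)),
                vol_intercept=float(intercept),
                vol_slope=float(slope),
                vol_resid_sd=float(max(resid.std(ddof=1), 1e-6)),
            )
        return CohortSpec(groups=groups, seed=seed)

    def truth_auc(self, marker: str, positive: str, negative: str) -> float:
        """Closed-form AUC of the generating distributions.

        Markers are log-normal (I_delta as the ratio of two independent
        log-normals), so AUC = Phi((mu_p - mu_n) / sqrt(s_p^2 + s_n^2)) on
        the log scale.
        """
        from scipy.stats import norm

        def moments(g: GroupParams):
            if marker == "I_S":
                return g.mu_log_is, g.sd_log_is
            if marker == "I_BA":
                return g.mu_log_iba, g.sd_log_iba
            if marker == "I_delta":
                return (g.mu_log_iba - g.mu_log_is,
                        math.hypot(g.sd_log_iba, g.sd_log_is))
            raise ValueError(f"unknown marker {marker!r}")

        mp, sp = moments(self.groups[positive])
        mn, sn = moments(self.groups[negative])
        return float(norm.cdf((mp - mn) / math.hypot(sp, sn)))


_LOCATIONS = np.array(["MCA", "AcomA", "PcomA", "ICA"])
_LOCATION_P = np.array([0.66, 0.14, 0.12, 0.08])


def sample_cohort(spec: CohortSpec) -> list[CoefficientRecord]:
    """Draw one synthetic cohort; I_delta is always derived as I_BA / I_S."""
    rng = np.random.default_rng(spec.seed)
    records: list[CoefficientRecord] = []
    next_id = 1
    for g in sorted(spec.groups):
        p = spec.groups[g]
        for _ in range(p.n):
            log_is = rng.normal(p.mu_log_is, p.sd_log_is)
            log_iba = rng.normal(p.mu_log_iba, p.sd_log_iba)
            log_vol = rng.normal(p.vol_intercept + p.vol_slope * log_is,
                                 p.vol_resid_sd)
            i_s = math.exp(log_is)
            i_ba = math.exp(log_iba)
            records.append(CoefficientRecord(
                id=next_id,
                location=str(rng.choice(_LOCATIONS, p=_LOCATION_P)),
                I_S=i_s,
                volume=math.exp(log_vol),
                I_BA=i_ba,
                I_delta=i_ba / i_s,
                group=g,
            ))
            next_id += 1
    return records
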