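"""Neck splitting and parent-artery patch reconstruction.

The aneurysm neck (ostium) is treated as a closed curve on the vessel
surface — a curved surface boundary, never a planar cut.  Given the
vessel-with-sac mesh and an operator-supplied neck polyline, the sac is
separated from the parent artery along mesh edges; the resulting neck hole
in the parent can then be filled with a smooth interpolating patch that
continues the parent wall, reconstructing the artery as if the sac had
never formed.  Neck delineation itself is an interactive step and is taken
as input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .mesh import BoundaryLoop, MeshError, TriangleMesh, boundary_loops, surface_area

__all__ = ["NeckSplit", "split_at_neck", "fill_neck_patch", "neck_split"]


@dataclass
class NeckSplit:
    """Result of separating one aneurysm from its parent artery.

    ``sac_mesh`` and ``patch_mesh`` share the identical rim polyline;
    S_A and S_B are their surface areas (the quantities entering I_S).
    """

    sac_mesh: TriangleMesh
    parent_mesh: TriangleMesh
    patch_mesh: TriangleMesh
    S_A: float
    S_B: float


def _snap_cycle(mesh: TriangleMesh, polyline: np.ndarray) -> list[int]:
    """Snap a closed 3D polyline to a closed cycle of mesh vertices/edges."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise MeshError("neck polyline must be an (n>=3, 3) array of points")
    tree = cKDTree(mesh.vertices)
    _, snapped = tree.query(pts)
    cycle: list[int] = []
    for v in snapped:
        if not cycle or cycle[-1] != v:
            cycle.append(int(v))
    if len(cycle) > 1 and cycle[0] == cycle[-1]:
        cycle.pop()
    if len(cycle) < 3:
        raise MeshError("neck polyline does not snap to a closed cycle")
    # bridge consecutive snapped vertices that are not direct neighbors
    adj = mesh.adjacency()
    full: list[int] = []
    for i, v in enumerate(cycle):
        w = cycle[(i + 1) % len(cycle)]
        full.append(v)
        if w in adj[v]:
            continue
        # BFS shortest path along edges
        prev = {v: None}
        queue = [v]
        found = False
        while queue and not found:
            nxt = []
            for q in queue:
                for r in adj[q]:
                    if r not in prev:
                        prev[r] = q
                        if r == w:
                            found = True
                            break
                        nxt.append(r)
                if found:
                    break
            queue = nxt
        if not found:
            raise MeshError("neck polyline cannot be connected along mesh edges")
        path = []
        cur = w
        while cur != v:
            path.append(cur)
            cur = prev[cur]
        full.extend(reversed(path[1:]))
    return full


def split_at_neck(model_a: TriangleMesh, neck) -> tuple[TriangleMesh, TriangleMesh]:
    """Separate sac and parent along the neck curve.

    ``neck`` may be an (n, 3) polyline (snapped to the nearest mesh
    vertices, bridged along edges) or a BoundaryLoop-like sequence of vertex
    indices.  Cutting the rim edges must split the surface into exactly two
    components; the sac is the one that carries no vessel port.  Returns
    ``(sac_mesh, parent_mesh)``; both keep a copy of the rim vertices.
    """
    if isinstance(neck, BoundaryLoop):
        cycle = list(neck.vertices)
    elif isinstance(neck, np.ndarray) and neck.ndim == 2:
        cycle = _snap_cycle(model_a, neck)
    else:
        cycle = [int(v) for v in neck]
    rim_edges = set()
    for i, v in enumerate(cycle):
        w = cycle[(i + 1) % len(cycle)]
        if v == w:
            raise MeshError("neck cycle contains a repeated vertex")
        rim_edges.add((min(v, w), max(v, w)))

    # face adjacency graph, rim edges removed
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(model_a.faces):
        for e in ((a, b), (b, c), (c, a)):
            key = (min(e), max(e))
            edge_faces.setdefault(key, []).append(fi)
    n_f = len(model_a.faces)
    g = lil_matrix((n_f, n_f), dtype=np.int8)
    for key, fs in edge_faces.items():
        if key in rim_edges or len(fs) < 2:
            continue
        g[fs[0], fs[1]] = 1
        g[fs[1], fs[0]] = 1
    n_comp, labels = connected_components(g.tocsr(), directed=False)
    if n_comp != 2:
        raise MeshError(
            f"neck curve does not separate the surface into two components "
            f"(got {n_comp})"
        )

    port_vertices = {int(v) for e in model_a.boundary_edges() for v in e}

    def submesh(face_mask: np.ndarray) -> TriangleMesh:
        faces = model_a.faces[face_mask]
        used = np.unique(faces)
        remap = -np.ones(len(model_a.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(model_a.vertices[used].copy(), remap[faces])

    comp_has_port = []
    for comp in range(2):
        verts = set(np.unique(model_a.faces[labels == comp]).tolist())
        comp_has_port.append(bool(verts & port_vertices))
    if comp_has_port[0] == comp_has_port[1]:
        raise MeshError("cannot identify the sac: port assignment ambiguous")
    sac_comp = 0 if not comp_has_port[0] else 1
    sac = submesh(labels == sac_comp)
    parent = submesh(labels != sac_comp)
    return sac, parent


def fill_neck_patch(parent_mesh: TriangleMesh, neck: BoundaryLoop) -> TriangleMesh:
    """Fill the neck hole with a smooth interpolating curved patch.

    The hole is triangulated by a centroid fan, midpoint-subdivided to gain
    interior freedom, and interior vertices are placed at the fixed point of
    umbrella (graph-Laplacian) smoothing with the rim held — i.e. the
    discrete harmonic fill, solved directly.  The patch is a curved surface
    spanning the rim, not a planar cap.
    """
    loops = boundary_loops(parent_mesh)
    ring = None
    target = set(neck.vertices)
    for lp in loops:
        if set(lp.vertices) == target:
            ring = list(lp.vertices)
            break
    if ring is None:
        raise MeshError("neck is not a boundary loop of the parent mesh")
    if len(ring) != len(set(ring)):
        raise MeshError("neck loop is not simple")

    rim_pts = parent_mesh.vertices[ring]
    centroid = rim_pts.mean(axis=0)
    n = len(ring)
    verts = np.vstack([rim_pts, centroid])
    # fan continuing the parent's outward orientation (boundary edges run
    # opposite to face winding)
    faces = np.array([[(i + 1) % n, i, n] for i in range(n)], dtype=np.int64)

    rim_edge = float(np.linalg.norm(rim_pts - np.roll(rim_pts, -1, axis=0), axis=1).mean())
    spoke = float(np.linalg.norm(rim_pts - centroid, axis=1).mean())
    n_sub = int(np.clip(np.ceil(np.log2(max(spoke / rim_edge, 1.0))) + 1, 1, 4))

    fixed = np.zeros(len(verts), dtype=bool)
    fixed[:n] = True
    for _ in range(n_sub):
        verts, faces, fixed = _midpoint_subdivide(verts, faces, fixed)

    patch = TriangleMesh(verts, faces)
    interior = np.flatnonzero(~fixed)
    if len(interior):
        adj = patch.adjacency()
        n_v = len(verts)
        lap = lil_matrix((n_v, n_v))
        for i in range(n_v):
            for j in adj[i]:
                lap[i, j] = -1.0
            lap[i, i] = float(len(adj[i]))
        lap = lap.tocsr()
        a_ii = lap[interior][:, interior]
        a_ib = lap[interior][:, np.flatnonzero(fixed)]
        rhs = -a_ib @ verts[np.flatnonzero(fixed)]
        sol = spsolve(a_ii.tocsc(), rhs)
        verts = verts.copy()
        verts[interior] = np.atleast_2d(sol)
    return TriangleMesh(verts, faces)


def _midpoint_subdivide(verts: np.ndarray, faces: np.ndarray, fixed: np.ndarray):
    """1-to-4 midpoint subdivision; midpoints of fixed-fixed rim edges stay fixed."""
    boundary_edges = set()
    counts: dict[tuple[int, int], int] = {}
    for a, b, c in faces:
        for e in ((a, b), (b, c), (c, a)):
            key = (min(e), max(e))
            counts[key] = counts.get(key, 0) + 1
    for key, cnt in counts.items():
        if cnt == 1:
            boundary_edges.add(key)

    mid_index: dict[tuple[int, int], int] = {}
    new_verts = [verts]
    new_fixed = [fixed]
    next_id = len(verts)

    def midpoint(a, b):
        nonlocal next_id
        key = (min(a, b), max(a, b))
        if key not in mid_index:
            mid_index[key] = next_id
            new_verts.append(((verts[a] + verts[b]) / 2.0)[None, :])
            is_rim = key in boundary_edges and fixed[a] and fixed[b]
            new_fixed.append(np.array([is_rim]))
            next_id += 1
        return mid_index[key]

    out_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
    return (np.vstack(new_verts), np.array(out_faces, dtype=np.int64),
            np.concatenate(new_fixed))


def neck_split(model_a: TriangleMesh, neck) -> NeckSplit:
    """Split at the neck and reconstruct the parent patch in one call."""
    sac, parent = split_at_neck(model_a, neck)
    hole = None
    sac_rim = {tuple(np.round(p, 9)) for e in sac.boundary_edges()
               for p in sac.vertices[list(e)]}
    for lp in boundary_loops(parent):
        pts = {tuple(np.round(parent.vertices[v], 9)) for v in lp.vertices}
        if pts & sac_rim:
            hole = lp
            break
    if hole is None:
        raise MeshError("could not locate the neck hole on the parent mesh")
    patch = fill_neck_patch(parent, hole)
    return NeckSplit(
        sac_mesh=sac,
        parent_mesh=parent,
        patch_mesh=patch,
        S_A=surface_area(sac),
        S_B=surface_area(patch),
    )
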