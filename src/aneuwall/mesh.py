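"""Triangle-mesh geometry kernel.

Indexed triangle surfaces (vertices in mm, faces as 0-based CCW triples with
outward normals) carry the two vessel models used throughout the pipeline:
the vessel-with-sac "mold" and the reconstructed parent artery.  The kernel
provides exactly the primitives the thickness pipeline needs: areas, enclosed
volumes by the divergence theorem, boundary-loop extraction, capping of open
vessel ports, and one-ring queries for local-minimum detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "BoundaryLoop",
    "MeshError",
    "surface_area",
    "enclosed_volume",
    "boundary_loops",
    "cap_port",
    "vertex_ring",
]

# Faces below this area (mm^2) are rejected at construction.
DEGENERATE_AREA = 1e-12


class MeshError(ValueError):
    """Invalid mesh, field or query (non-manifold edge, open mesh, ...)."""


@dataclass(frozen=True)
class BoundaryLoop:
    """Closed cycle of boundary-edge vertices, in order."""

    vertices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class TriangleMesh:
    """Manifold-with-boundary triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, 0-based, counter-clockwise seen from outside
    """

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshError("non-finite vertex coordinate")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError("face vertex index out of range")
        areas = self.face_areas()
        if len(areas) and areas.min() < DEGENERATE_AREA:
            bad = np.flatnonzero(areas < DEGENERATE_AREA)
            raise MeshError(
                f"{len(bad)} degenerate (area < {DEGENERATE_AREA} mm^2) "
                f"face(s), e.g. face {bad[0]}"
            )
        counts = self._edge_counts()
        if len(counts) and counts.max() > 2:
            raise MeshError("non-manifold edge shared by more than two faces")

    # ---- derived quantities -------------------------------------------------

    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            f = self.faces
            cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(cross, axis=1)
        return self._cache["face_areas"]

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(cross, axis=1)
        return cross / norm[:, None]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident face areas."""
        va = np.zeros(len(self.vertices))
        np.add.at(va, self.faces.ravel(), np.repeat(self.face_areas() / 3.0, 3))
        return va

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals, unit length (zero rows stay zero)."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, f[:, k], cross)
        norm = np.linalg.norm(vn, axis=1)
        mask = norm > 0
        vn[mask] /= norm[mask, None]
        return vn

    def edges_sorted(self) -> np.ndarray:
        """(3m, 2) array of undirected edges, both columns sorted."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.sort(e, axis=1)

    def _edge_counts(self) -> np.ndarray:
        e = self.edges_sorted()
        if not len(e):
            return np.zeros(0, dtype=int)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def boundary_edges(self) -> np.ndarray:
        """Directed boundary edges (those appearing on exactly one face)."""
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        und = np.sort(directed, axis=1)
        uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        return directed[counts[inv] == 1]

    def adjacency(self) -> list[set]:
        """Vertex adjacency as list of neighbor sets (1-ring)."""
        if "adjacency" not in self._cache:
            adj: list[set] = [set() for _ in range(len(self.vertices))]
            for a, b, c in self.faces:
                adj[a].update((b, c))
                adj[b].update((a, c))
                adj[c].update((a, b))
            self._cache["adjacency"] = adj
        return self._cache["adjacency"]

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def bounding_box_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in mm^2 (orientation independent)."""
    return float(mesh.face_areas().sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in mm^3 by the divergence theorem.

    Sums signed tetrahedra spanned by the origin and each face; for a closed,
    consistently outward-oriented surface this equals the enclosed volume.
    Raises on open meshes (naming the boundary loops) and on negative totals
    (which indicate inward orientation).
    """
    loops = boundary_loops(mesh)
    if loops:
        sizes = ", ".join(str(len(lp)) for lp in loops)
        raise MeshError(
            f"mesh is open: {len(loops)} boundary loop(s) of size(s) {sizes}; "
            "cap the ports before computing enclosed volume"
        )
    v = mesh.vertices
    f = mesh.faces
    vol = float(np.einsum("ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))) / 6.0
    if vol < 0:
        raise MeshError(
            f"signed volume {vol:.6g} mm^3 is negative: faces appear to be "
            "oriented inward; flip the face winding"
        )
    return vol


def boundary_loops(mesh: TriangleMesh) -> list[BoundaryLoop]:
    """Closed loops of boundary edges, each edge used exactly once."""
    edges = mesh.boundary_edges()
    if not len(edges):
        return []
    succ: dict[int, list[int]] = {}
    for a, b in edges:
        succ.setdefault(int(a), []).append(int(b))
    loops = []
    # walk each directed boundary edge once
    remaining = {(int(a), int(b)) for a, b in edges}
    while remaining:
        start = next(iter(remaining))
        loop = [start[0]]
        cur = start
        while True:
            remaining.discard(cur)
            nxt_candidates = [b for b in succ.get(cur[1], []) if (cur[1], b) in remaining]
            if not nxt_candidates:
                if cur[1] == loop[0]:
                    break
                raise MeshError("boundary edges do not close into loops")
            loop.append(cur[1])
            cur = (cur[1], nxt_candidates[0])
        loops.append(BoundaryLoop(tuple(loop)))
    return loops


def cap_port(mesh: TriangleMesh, loop: BoundaryLoop) -> TriangleMesh:
    """Close one boundary loop with a triangle fan from its centroid.

    The cap preserves outward orientation.  Any triangulation of a planar
    port yields the same enclosed volume, so the simple centroid fan is
    exact for planar ports and adequate for the near-planar vessel ports;
    self-intersection of the cap is not checked.
    """
    existing = {lp.vertices for lp in boundary_loops(mesh)}
    # accept any rotation/reversal of a stored loop
    def _canon(seq):
        seq = list(seq)
        i = seq.index(min(seq))
        fwd = tuple(seq[i:] + seq[:i])
        rev = tuple([fwd[0]] + list(reversed(fwd[1:])))
        return min(fwd, rev)

    if _canon(loop.vertices) not in {_canon(lv) for lv in existing}:
        raise MeshError("loop is not a boundary loop of this mesh")

    ring = list(loop.vertices)
    centroid = mesh.vertices[ring].mean(axis=0)
    new_v = np.vstack([mesh.vertices, centroid])
    c = len(mesh.vertices)
    # boundary edges run opposite to face winding; fan (b, a, c) restores CCW
    ring_next = ring[1:] + ring[:1]
    fan = np.array([[b, a, c] for a, b in zip(ring, ring_next)], dtype=np.int64)
    return TriangleMesh(new_v, np.vstack([mesh.faces, fan]))


def cap_all_ports(mesh: TriangleMesh) -> TriangleMesh:
    """Cap every boundary loop; returns a closed mesh."""
    out = mesh
    while True:
        loops = boundary_loops(out)
        if not loops:
            return out
        out = cap_port(out, loops[0])


def vertex_ring(mesh: TriangleMesh, v: int) -> np.ndarray:
    """Unordered 1-ring neighbor indices of vertex ``v``."""
    if not (0 <= v < len(mesh.vertices)):
        raise MeshError(f"vertex index {v} out of range [0, {len(mesh.vertices)})")
    return np.array(sorted(mesh.adjacency()[v]), dtype=np.int64)
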