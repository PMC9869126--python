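"""Thickness-field analysis: isolines, extreme points, coefficients.

The inflated wall-thickness field is read the way an operator reads a
contour plot: 200 evenly spaced isolines are drawn between the field
extremes; nested closed rings mark extreme thickness points, and the global
minimum is the predicted translucent/rupture site.  Three dimensionless
coefficients summarize each aneurysm:

    I_S      = S_A / S_B          (area increase multiple)
    I_BA     = delta_B / delta_B' (thinning magnification at the minimum)
    I_delta  = I_BA / I_S         (inhomogeneity coefficient, the rupture
                                   risk marker; equals mean thickness over
                                   minimum thickness)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshError, TriangleMesh, enclosed_volume

__all__ = [
    "ScalarField",
    "IsolineSet",
    "ExtremePoint",
    "CoefficientRecord",
    "compute_IS",
    "compute_Idelta",
    "aneurysm_volume",
    "extract_isolines",
    "find_extreme_points",
    "isoline_regularity",
]


@dataclass
class ScalarField:
    """One finite value per mesh vertex; ``units`` is 'mm' for thickness."""

    values: np.ndarray
    units: str = "mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("scalar field must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("scalar field contains non-finite values")


def _field_values(f, mesh: TriangleMesh) -> np.ndarray:
    values = f.values if isinstance(f, ScalarField) else np.asarray(f, dtype=float)
    if len(values) != len(mesh.vertices):
        raise ValueError(
            f"field length {len(values)} != vertex count {len(mesh.vertices)}"
        )
    if not np.isfinite(values).all():
        raise ValueError("scalar field contains non-finite values")
    return values


@dataclass
class IsolineSet:
    """Level curves of a field: per level, a list of polylines.

    ``levels`` are the interior levels (endpoints excluded, contour-plot
    convention); ``polylines[k]`` is a list of (m, 3) point arrays and
    ``closed[k]`` the matching closed-curve flags.
    """

    levels: np.ndarray
    polylines: list[list[np.ndarray]]
    closed: list[list[bool]]


@dataclass(frozen=True)
class ExtremePoint:
    """Strict local minimum of the thickness field on the mesh."""

    vertex: int
    position: np.ndarray
    thickness: float
    is_global_min: bool


@dataclass(frozen=True)
class CoefficientRecord:
    """One aneurysm's coefficients; a row of the cohort table."""

    id: int
    location: str
    I_S: float
    volume: float
    I_BA: float
    I_delta: float
    group: str

    def __post_init__(self) -> None:
        if min(self.I_S, self.I_BA, self.I_delta, self.volume) <= 0:
            raise ValueError(f"record {self.id}: coefficients must be positive")
        if self.group not in ("A", "B", "C"):
            raise ValueError(f"record {self.id}: group must be A, B or C")
        rel = abs(self.I_delta * self.I_S - self.I_BA) / self.I_BA
        if rel > 1e-5:
            raise ValueError(
                f"record {self.id}: I_delta * I_S != I_BA (relative error {rel:.2g})"
            )


# --------------------------------------------------------------------------
# coefficients
# --------------------------------------------------------------------------

def compute_IS(s_a: float, s_b: float) -> float:
    """Area-increase multiple S_A / S_B."""
    if s_a <= 0 or s_b <= 0:
        raise ValueError("areas must be positive")
    return s_a / s_b


def compute_Idelta(i_ba: float, i_s: float) -> float:
    """Inhomogeneity coefficient I_delta = I_BA / I_S."""
    if i_ba <= 0 or i_s <= 0:
        raise ValueError("coefficients must be positive")
    return i_ba / i_s


def aneurysm_volume(model_a: TriangleMesh, model_b: TriangleMesh) -> float:
    """Sac volume: enclosed volume of the capped mold minus the capped parent."""
    vol = enclosed_volume(model_a) - enclosed_volume(model_b)
    if vol < 0:
        raise MeshError(
            f"negative sac volume ({vol:.6g} mm^3): model B encloses more "
            "than model A; check the pairing"
        )
    return vol


# --------------------------------------------------------------------------
# isolines
# --------------------------------------------------------------------------

def isoline_levels(values: np.ndarray, n_levels: int) -> np.ndarray:
    """``n_levels`` evenly spaced interior levels between min and max."""
    vmin, vmax = float(values.min()), float(values.max())
    return np.linspace(vmin, vmax, n_levels + 2)[1:-1]


def extract_isolines(f, mesh: TriangleMesh, n_levels: int = 200) -> IsolineSet:
    """Marching-triangles level curves of a per-vertex field.

    Each triangle crossed by a level contributes one segment with endpoints
    linearly interpolated on the crossed edges; segments are chained into
    polylines (closed where the chain returns to its start).  A constant
    field yields an empty set with a warning.
    """
    values = _field_values(f, mesh)
    if values.max() == values.min():
        warnings.warn("constant field: no isolines extracted")
        return IsolineSet(np.zeros(0), [], [])
    # nudge exact level hits so crossings are strict sign changes
    scale = (values.max() - values.min()) * 1e-12
    levels = isoline_levels(values, n_levels)
    f0 = values[mesh.faces]
    polylines: list[list[np.ndarray]] = []
    closed: list[list[bool]] = []
    for level in levels:
        fv = np.where(f0 == level, level + scale, f0)
        lower = fv < level
        n_below = lower.sum(axis=1)
        crossing = np.flatnonzero((n_below == 1) | (n_below == 2))
        seg_keys = []
        seg_pts = []
        for fi in crossing:
            tri = mesh.faces[fi]
            vals = fv[fi]
            pts = []
            keys = []
            for e0, e1 in ((0, 1), (1, 2), (2, 0)):
                va, vb = vals[e0], vals[e1]
                if (va < level) != (vb < level):
                    t = (level - va) / (vb - va)
                    p = (1 - t) * mesh.vertices[tri[e0]] + t * mesh.vertices[tri[e1]]
                    a, b = int(tri[e0]), int(tri[e1])
                    keys.append((min(a, b), max(a, b)))
                    pts.append(p)
            if len(pts) == 2:
                seg_keys.append((keys[0], keys[1]))
                seg_pts.append((pts[0], pts[1]))
        polylines.append([])
        closed.append([])
        if not seg_keys:
            continue
        # chain segments that share an edge key
        point_of: dict[tuple, np.ndarray] = {}
        graph: dict[tuple, list[int]] = {}
        for si, (ka, kb) in enumerate(seg_keys):
            point_of[ka] = seg_pts[si][0]
            point_of[kb] = seg_pts[si][1]
            graph.setdefault(ka, []).append(si)
            graph.setdefault(kb, []).append(si)
        used = [False] * len(seg_keys)

        def walk(start_key):
            chain = [start_key]
            key = start_key
            while True:
                nxt = [s for s in graph[key] if not used[s]]
                if not nxt:
                    return chain
                si = nxt[0]
                used[si] = True
                ka, kb = seg_keys[si]
                key = kb if ka == key else ka
                if key == chain[0]:
                    chain.append(key)
                    return chain
                chain.append(key)

        # open chains first (keys of degree 1), then remaining cycles
        for key in list(graph):
            if len(graph[key]) == 1 and not all(used[s] for s in graph[key]):
                chain = walk(key)
                polylines[-1].append(np.array([point_of[k] for k in chain]))
                closed[-1].append(chain[0] == chain[-1])
        for si in range(len(seg_keys)):
            if not used[si]:
                used[si] = True
                ka, kb = seg_keys[si]
                chain = [ka] + walk(kb)
                polylines[-1].append(np.array([point_of[k] for k in chain]))
                closed[-1].append(chain[0] == chain[-1])
    return IsolineSet(levels, polylines, closed)


# --------------------------------------------------------------------------
# extreme points
# --------------------------------------------------------------------------

def find_extreme_points(f, mesh: TriangleMesh) -> list[ExtremePoint]:
    """Strict local minima of a per-vertex field (1-ring neighborhoods).

    Plateau vertices are suppressed (a flat region is not a nest of rings).
    The global minimum vertex is always reported and flagged, so every
    non-empty field yields exactly one ``is_global_min`` point.
    """
    values = _field_values(f, mesh)
    if values.max() == values.min():
        return []  # a flat field has no nested isoline rings
    adj = mesh.adjacency()
    global_min = int(values.argmin())
    points = []
    for v, nbrs in enumerate(adj):
        if not nbrs:
            continue
        nb = np.fromiter(nbrs, dtype=np.int64)
        if (values[v] < values[nb]).all():
            points.append(ExtremePoint(
                vertex=v,
                position=mesh.vertices[v].copy(),
                thickness=float(values[v]),
                is_global_min=(v == global_min),
            ))
    if not any(p.is_global_min for p in points):
        points.append(ExtremePoint(
            vertex=global_min,
            position=mesh.vertices[global_min].copy(),
            thickness=float(values[global_min]),
            is_global_min=True,
        ))
    return points


# --------------------------------------------------------------------------
# isoline regularity along the steepest-ascent path
# --------------------------------------------------------------------------

def _face_gradients(mesh: TriangleMesh, values: np.ndarray) -> np.ndarray:
    """Per-face gradient of the piecewise-linear field (in-plane 3-vector)."""
    v = mesh.vertices
    f = mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(n, axis=1)
    n_hat = n / area2[:, None]
    grad = (values[f[:, 0], None] * np.cross(n_hat, p2 - p1)
            + values[f[:, 1], None] * np.cross(n_hat, p0 - p2)
            + values[f[:, 2], None] * np.cross(n_hat, p1 - p0)) / area2[:, None]
    return grad


def _trace_ascent(mesh: TriangleMesh, values: np.ndarray, start_vertex: int,
                  max_steps: int = 20000):
    """Steepest-ascent streamline of a PL field from a vertex.

    Returns (points, field values) sampled along the polyline.  Within each
    face the gradient is constant, so the path is straight until it exits
    through an edge; tracing stops at the boundary or at a local maximum.
    """
    grads = _face_gradients(mesh, values)
    # face adjacency across undirected edges
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for e in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(e), max(e)), []).append(fi)
    vert_faces: dict[int, list[int]] = {}
    for fi, tri in enumerate(mesh.faces):
        for vtx in tri:
            vert_faces.setdefault(int(vtx), []).append(fi)

    def barycentric(fi, p):
        tri = mesh.faces[fi]
        a, b, c = mesh.vertices[tri]
        m = np.column_stack([b - a, c - a])
        sol, *_ = np.linalg.lstsq(m, p - a, rcond=None)
        u, w = sol
        return np.array([1 - u - w, u, w])

    def best_face_from_vertex(v):
        """Incident face with the largest gradient pointing into the face."""
        best, best_norm = None, 1e-14
        pv = mesh.vertices[v]
        for fi in vert_faces.get(v, []):
            g = grads[fi]
            gn = np.linalg.norm(g)
            if gn <= best_norm:
                continue
            probe = pv + g / gn * 1e-6 * np.sqrt(mesh.face_areas()[fi])
            if barycentric(fi, probe).min() > -1e-9:
                best, best_norm = fi, gn
        return best

    p = mesh.vertices[start_vertex].copy()
    fi = best_face_from_vertex(start_vertex)
    if fi is None:
        return np.array([p]), np.array([values[start_vertex]])

    pts = [p.copy()]
    fvals = [float(values[start_vertex])]
    visited_vertices = {start_vertex}
    for _ in range(max_steps):
        g = grads[fi]
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            break
        d = g / gn
        tri = mesh.faces[fi]
        a, b, c = mesh.vertices[tri]
        m = np.column_stack([b - a, c - a])
        lam = barycentric(fi, p)
        # barycentric directional derivatives of a step along d
        sol, *_ = np.linalg.lstsq(m, d, rcond=None)
        dl = np.array([-sol[0] - sol[1], sol[0], sol[1]])
        s_exit = np.inf
        exit_i = -1
        for i in range(3):
            if dl[i] < -1e-14:
                s = -lam[i] / dl[i]
                if s < s_exit:
                    s_exit = s
                    exit_i = i
        scale = float(np.sqrt(mesh.face_areas()[fi]))
        if exit_i >= 0 and np.isfinite(s_exit) and s_exit > 1e-9 * scale:
            lam_new = np.clip(lam + s_exit * dl, 0.0, None)
            lam_new /= lam_new.sum()
            p = lam_new[0] * a + lam_new[1] * b + lam_new[2] * c
            pts.append(p.copy())
            fvals.append(float(lam_new @ values[tri]))
            if lam_new.max() > 1 - 1e-7:
                # landed (numerically) on a vertex: hop through it
                v = int(tri[int(lam_new.argmax())])
                if v in visited_vertices:
                    break
                visited_vertices.add(v)
                p = mesh.vertices[v].copy()
                nxt = best_face_from_vertex(v)
                if nxt is None:
                    break
                fi = nxt
                continue
            ea, eb = int(tri[(exit_i + 1) % 3]), int(tri[(exit_i + 2) % 3])
            nbrs = [g2 for g2 in edge_faces[(min(ea, eb), max(ea, eb))] if g2 != fi]
            if not nbrs:
                break  # mesh boundary
            fi = nbrs[0]
        else:
            # stuck on a vertex or edge: hop via the nearest vertex
            v = int(tri[int(lam.argmax())])
            if v in visited_vertices:
                break
            visited_vertices.add(v)
            p = mesh.vertices[v].copy()
            if not np.allclose(p, pts[-1]):
                pts.append(p.copy())
                fvals.append(float(values[v]))
            nxt = best_face_from_vertex(v)
            if nxt is None or nxt == fi:
                break
            fi = nxt
    return np.asarray(pts), np.asarray(fvals)


def isoline_regularity(f, mesh: TriangleMesh, point: ExtremePoint,
                       k_levels: int, n_levels: int = 200) -> float:
    """Coefficient of variation of inter-isoline spacing near a minimum.

    Walks the steepest-ascent polyline from the extreme point, records the
    arc length at which each of the ``k_levels`` nearest isoline levels is
    crossed, and returns std/mean of the consecutive spacings.  Evenly
    spaced rings (a locally linear field) give CV ~ 0; rings that spread
    out toward the minimum (a flattening basin) give CV > 0.
    """
    if k_levels < 3:
        raise ValueError("k_levels must be at least 3")
    values = _field_values(f, mesh)
    boundary = {int(v) for edge in mesh.boundary_edges() for v in edge}
    if point.vertex in boundary:
        raise ValueError("extreme point lies on the mesh boundary")
    levels = isoline_levels(values, n_levels)
    above = levels[levels > values[point.vertex]]
    if len(above) < k_levels:
        raise ValueError(
            f"only {len(above)} isoline levels above the extreme point; "
            f"need {k_levels}"
        )
    targets = above[:k_levels]
    pts, fvals = _trace_ascent(mesh, values, point.vertex)
    if len(pts) < 2:
        raise ValueError("could not trace an ascent path from the extreme point")
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    crossings = []
    for level in targets:
        idx = np.flatnonzero((fvals[:-1] < level) & (fvals[1:] >= level))
        if not len(idx):
            break
        i = idx[0]
        t = (level - fvals[i]) / (fvals[i + 1] - fvals[i])
        crossings.append(arc[i] + t * seg_len[i])
    if len(crossings) < 3:
        raise ValueError(
            f"ascent path crossed only {len(crossings)} of {k_levels} levels"
        )
    spacings = np.diff(crossings)
    return float(spacings.std() / spacings.mean())
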