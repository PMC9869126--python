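"""Quasi-static membrane inflation into a rigid mold.

Surrogate for the transient blow-molding shell solve: the neck patch is
inflated outward until it rests on the inner surface of the sac ("mold").
The derived quantities — per-vertex area stretch and, by incompressibility,
thickness delta_i = delta_B / lambda_i — depend only on the geometric
mapping from the rest patch onto the mold, not on rheology, so a
deterministic geometric flow suffices:

repeat:
    advance each free vertex along its area-weighted normal by
    min(step, distance to the mold);
    blend in tangential umbrella smoothing;
    freeze vertices that are within the contact tolerance of the mold.

Advancing by at most the current closest-point distance can never carry a
vertex through the mold surface, so no ray casting is required.  The solver
contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .mesh import MeshError, TriangleMesh, surface_area

__all__ = ["InflationConfig", "ThicknessResult", "inflate_to_mold", "thickness_summary"]


@dataclass(frozen=True)
class InflationConfig:
    """Solver parameters.

    delta_b : initial wall thickness (dimensionless; all outputs are ratios)
    step : max normal advance per iteration, fraction of the bbox diagonal
    contact_tol : contact tolerance, fraction of the bbox diagonal
    smooth_weight : tangential umbrella blending weight per iteration
    max_iterations : iteration cap
    """

    delta_b: float = 1.0
    step: float = 0.005
    contact_tol: float = 1e-3
    smooth_weight: float = 0.5
    max_iterations: int = 2000

    def __post_init__(self) -> None:
        if min(self.delta_b, self.step, self.contact_tol, self.smooth_weight) <= 0:
            raise ValueError("all InflationConfig parameters must be positive")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")
        if self.contact_tol >= self.step:
            raise ValueError("contact_tol must be smaller than step")


@dataclass
class ThicknessResult:
    """Inflated patch with stretch and thickness fields.

    stretch[i] is the per-vertex area ratio (barycentric area after / before),
    thickness[i] = delta_b / stretch[i].  ``delta_b_prime`` is the thickness
    at the global minimum (the predicted translucent/rupture site);
    ``delta_bar`` is the conserved mean thickness delta_b * S_B / S_A.
    """

    inflated_mesh: TriangleMesh
    stretch: np.ndarray
    thickness: np.ndarray
    delta_b: float
    S_B: float
    S_A: float
    delta_b_prime: float
    delta_bar: float
    converged: bool
    iterations: int
    diagnostics: dict = field(default_factory=dict)


class _MoldDistance:
    """Closest-point distance to a triangle soup.

    Candidate triangles come from a KD-tree over triangle centroids: every
    triangle whose centroid lies within (distance to nearest centroid +
    2 * largest circumradius) of the query can contain the closest point, so
    the query is exact.
    """

    def __init__(self, mold: TriangleMesh):
        v = mold.vertices
        f = mold.faces
        self.a = v[f[:, 0]]
        self.ab = v[f[:, 1]] - self.a
        self.ac = v[f[:, 2]] - self.a
        centroids = (v[f[:, 0]] + v[f[:, 1]] + v[f[:, 2]]) / 3.0
        self.tree = cKDTree(centroids)
        corner_d = np.stack([
            np.linalg.norm(v[f[:, k]] - centroids, axis=1) for k in range(3)
        ])
        self.r_max = float(corner_d.max())

    def __call__(self, points: np.ndarray, cutoff: float = np.inf) -> np.ndarray:
        """Distances to the mold; beyond ``cutoff`` a lower bound suffices.

        ``d1 - 2 r_max`` underestimates the true distance, so points whose
        bound already exceeds the cutoff skip the exact narrow phase — the
        solver only needs exact values within one advance step.
        """
        d1, _ = self.tree.query(points)
        bound = d1 - 2.0 * self.r_max
        out = np.maximum(bound, 0.0)
        near = bound < cutoff if np.isfinite(cutoff) else np.ones(len(points), bool)
        if not near.any():
            return out
        idx_near = np.flatnonzero(near)
        radii = d1[idx_near] + 2.0 * self.r_max + 1e-12
        groups = self.tree.query_ball_point(points[idx_near], radii)
        lens = np.fromiter((len(g) for g in groups), dtype=np.int64, count=len(groups))
        pt_idx = np.repeat(idx_near, lens)
        tri_idx = np.concatenate([np.asarray(g, dtype=np.int64) for g in groups])
        d = _point_triangle_distance(points[pt_idx], self.a[tri_idx],
                                     self.ab[tri_idx], self.ac[tri_idx])
        out[idx_near] = np.inf
        np.minimum.at(out, pt_idx, d)
        return out


def _point_triangle_distance(p, a, ab, ac):
    """Vectorized closest distance point -> triangle (Ericson's clamp)."""
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = ap - ab
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = ap - ac
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom_uv = np.einsum("ij,ij->i", ab, ab) * np.einsum("ij,ij->i", ac, ac) \
        - np.einsum("ij,ij->i", ab, ac) ** 2

    u = np.zeros(len(p))
    v = np.zeros(len(p))

    # interior region
    denom = np.maximum(va + vb + vc, 1e-300)
    u_int = vb / denom
    v_int = vc / denom
    u[:] = u_int
    v[:] = v_int

    # vertex a
    m = (d1 <= 0) & (d2 <= 0)
    u[m], v[m] = 0.0, 0.0
    # vertex b
    m = (d3 >= 0) & (d4 <= d3)
    u[m], v[m] = 1.0, 0.0
    # vertex c
    m = (d6 >= 0) & (d5 <= d6)
    u[m], v[m] = 0.0, 1.0
    # edge ab
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ab = d1 / (d1 - d3)
    u[m], v[m] = t_ab[m], 0.0
    # edge ac
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_ac = d2 / (d2 - d6)
    u[m], v[m] = 0.0, t_ac[m]
    # edge bc
    m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    u[m], v[m] = 1.0 - t_bc[m], t_bc[m]

    closest = a + u[:, None] * ab + v[:, None] * ac
    return np.linalg.norm(p - closest, axis=1)


def _umbrella_matrix(mesh: TriangleMesh) -> csr_matrix:
    """Row-normalized vertex adjacency (neighbor averaging operator)."""
    adj = mesh.adjacency()
    rows, cols, vals = [], [], []
    for i, nbrs in enumerate(adj):
        if not nbrs:
            continue
        w = 1.0 / len(nbrs)
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            vals.append(w)
    n = len(mesh.vertices)
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    cross = np.cross(vertices[faces[:, 1]] - vertices[faces[:, 0]],
                     vertices[faces[:, 2]] - vertices[faces[:, 0]])
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], cross)
    norm = np.linalg.norm(vn, axis=1)
    mask = norm > 0
    vn[mask] /= norm[mask, None]
    return vn


def inflate_to_mold(patch: TriangleMesh, mold: TriangleMesh,
                    config: InflationConfig | None = None) -> ThicknessResult:
    """Inflate ``patch`` until it contacts ``mold``; derive stretch/thickness.

    Patch vertices already within the contact tolerance (for instance rim
    vertices lying on the mold's neck rim) are frozen from the start and act
    as the fixed boundary.  Returns a result with ``converged=False`` plus
    diagnostics if the iteration cap is reached before full contact.
    """
    config = config or InflationConfig()
    lo = np.minimum(patch.vertices.min(0), mold.vertices.min(0))
    hi = np.maximum(patch.vertices.max(0), mold.vertices.max(0))
    diag = float(np.linalg.norm(hi - lo))
    if diag <= 0:
        raise MeshError("degenerate patch/mold bounding box")
    step = config.step * diag
    eps = config.contact_tol * diag

    dist = _MoldDistance(mold)
    faces = patch.faces
    x = patch.vertices.copy()
    avg = _umbrella_matrix(patch)
    # umbrella smoothing is only meaningful for interior vertices; open
    # boundary rings advance along their normals untouched
    interior = np.ones(len(x), dtype=bool)
    interior[np.unique(patch.boundary_edges())] = False

    frozen = dist(x, cutoff=step) < eps
    iterations = 0
    converged = bool(frozen.all())
    if not converged:
        for iterations in range(1, config.max_iterations + 1):
            free = ~frozen
            normals = _vertex_normals(x, faces)
            d = dist(x[free], cutoff=step)
            advance = np.minimum(step, d)
            x[free] += normals[free] * advance[:, None]

            lap = avg @ x - x
            normal_part = np.einsum("ij,ij->i", lap, normals)[:, None] * normals
            tangential = lap - normal_part
            smooth = free & interior
            x[smooth] += config.smooth_weight * tangential[smooth]

            frozen[free] = dist(x[free], cutoff=step) < eps
            if frozen.all():
                converged = True
                break

    inflated = TriangleMesh(x, faces.copy())
    area_before = patch.vertex_areas()
    area_after = inflated.vertex_areas()
    stretch = area_after / area_before
    thickness = config.delta_b / stretch

    s_b = surface_area(patch)
    s_a = surface_area(inflated)
    delta_b_prime = float(thickness.min())
    delta_bar = config.delta_b * s_b / s_a
    diagnostics = {}
    if not converged:
        free_d = dist(x[~frozen])
        diagnostics = {
            "n_free": int((~frozen).sum()),
            "max_residual_distance": float(free_d.max()) if len(free_d) else 0.0,
        }
    return ThicknessResult(
        inflated_mesh=inflated,
        stretch=stretch,
        thickness=thickness,
        delta_b=config.delta_b,
        S_B=s_b,
        S_A=s_a,
        delta_b_prime=delta_b_prime,
        delta_bar=delta_bar,
        converged=converged,
        iterations=iterations,
        diagnostics=diagnostics,
    )


def thickness_summary(result: ThicknessResult) -> tuple[float, float, float]:
    """(delta_b_prime, delta_bar, I_BA) for a converged inflation.

    I_BA = delta_b / delta_b_prime is the thinning magnification at the
    minimum extreme point; it is >= I_S because the maximum stretch is at
    least the mean stretch.
    """
    if not result.converged:
        raise MeshError(
            "inflation did not converge "
            f"({result.diagnostics.get('n_free', '?')} free vertices remain); "
            "thickness summary requires a converged result"
        )
    i_ba = result.delta_b / result.delta_b_prime
    return result.delta_b_prime, result.delta_bar, i_ba
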