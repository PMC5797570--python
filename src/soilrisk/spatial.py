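"""Spatial building blocks: mesh, Matérn/SPDE precision, projector, ICAR.

The latent exposure surface is a Matérn Gaussian field (smoothness fixed at
ν = 1) represented as a Gauss–Markov random field on a triangulated mesh via
the finite-element SPDE construction: the precision matrix

    Q = τ² (κ⁴ C + 2 κ² G + G C⁻¹ G),      κ = √8 / ρ,

with C the lumped mass matrix and G the stiffness matrix, is sparse, and
τ is chosen so the stationary marginal standard deviation equals σ
(σ² = 1 / (4π κ² τ²) in two dimensions).  The mesh is a hexagonal lattice
covering the data's bounding box, refined so no interior edge exceeds
``max_edge``, surrounded by a coarser extension ring that pushes boundary
effects away from the study region; the vertex set is triangulated with a
Delaunay triangulation.

Town-level spatial heterogeneity uses the Besag intrinsic CAR structure
matrix (degree minus adjacency) over the town adjacency graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, cKDTree
from scipy.special import k1

from .exceptions import MeshError, ValidationError

__all__ = [
    "Mesh",
    "build_mesh",
    "SpdeField",
    "spde_precision",
    "Projector",
    "make_projector",
    "AdjacencyGraph",
    "icar_precision",
    "sample_gmrf",
    "matern_correlation",
    "read_mesh",
    "write_mesh",
]


# ---------------------------------------------------------------------------
# Matérn correlation (ν = 1)

def matern_correlation(d, range_: float):
    """Matérn ν=1 correlation r(d) = (κd)·K₁(κd), κ = √8/ρ; r(0) = 1.

    With this practical-range convention the correlation at distance ρ is
    ≈ 0.14.  Accepts scalars or arrays.
    """
    if range_ <= 0:
        raise ValidationError(f"range must be > 0, got {range_}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be >= 0")
    kd = np.sqrt(8.0) / range_ * d
    with np.errstate(invalid="ignore", over="ignore"):
        r = np.where(kd > 0, kd * k1(np.maximum(kd, 1e-300)), 1.0)
    r = np.where(kd > 700, 0.0, r)  # K1 underflow far beyond the range
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# mesh

@dataclass
class Mesh:
    """Triangulated mesh: vertices (n_v, 2), triangle index triples,
    per-vertex extension flag (True = boundary-extension ring)."""

    vertices: np.ndarray
    triangles: np.ndarray
    is_extension: np.ndarray
    max_edge: float
    _centroid_tree: cKDTree = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.is_extension = np.asarray(self.is_extension, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise MeshError("vertices must be (n_v, 2)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be (n_t, 3)")
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            raise MeshError("mesh contains a degenerate (zero-area) triangle")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def edge_lengths(self):
        """Unique edges and their lengths, with an interior flag (both
        endpoints outside the extension ring)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        lengths = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                                 axis=1)
        interior = ~(self.is_extension[e[:, 0]] | self.is_extension[e[:, 1]])
        return e, lengths, interior

    # -- point location -----------------------------------------------------

    def _tree(self) -> cKDTree:
        if self._centroid_tree is None:
            centroids = self.vertices[self.triangles].mean(axis=1)
            self._centroid_tree = cKDTree(centroids)
        return self._centroid_tree

    def _barycentric(self, tri_idx: int, point: np.ndarray) -> np.ndarray:
        a, b, c = self.vertices[self.triangles[tri_idx]]
        m = np.column_stack([b - a, c - a])
        try:
            lam = np.linalg.solve(m, point - a)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate guard
            return np.array([-1.0, -1.0, -1.0])
        return np.array([1.0 - lam[0] - lam[1], lam[0], lam[1]])

    def locate(self, points: np.ndarray, tol: float = 1e-9):
        """Containing triangle and barycentric weights for each point.

        Points on shared edges resolve to the lowest-index containing
        triangle.  Returns (tri_indices, weights (n,3)); a point outside
        every triangle gets index -1.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(32, self.n_triangles)
        _, neigh = self._tree().query(points, k=k)
        neigh = np.atleast_2d(neigh)
        idx_out = np.full(len(points), -1, dtype=int)
        w_out = np.zeros((len(points), 3))
        for i, pt in enumerate(points):
            candidates = np.sort(neigh[i])
            best = -1
            for t in candidates:
                w = self._barycentric(int(t), pt)
                if np.all(w >= -tol):
                    best = int(t)
                    break
            if best < 0:  # exhaustive fallback for points far from centroids
                for t in range(self.n_triangles):
                    w = self._barycentric(t, pt)
                    if np.all(w >= -tol):
                        best = t
                        break
            if best >= 0:
                w = np.clip(self._barycentric(best, pt), 0.0, None)
                idx_out[i] = best
                w_out[i] = w / w.sum()
        return idx_out, w_out


def _hex_lattice(xmin, xmax, ymin, ymax, h):
    """Hexagonal point lattice spanning the box with spacing <= h; the four
    box corners are lattice points."""
    ny = max(2, int(np.ceil((ymax - ymin) / (h * np.sqrt(3) / 2))) + 1)
    dy = (ymax - ymin) / (ny - 1)
    nx = max(2, int(np.ceil((xmax - xmin) / h)) + 1)
    dx = (xmax - xmin) / (nx - 1)
    pts = []
    for i in range(ny):
        y = ymin + i * dy
        if i % 2 == 0:
            xs = xmin + dx * np.arange(nx)
        else:
            xs = np.concatenate(
                [[xmin], xmin + dx * (np.arange(nx - 1) + 0.5), [xmax]]
            )
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    return np.vstack(pts)


def build_mesh(points, max_edge: float, extension_factor: float = 3.0,
               extension_width: float | None = None,
               max_vertices: int = 20000) -> Mesh:
    """Triangulated mesh covering the bounding box of ``points``.

    A hexagonal lattice at spacing 0.95·``max_edge`` covers the box (so no
    interior edge exceeds ``max_edge``), surrounded by a coarser lattice ring
    of width ``extension_width`` (default: max(15% of the domain diameter,
    2 coarse edges)) at spacing ``max_edge × extension_factor`` to control
    boundary effects.  The union is Delaunay-triangulated.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise MeshError("non-finite input points")
    if len(points) < 3:
        raise MeshError("need at least 3 points to build a mesh")
    if max_edge <= 0:
        raise MeshError(f"max_edge must be > 0, got {max_edge}")
    if extension_factor < 1:
        raise MeshError("extension_factor must be >= 1")
    xmin, ymin = points.min(axis=0)
    xmax, ymax = points.max(axis=0)
    span = max(xmax - xmin, ymax - ymin)
    if span <= 0 or min(xmax - xmin, ymax - ymin) < 1e-9 * max(span, 1.0):
        raise MeshError("input points are collinear; cannot build a 2-D mesh")

    h = 0.95 * max_edge
    interior = _hex_lattice(xmin, xmax, ymin, ymax, h)

    h_ext = 0.95 * max_edge * extension_factor
    diam = float(np.hypot(xmax - xmin, ymax - ymin))
    if extension_width is None:
        extension_width = max(0.15 * diam, 2.0 * max_edge * extension_factor)
    w = float(extension_width)
    outer = _hex_lattice(xmin - w, xmax + w, ymin - w, ymax + w, h_ext)
    gap = 0.35 * h_ext
    keep = (
        (outer[:, 0] < xmin - gap) | (outer[:, 0] > xmax + gap)
        | (outer[:, 1] < ymin - gap) | (outer[:, 1] > ymax + gap)
    )
    outer = outer[keep]

    vertices = np.vstack([interior, outer])
    is_ext = np.zeros(len(vertices), dtype=bool)
    is_ext[len(interior):] = True
    # collapse near-duplicate vertices
    _, unique_idx = np.unique(np.round(vertices / (1e-9 * max(span, 1.0))),
                              axis=0, return_index=True)
    unique_idx = np.sort(unique_idx)
    vertices = vertices[unique_idx]
    is_ext = is_ext[unique_idx]
    if len(vertices) > max_vertices:
        raise MeshError(
            f"mesh would need {len(vertices)} vertices (cap {max_vertices}); "
            "increase max_edge"
        )
    tri = Delaunay(vertices)
    simplices = tri.simplices
    p = vertices[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    simplices = simplices[areas > 1e-12 * max(span, 1.0) ** 2]
    mesh = Mesh(vertices=vertices, triangles=simplices, is_extension=is_ext,
                max_edge=max_edge)
    idx, _ = mesh.locate(points)
    if np.any(idx < 0):  # pragma: no cover - coverage guard
        raise MeshError("an input point falls outside the constructed mesh")
    return mesh


def write_mesh(mesh: Mesh, vertices_path, triangles_path) -> None:
    pd.DataFrame({
        "id": np.arange(mesh.n_vertices),
        "x": mesh.vertices[:, 0],
        "y": mesh.vertices[:, 1],
        "is_extension": mesh.is_extension.astype(int),
    }).to_csv(vertices_path, index=False)
    pd.DataFrame(mesh.triangles, columns=["v1", "v2", "v3"]).to_csv(
        triangles_path, index=False
    )


def read_mesh(vertices_path, triangles_path, max_edge: float = np.inf) -> Mesh:
    v = pd.read_csv(vertices_path)
    t = pd.read_csv(triangles_path)
    return Mesh(
        vertices=v[["x", "y"]].to_numpy(float),
        triangles=t[["v1", "v2", "v3"]].to_numpy(int),
        is_extension=v["is_extension"].to_numpy(bool),
        max_edge=max_edge,
    )


# ---------------------------------------------------------------------------
# finite elements / SPDE

def _fem_matrices(mesh: Mesh):
    """Lumped mass matrix C (diagonal) and stiffness matrix G."""
    n = mesh.n_vertices
    tris = mesh.triangles
    p = mesh.vertices[tris]
    areas = mesh.triangle_areas()
    c_diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for t in range(len(tris)):
        i0, i1, i2 = tris[t]
        a = areas[t]
        # edge vectors opposite each vertex
        e = np.array([p[t, 2] - p[t, 1], p[t, 0] - p[t, 2], p[t, 1] - p[t, 0]])
        g_local = (e @ e.T) / (4.0 * a)
        idx = [i0, i1, i2]
        for ii in range(3):
            c_diag[idx[ii]] += a / 3.0
            for jj in range(3):
                rows.append(idx[ii])
                cols.append(idx[jj])
                vals.append(g_local[ii, jj])
    g = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    c = sp.diags(c_diag)
    return c, g


@dataclass
class SpdeField:
    """Sparse-precision Matérn (ν = 1) field on a mesh."""

    mesh: Mesh
    precision: sp.spmatrix
    range_: float
    sigma: float
    kappa: float
    tau: float

    def logdet(self) -> float:
        lu = sp.linalg.splu(self.precision.tocsc())
        return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


class SpdeBasis:
    """Pre-assembled FEM matrices for one mesh, so the precision can be
    re-formed cheaply for many (ρ, σ) values during optimisation."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.c, self.g = _fem_matrices(mesh)
        c_inv = sp.diags(1.0 / self.c.diagonal())
        self.gcg = (self.g @ c_inv @ self.g).tocsc()
        self.c = self.c.tocsc()
        self.g = self.g.tocsc()

    def precision(self, range_: float, sigma: float) -> sp.csc_matrix:
        if range_ <= 0 or sigma <= 0:
            raise ValidationError("range and sigma must be > 0")
        kappa = np.sqrt(8.0) / range_
        tau2 = 1.0 / (4.0 * np.pi * kappa**2 * sigma**2)
        q = tau2 * (kappa**4 * self.c + 2.0 * kappa**2 * self.g + self.gcg)
        return ((q + q.T) * 0.5).tocsc()  # exact symmetry despite roundoff


def spde_precision(mesh: Mesh, range_: float, sigma: float) -> SpdeField:
    """SPDE (ν=1) precision Q = τ²(κ⁴C + 2κ²G + GC⁻¹G) with κ = √8/ρ and τ
    set so the stationary marginal sd is σ."""
    basis = SpdeBasis(mesh)
    q = basis.precision(range_, sigma)
    kappa = np.sqrt(8.0) / range_
    tau = np.sqrt(1.0 / (4.0 * np.pi * kappa**2 * sigma**2))
    return SpdeField(mesh=mesh, precision=q, range_=range_, sigma=sigma,
                     kappa=kappa, tau=tau)


# ---------------------------------------------------------------------------
# projector

@dataclass
class Projector:
    """Sparse barycentric interpolation matrix A: field at mesh vertices →
    field at point locations (rows sum to 1, ≤ 3 non-zeros per row)."""

    matrix: sp.csr_matrix
    locations: np.ndarray

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    def __matmul__(self, other):
        return self.matrix @ other

    def project(self, field_values: np.ndarray) -> np.ndarray:
        return self.matrix @ field_values


def make_projector(mesh: Mesh, locations) -> Projector:
    """Barycentric projector for arbitrary locations inside the mesh."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if not np.all(np.isfinite(locations)):
        raise ValidationError("non-finite projector locations")
    idx, weights = mesh.locate(locations)
    outside = np.where(idx < 0)[0]
    if outside.size:
        pts = ", ".join(str(tuple(locations[i])) for i in outside[:5])
        raise MeshError(
            f"{outside.size} point(s) fall outside the mesh (including its "
            f"extension): {pts}"
        )
    rows = np.repeat(np.arange(len(locations)), 3)
    cols = mesh.triangles[idx].ravel()
    vals = weights.ravel()
    a = sp.csr_matrix((vals, (rows, cols)),
                      shape=(len(locations), mesh.n_vertices))
    return Projector(matrix=a, locations=locations)


# ---------------------------------------------------------------------------
# town adjacency / ICAR

class AdjacencyGraph:
    """Undirected simple graph over town ids (duplicate edges collapse)."""

    def __init__(self, town_ids, edges):
        self.ids = [str(t) for t in town_ids]
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate town ids in adjacency graph")
        known = set(self.ids)
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValidationError(f"self-loop on town {a!r}")
            for t in (a, b):
                if t not in known:
                    raise ValidationError(f"edge references unknown town id {t!r}")
            g.add_edge(a, b)
        self.graph = g
        comp_label = {}
        for label, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_label[node] = label
        self.component_labels = np.array([comp_label[t] for t in self.ids])

    @property
    def n_towns(self) -> int:
        return len(self.ids)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.ids else 0

    @property
    def edges(self):
        index = {t: i for i, t in enumerate(self.ids)}
        return sorted(self.graph.edges(), key=lambda e: (index[e[0]], index[e[1]]))

    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(t) for t in self.ids])

    def adjacency_matrix(self) -> sp.csr_matrix:
        return nx.to_scipy_sparse_array(self.graph, nodelist=self.ids,
                                        format="csr", dtype=float)


def icar_precision(graph: AdjacencyGraph) -> sp.csr_matrix:
    """Intrinsic CAR structure matrix Q_u = D − W (degree minus adjacency).

    Symmetric, rows sum to zero; rank is n minus the number of connected
    components, so sum-to-zero constraints per component are required for a
    proper density (``graph.component_labels`` carries the metadata).
    """
    if graph.n_towns == 0:
        raise ValidationError("empty adjacency graph")
    w = graph.adjacency_matrix()
    d = sp.diags(np.asarray(w.sum(axis=1)).ravel())
    return (d - w).tocsr()


# ---------------------------------------------------------------------------
# GMRF sampling

def sample_gmrf(precision, seed, constraint=None, n_draws: int = 1) -> np.ndarray:
    """Draw from a (possibly intrinsic) Gaussian with the given precision.

    ``constraint`` is an optional list of index arrays; the draw is
    conditioned on the sum over each index set being zero (the ICAR
    identifiability constraint).  Improper precisions are allowed only when
    their null space is spanned by the constraint's indicator vectors.
    Deterministic given ``seed``.
    """
    q = precision.toarray() if sp.issparse(precision) else np.asarray(precision,
                                                                      dtype=float)
    n = q.shape[0]
    if not np.allclose(q, q.T, atol=1e-8):
        raise ValidationError("precision must be symmetric")
    vals, vecs = np.linalg.eigh((q + q.T) / 2.0)
    tol = 1e-8 * max(1.0, float(vals.max()))
    if np.any(vals < -tol):
        raise ValidationError("precision is indefinite")
    null = vals < tol
    if np.any(null) and constraint is None:
        raise ValidationError(
            "improper precision: a sum-to-zero constraint is required"
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, n))
    pos = ~null
    draws = (vecs[:, pos] / np.sqrt(vals[pos])) @ z[:, pos].T  # (n, n_draws)
    draws = draws.T
    if constraint is not None:
        cov = (vecs[:, pos] / vals[pos]) @ vecs[:, pos].T
        a = np.zeros((len(constraint), n))
        for i, idx in enumerate(constraint):
            a[i, np.asarray(idx, dtype=int)] = 1.0
        resid = draws @ a.T                      # (n_draws, n_c)
        if np.max(np.abs(resid)) > 1e-10:
            m = a @ cov @ a.T
            correction = np.linalg.lstsq(m, resid.T, rcond=None)[0]
            draws = draws - (cov @ a.T @ correction).T
        # exact zero-sum per constrained block
        for idx in constraint:
            idx = np.asarray(idx, dtype=int)
            draws[:, idx] -= draws[:, idx].mean(axis=1, keepdims=True)
    return draws[0] if n_draws == 1 else draws
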