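"""Uniform-mesh P1 finite-element assembly for the membrane model.

The conductivity equation -div(sigma grad u) = 0 is discretised with
continuous piecewise-linear elements on a structured triangulation of a
square: each grid square is split along its lower-left to upper-right
diagonal, giving 2*N^2 congruent right triangles and the classical
5-point stencil for the Laplacian.

The conductivity is split as sigma(x) = sigma0 - sigma_tilde(x), where
sigma_tilde = (sigma0 - sigmaA) * chi_A is supported on the thin
membrane region A only.  Correspondingly two matrices are assembled:

* ``K``       -- the plain stiffness matrix of grad(phi_i).grad(phi_j),
* ``K_tilde`` -- the membrane correction, (sigma0-sigmaA) chi_A times
  the same gradient products.

P1 gradients are constant per triangle, so K_tilde only needs the area
of the intersection of each triangle with A.  That area is estimated by
composite Gaussian quadrature: every membrane-crossing triangle is
subdivided into 4**level congruent subtriangles carrying a 3-point
Gauss rule each, and the indicator chi_A is integrated on the points.
The default level makes the subtriangle diameter at most a quarter of
the membrane thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .geometry import DEFAULT_DOMAIN, MembraneGeometry

__all__ = [
    "BoundaryCondition",
    "UniformMesh",
    "FemSystem",
    "build_uniform_mesh",
    "assemble_laplace",
    "assemble_membrane_matrix",
    "assemble_load",
    "build_system",
    "gamma_of",
    "epsilon_of",
    "membrane_area_fractions",
    "default_quad_level",
]

_EDGES = ("left", "right", "bottom", "top")

ScalarFunc = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _as_func(v) -> ScalarFunc:
    if callable(v):
        return v
    c = float(v)
    return lambda x, y: np.full_like(np.asarray(x, dtype=float), c)


@dataclass(frozen=True)
class BoundaryCondition:
    """Assignment of each box edge to a Dirichlet or Neumann condition.

    ``dirichlet`` and ``neumann`` map edge names ('left', 'right',
    'bottom', 'top') to boundary data: constants or callables f(x, y).
    Every edge must appear exactly once, and at least one edge must be
    Dirichlet so the discrete system is nonsingular.
    """

    dirichlet: dict
    neumann: dict

    def __post_init__(self) -> None:
        assigned = set(self.dirichlet) | set(self.neumann)
        if set(self.dirichlet) & set(self.neumann):
            raise ValueError("an edge cannot be both Dirichlet and Neumann")
        if assigned != set(_EDGES):
            raise ValueError(f"edges {sorted(set(_EDGES) - assigned)} unassigned")
        if not self.dirichlet:
            raise ValueError("at least one Dirichlet edge is required")

    @staticmethod
    def horizontal_injection() -> "BoundaryCondition":
        """Current driven in +x by electrodes spanning the left/right edges.

        Large electrodes are equipotential surfaces, so the edges they
        cover carry Dirichlet data (unit potential drop) while the
        remaining edges are insulated (zero Neumann flux).
        """
        return BoundaryCondition(
            dirichlet={"left": 1.0, "right": 0.0},
            neumann={"top": 0.0, "bottom": 0.0},
        )

    @staticmethod
    def vertical_injection() -> "BoundaryCondition":
        """The 90-degree rotation: electrodes on bottom/top, sides insulated."""
        return BoundaryCondition(
            dirichlet={"bottom": 1.0, "top": 0.0},
            neumann={"left": 0.0, "right": 0.0},
        )

    @staticmethod
    def horizontal_flux_injection() -> "BoundaryCondition":
        """Alternative drive: unit Neumann influx on the left, grounded right."""
        return BoundaryCondition(
            dirichlet={"right": 0.0},
            neumann={"left": 1.0, "top": 0.0, "bottom": 0.0},
        )

    @staticmethod
    def vertical_flux_injection() -> "BoundaryCondition":
        """Unit Neumann influx on the bottom edge, grounded top."""
        return BoundaryCondition(
            dirichlet={"top": 0.0},
            neumann={"bottom": 1.0, "left": 0.0, "right": 0.0},
        )


@dataclass(frozen=True)
class UniformMesh:
    """Structured triangulation of a square with N subdivisions per side.

    Nodes are ordered row-major: index = j*(N+1) + i with i the x-index
    and j the y-index.  ``free_nodes`` are interior plus Neumann-edge
    nodes (the unknowns); ``dirichlet_nodes`` carry prescribed values.
    """

    N: int
    domain: tuple[float, float, float, float]
    nodes: np.ndarray  # ((N+1)^2, 2)
    triangles: np.ndarray  # (2 N^2, 3) int
    free_nodes: np.ndarray  # int indices
    dirichlet_nodes: np.ndarray  # int indices

    @property
    def h(self) -> float:
        xmin, xmax, _, _ = self.domain
        return (xmax - xmin) / self.N

    @property
    def n_nodes(self) -> int:
        return (self.N + 1) ** 2

    def edge_nodes(self, edge: str) -> np.ndarray:
        """Node indices on a named boundary edge (corners included)."""
        N = self.N
        i = np.arange(N + 1)
        if edge == "left":
            return i * (N + 1)
        if edge == "right":
            return i * (N + 1) + N
        if edge == "bottom":
            return i
        if edge == "top":
            return N * (N + 1) + i
        raise ValueError(f"unknown edge {edge!r}")


def build_uniform_mesh(
    N: int,
    domain: tuple[float, float, float, float] = DEFAULT_DOMAIN,
    bc: BoundaryCondition | None = None,
) -> UniformMesh:
    """Build the structured right-triangle mesh and classify its nodes.

    Each grid square is split along the lower-left to upper-right
    diagonal.  Dirichlet status wins at corners shared with a Neumann
    edge.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if bc is None:
        bc = BoundaryCondition.horizontal_injection()
    xmin, xmax, ymin, ymax = domain
    x = np.linspace(xmin, xmax, N + 1)
    y = np.linspace(ymin, ymax, N + 1)
    X, Y = np.meshgrid(x, y)  # row-major: row j is y_j
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    i, j = np.meshgrid(np.arange(N), np.arange(N))
    v00 = (j * (N + 1) + i).ravel()
    v10 = v00 + 1
    v01 = v00 + (N + 1)
    v11 = v01 + 1
    # lower-right triangle (v00, v10, v11) and upper-left (v00, v11, v01),
    # both positively oriented
    tris = np.vstack(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )

    dir_mask = np.zeros(nodes.shape[0], dtype=bool)
    for edge in bc.dirichlet:
        dir_mask[_edge_nodes_static(N, edge)] = True
    free = np.flatnonzero(~dir_mask)
    diri = np.flatnonzero(dir_mask)
    return UniformMesh(
        N=N,
        domain=domain,
        nodes=nodes,
        triangles=tris,
        free_nodes=free,
        dirichlet_nodes=diri,
    )


def _edge_nodes_static(N: int, edge: str) -> np.ndarray:
    i = np.arange(N + 1)
    return {
        "left": i * (N + 1),
        "right": i * (N + 1) + N,
        "bottom": i,
        "top": N * (N + 1) + i,
    }[edge]


def _triangle_gradients(mesh: UniformMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triangle P1 gradient coefficients and areas.

    Returns (bx, by, area) where bx[t, k], by[t, k] are the constant
    gradient components of the hat function at local vertex k.
    """
    p = mesh.nodes[mesh.triangles]  # (T, 3, 2)
    x, y = p[:, :, 0], p[:, :, 1]
    # signed doubled area
    d = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
        y[:, 1] - y[:, 0]
    )
    area = 0.5 * d
    bx = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    ) / d[:, None]
    by = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    ) / d[:, None]
    return bx, by, area


def _assemble_gradgrad(
    mesh: UniformMesh, tri_weights: np.ndarray | None = None
) -> sp.csr_matrix:
    """Assemble sum_tau w_tau * area_tau * grad(phi_i).grad(phi_j) on ALL nodes."""
    bx, by, area = _triangle_gradients(mesh)
    w = area if tri_weights is None else area * tri_weights
    # local 3x3 blocks, vectorised over triangles
    loc = (bx[:, :, None] * bx[:, None, :] + by[:, :, None] * by[:, None, :]) * w[
        :, None, None
    ]
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    M = sp.coo_matrix(
        (loc.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    M.sum_duplicates()
    return M


def assemble_laplace(mesh: UniformMesh, *, full: bool = False) -> sp.csr_matrix:
    """Stiffness matrix K of grad(phi_i).grad(phi_j).

    By default K is restricted to the free nodes (the system actually
    solved); ``full=True`` returns the matrix over all nodes, used for
    the Dirichlet lift in the load vector.
    """
    K = _assemble_gradgrad(mesh)
    if full:
        return K
    f = mesh.free_nodes
    return _restrict(K, f, f)


def default_quad_level(h: float, delta: float) -> int:
    """Subdivision level making subtriangle diameter <= delta / 4.

    The crossing triangle has diameter h*sqrt(2); each subdivision
    halves it.
    """
    return max(1, math.ceil(math.log2(4.0 * h * math.sqrt(2.0) / delta)))


_REF_QUAD_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _restrict(M: sp.spmatrix, rows: np.ndarray, cols: np.ndarray) -> sp.csr_matrix:
    """Submatrix M[rows][:, cols] via projection matrices (fast at scale)."""
    Pr = sp.csr_matrix(
        (np.ones(rows.size), (np.arange(rows.size), rows)),
        shape=(rows.size, M.shape[0]),
    )
    Pc = sp.csr_matrix(
        (np.ones(cols.size), (np.arange(cols.size), cols)),
        shape=(cols.size, M.shape[1]),
    )
    return (Pr @ M @ Pc.T).tocsr()


def _ref_quad_points(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite 3-point Gauss rule on the reference triangle.

    The reference triangle {x>=0, y>=0, x+y<=1} is split into 4**level
    congruent subtriangles; each carries the degree-2 interior rule with
    points (1/6,1/6), (2/3,1/6), (1/6,2/3) and equal weights.  Returns
    (points (M,2), weights (M,)) with weights summing to 1.
    """
    if level in _REF_QUAD_CACHE:
        return _REF_QUAD_CACHE[level]
    m = 2**level
    g = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
    pts = []
    for i in range(m):
        for j in range(m - i):
            o = np.array([i, j]) / m
            # upward subtriangle with corner o, legs 1/m
            pts.append(o + g / m)
            if j < m - 1 - i:
                # downward subtriangle sharing the hypotenuse
                pts.append(o + (np.array([1, 1]) / m) - g / m)
    pts = np.concatenate(pts)
    w = np.full(pts.shape[0], 1.0 / pts.shape[0])
    _REF_QUAD_CACHE[level] = (pts, w)
    return pts, w


def _candidate_triangles(mesh: UniformMesh, geom: MembraneGeometry) -> np.ndarray:
    """Indices of triangles whose hull can intersect some cell ring."""
    cen = mesh.nodes[mesh.triangles].mean(axis=1)  # centroids
    h = mesh.h
    mask = np.zeros(cen.shape[0], dtype=bool)
    for c in geom.cells:
        d = np.hypot(cen[:, 0] - c.center[0], cen[:, 1] - c.center[1])
        mask |= (d >= c.inner_radius - h) & (d <= c.outer_radius + h)
    return np.flatnonzero(mask)


def membrane_area_fractions(
    mesh: UniformMesh,
    geom: MembraneGeometry,
    quad_level: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate |A intersect tau| / |tau| for membrane-crossing triangles.

    Returns (triangle indices, fractions) for the candidate triangles;
    all other triangles have fraction 0.  Fractions come from the
    composite Gauss rule applied to the indicator chi_A.
    """
    if not geom.cells:
        return np.empty(0, dtype=int), np.empty(0)
    delta = min(c.thickness for c in geom.cells)
    if quad_level is None:
        quad_level = default_quad_level(mesh.h, delta)
    cand = _candidate_triangles(mesh, geom)
    if cand.size == 0:
        return cand, np.empty(0)
    ref_pts, ref_w = _ref_quad_points(quad_level)
    p = mesh.nodes[mesh.triangles[cand]]  # (T, 3, 2)
    v0 = p[:, 0, :]
    e1 = p[:, 1, :] - v0
    e2 = p[:, 2, :] - v0
    # physical quadrature points, (T, M, 2)
    phys = (
        v0[:, None, :]
        + ref_pts[None, :, 0, None] * e1[:, None, :]
        + ref_pts[None, :, 1, None] * e2[:, None, :]
    )
    chi = geom.chi(phys.reshape(-1, 2)).reshape(phys.shape[0], -1)
    fr = chi @ ref_w
    keep = fr > 0.0
    return cand[keep], fr[keep]


def assemble_membrane_matrix(
    mesh: UniformMesh,
    geom: MembraneGeometry,
    sigma0: float,
    sigmaA: float,
    quad_level: int | None = None,
    *,
    full: bool = False,
) -> sp.csr_matrix:
    """Membrane correction matrix K_tilde.

    Per triangle the contribution is (sigma0 - sigmaA) * est|A ^ tau| *
    grad(phi_i).grad(phi_j)|_tau; triangles missing the membrane
    contribute nothing.  Requires sigma0 > sigmaA (the conductivity
    splitting is only contractive then); sigmaA == sigma0 gives the
    zero matrix.
    """
    if sigmaA > sigma0:
        raise ValueError(f"need sigmaA <= sigma0, got {sigmaA} > {sigma0}")
    n_tri = mesh.triangles.shape[0]
    weights = np.zeros(n_tri)
    if sigma0 > sigmaA and geom.cells:
        idx, fr = membrane_area_fractions(mesh, geom, quad_level)
        weights[idx] = (sigma0 - sigmaA) * fr
    Kt = _assemble_gradgrad(mesh, tri_weights=weights)
    if full:
        return Kt
    f = mesh.free_nodes
    return _restrict(Kt, f, f)


def _boundary_integral(
    mesh: UniformMesh, bc: BoundaryCondition
) -> np.ndarray:
    """Line integral of g_N against boundary hat functions, on all nodes.

    Each boundary segment of length h carries a 3-point Gauss rule,
    exact for the products of hat functions with data up to degree 4.
    """
    g = np.zeros(mesh.n_nodes)
    # 3-point Gauss on [0, 1]
    s = np.array([0.5 - math.sqrt(15) / 10, 0.5, 0.5 + math.sqrt(15) / 10])
    w = np.array([5 / 18, 8 / 18, 5 / 18])
    for edge, data in bc.neumann.items():
        fn = _as_func(data)
        idx = mesh.edge_nodes(edge)
        pts = mesh.nodes[idx]
        a, b = pts[:-1], pts[1:]  # segments along the edge
        seg_len = np.hypot(*(b - a).T)
        for sk, wk in zip(s, w):
            q = a + sk * (b - a)
            val = fn(q[:, 0], q[:, 1]) * seg_len * wk
            np.add.at(g, idx[:-1], val * (1.0 - sk))  # hat at segment start
            np.add.at(g, idx[1:], val * sk)  # hat at segment end
    return g


def dirichlet_values(mesh: UniformMesh, bc: BoundaryCondition) -> np.ndarray:
    """Prescribed values g_D at the mesh's Dirichlet nodes."""
    vals = np.zeros(mesh.dirichlet_nodes.size)
    pos = {n: k for k, n in enumerate(mesh.dirichlet_nodes)}
    for edge, data in bc.dirichlet.items():
        fn = _as_func(data)
        for n in mesh.edge_nodes(edge):
            if n in pos:
                p = mesh.nodes[n]
                vals[pos[n]] = fn(np.array([p[0]]), np.array([p[1]]))[0]
    return vals


def assemble_load(
    mesh: UniformMesh,
    bc: BoundaryCondition,
    K_full: sp.csr_matrix,
    Kt_full: sp.csr_matrix,
    sigma0: float,
) -> np.ndarray:
    """Load vector on the free nodes.

    Combines the Neumann line integral with the Dirichlet lift: the
    columns of the full conductivity matrix sigma0*K - K_tilde at
    Dirichlet nodes, applied to the prescribed boundary values, move to
    the right-hand side.
    """
    g = _boundary_integral(mesh, bc)[mesh.free_nodes]
    gD = dirichlet_values(mesh, bc)
    if gD.size and np.any(gD != 0.0):
        A_fd = _restrict(sigma0 * K_full - Kt_full, mesh.free_nodes, mesh.dirichlet_nodes)
        g = g - A_fd @ gD
    return g


def gamma_of(
    mesh: UniformMesh, geom: MembraneGeometry, quad_level: int | None = None
) -> float:
    """Largest membrane area fraction of any triangle, gamma in [0, 1].

    For a layer of thickness delta this scales like delta / h and,
    together with the contrast ratio epsilon, bounds the contraction
    factor of the fixed-point iteration by gamma * (1 - epsilon).
    """
    _, fr = membrane_area_fractions(mesh, geom, quad_level)
    return float(fr.max()) if fr.size else 0.0


def epsilon_of(sigma0: float, sigmaA: float) -> float:
    """Conductivity contrast ratio epsilon = sigmaA / sigma0."""
    if sigma0 <= 0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    return sigmaA / sigma0


@dataclass
class FemSystem:
    """Assembled discrete problem ready for the solver.

    ``K`` and ``K_tilde`` are restricted to the free nodes; the full
    versions are kept for the Dirichlet lift and for re-attaching
    boundary values to solutions.
    """

    mesh: UniformMesh
    geom: MembraneGeometry
    bc: BoundaryCondition
    sigma0: float
    sigmaA: float
    quad_level: int | None
    K: sp.csr_matrix
    K_tilde: sp.csr_matrix
    g: np.ndarray
    gD: np.ndarray = field(repr=False)

    def attach_dirichlet(self, U_free: np.ndarray) -> np.ndarray:
        """Expand a free-node vector to all nodes, inserting g_D values."""
        U = np.empty(self.mesh.n_nodes)
        U[self.mesh.free_nodes] = U_free
        U[self.mesh.dirichlet_nodes] = self.gD
        return U

    def export(self, directory) -> None:
        """Dump K and K_tilde in MatrixMarket form, load and nodes as CSV."""
        import scipy.io

        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(d / "K.mtx", sp.coo_matrix(self.K))
        scipy.io.mmwrite(d / "K_tilde.mtx", sp.coo_matrix(self.K_tilde))
        np.savetxt(d / "load.csv", self.g, delimiter=",", header="g", comments="")
        np.savetxt(
            d / "nodes.csv",
            np.column_stack([self.mesh.nodes, np.arange(self.mesh.n_nodes)]),
            delimiter=",",
            header="x,y,index",
            comments="",
        )


def build_system(
    geom: MembraneGeometry,
    bc: BoundaryCondition,
    N: int,
    sigma0: float = 1.0,
    sigmaA: float = 0.001,
    quad_level: int | None = None,
) -> FemSystem:
    """Mesh the domain and assemble K, K_tilde and the load vector."""
    mesh = build_uniform_mesh(N, geom.domain, bc)
    K_full = assemble_laplace(mesh, full=True)
    Kt_full = assemble_membrane_matrix(
        mesh, geom, sigma0, sigmaA, quad_level, full=True
    )
    g = assemble_load(mesh, bc, K_full, Kt_full, sigma0)
    f = mesh.free_nodes
    return FemSystem(
        mesh=mesh,
        geom=geom,
        bc=bc,
        sigma0=sigma0,
        sigmaA=sigmaA,
        quad_level=quad_level,
        K=_restrict(K_full, f, f),
        K_tilde=_restrict(Kt_full, f, f),
        g=g,
        gD=dirichlet_values(mesh, bc),
    )
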