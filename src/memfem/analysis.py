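"""Reference solutions, current density and error metrics.

Errors of the coarse uniform-mesh method are measured against a
reference solution computed in-house on a much finer uniform mesh
(default N=1536, at which the 0.002-thick membrane spans some fifteen
mesh cells) with the coupled system solved directly.  The fine grid is a
multiple of each coarse grid, so coarse nodes are fine nodes and the
two voltage fields can be compared pointwise without interpolation.

The current density J = sigma * |grad u| is recovered at grid points by
differencing the nodal voltage (central differences inside, one-sided
second-order at the boundary), with sigma evaluated pointwise through
the membrane indicator.  The relative L2 error

    e(D) = sqrt( sum_{x_i in D} (u - U_h)^2 / sum_{x_i in D} u^2 )

is reported over the whole domain and over the lumen region inside the
cells' inner circles, where the membrane shields the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import BoundaryCondition, build_system
from .geometry import MembraneGeometry
from .solver import direct_solve

__all__ = [
    "FieldSolution",
    "ErrorReport",
    "solve_reference",
    "current_density",
    "sigma_at_nodes",
    "relative_l2_error",
    "omega_inner_mask",
    "convergence_slope",
]


@dataclass
class FieldSolution:
    """Voltage and current-density magnitude on a structured grid.

    ``U`` and ``J`` are (N+1, N+1) arrays indexed [j, i] with j the
    y-index (row) and i the x-index, matching the row-major mesh node
    ordering.
    """

    N: int
    domain: tuple[float, float, float, float]
    U: np.ndarray
    J: np.ndarray

    @property
    def h(self) -> float:
        xmin, xmax, _, _ = self.domain
        return (xmax - xmin) / self.N

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        xmin, xmax, ymin, ymax = self.domain
        x = np.linspace(xmin, xmax, self.N + 1)
        y = np.linspace(ymin, ymax, self.N + 1)
        return np.meshgrid(x, y)

    def sample_on(self, N_coarse: int) -> "FieldSolution":
        """Restrict the field to the nodes of a coarser divisor grid."""
        if self.N % N_coarse != 0:
            raise ValueError(
                f"fine grid N={self.N} is not a multiple of N_coarse={N_coarse}"
            )
        s = self.N // N_coarse
        return FieldSolution(
            N=N_coarse, domain=self.domain, U=self.U[::s, ::s], J=self.J[::s, ::s]
        )


@dataclass
class ErrorReport:
    """Relative L2 errors of voltage and current density.

    ``e_u_omega`` / ``e_J_omega`` are over the whole domain,
    ``e_u_inner`` / ``e_J_inner`` over the lumen region inside the
    cells; ``n_iter`` records the iterations the method used.
    """

    N: int
    e_u_omega: float
    e_u_inner: float
    e_J_omega: float
    e_J_inner: float
    n_iter: int
    converged: bool = True


def sigma_at_nodes(
    geom: MembraneGeometry,
    points: np.ndarray,
    sigma0: float,
    sigmaA: float,
) -> np.ndarray:
    """Pointwise conductivity sigma0 - (sigma0 - sigmaA) * chi_A."""
    chi = geom.chi(points)
    return sigma0 - (sigma0 - sigmaA) * chi


def current_density(
    U: np.ndarray,
    geom: MembraneGeometry,
    domain: tuple[float, float, float, float],
    sigma0: float = 1.0,
    sigmaA: float = 0.001,
) -> np.ndarray:
    """Current-density magnitude J = sigma * |grad U| at grid points.

    ``U`` is an (N+1, N+1) nodal voltage array.  Gradients are central
    differences at interior points and second-order one-sided at the
    boundary (exact for quadratic fields), and sigma is evaluated at
    each grid point through the membrane indicator.
    """
    n_row, n_col = U.shape
    xmin, xmax, ymin, ymax = domain
    hx = (xmax - xmin) / (n_col - 1)
    hy = (ymax - ymin) / (n_row - 1)
    dUdy, dUdx = np.gradient(U, hy, hx, edge_order=2)
    x = np.linspace(xmin, xmax, n_col)
    y = np.linspace(ymin, ymax, n_row)
    X, Y = np.meshgrid(x, y)
    sig = sigma_at_nodes(
        geom, np.column_stack([X.ravel(), Y.ravel()]), sigma0, sigmaA
    ).reshape(U.shape)
    return sig * np.hypot(dUdx, dUdy)


def solve_reference(
    geom: MembraneGeometry,
    bc: BoundaryCondition,
    N_fine: int = 1536,
    quad_level: int | None = None,
    sigma0: float = 1.0,
    sigmaA: float = 0.001,
) -> FieldSolution:
    """Fine-mesh direct solve serving as the reference ("true") field.

    The mesh must resolve the membrane: h_fine <= delta / 4.  Solves
    the coupled system (sigma0*K - K_tilde) U = g in one shot and
    attaches the current-density field.
    """
    if geom.cells:
        delta = min(c.thickness for c in geom.cells)
        xmin, xmax = geom.domain[0], geom.domain[1]
        h_fine = (xmax - xmin) / N_fine
        if h_fine > delta / 4.0:
            raise ValueError(
                f"N_fine={N_fine} does not resolve the membrane: "
                f"h={h_fine:.4g} > delta/4 = {delta / 4.0:.4g}"
            )
    sys_f = build_system(geom, bc, N_fine, sigma0, sigmaA, quad_level)
    U = direct_solve(sys_f).reshape(N_fine + 1, N_fine + 1)
    J = current_density(U, geom, geom.domain, sigma0, sigmaA)
    return FieldSolution(N=N_fine, domain=geom.domain, U=U, J=J)


def omega_inner_mask(
    geom: MembraneGeometry, N: int
) -> np.ndarray:
    """Grid-point mask of the lumen: strictly inside some inner circle."""
    xmin, xmax, ymin, ymax = geom.domain
    x = np.linspace(xmin, xmax, N + 1)
    y = np.linspace(ymin, ymax, N + 1)
    X, Y = np.meshgrid(x, y)
    mask = np.zeros_like(X, dtype=bool)
    for c in geom.cells:
        mask |= np.hypot(X - c.center[0], Y - c.center[1]) < c.inner_radius
    return mask


def relative_l2_error(
    field: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Discrete relative L2 error sqrt(sum (u-U)^2 / sum u^2) on a region.

    ``mask`` selects the grid points of the region (all points when
    None).  The reference must not vanish identically on the region.
    """
    f = np.asarray(field, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {r.shape}")
    if mask is not None:
        f = f[mask]
        r = r[mask]
    denom = float(np.sum(r**2))
    if denom == 0.0:
        raise ValueError("reference field is identically zero on the region")
    return float(np.sqrt(np.sum((f - r) ** 2) / denom))


def convergence_slope(
    errors, Ns, side_length: float = 0.2
) -> float:
    """Least-squares slope of log(error) against log(h), h = side / N.

    A slope near 1 indicates first-order O(h) convergence.
    """
    errors = np.asarray(errors, dtype=float)
    Ns = np.asarray(Ns, dtype=float)
    if errors.size < 3:
        raise ValueError("need at least 3 (N, error) pairs")
    if np.any(errors <= 0):
        raise ValueError("errors must be positive for a log-log fit")
    h = side_length / Ns
    slope, _ = np.polyfit(np.log(h), np.log(errors), 1)
    return float(slope)
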