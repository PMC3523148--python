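"""Fixed-point iteration for the split conductivity system.

The Galerkin system (sigma0*K - K_tilde) U = g is solved by iterating

    sigma0 * K * U^(n+1) = g + K_tilde * U^(n),

so each step is a uniform-conductivity solve with an updated right-hand
side.  K is factorised once (sparse LU) and the factorisation is reused
every step.  The membrane only enters through K_tilde * U^(n), an
integral of the previous iterate over the thin layer -- which is what
makes the scheme cheap on a structured mesh that never resolves the
membrane.

The error propagates as E^(n+1) = (sigma0*K)^{-1} K_tilde E^(n), so the
spectral norm of that matrix is the contraction factor.  It is bounded
by gamma * (1 - epsilon), with gamma the worst membrane area fraction
of a triangle (about delta/h) and epsilon = sigmaA/sigma0 the contrast
ratio; the iteration therefore converges whenever the mesh is coarse
relative to the membrane in the sense gamma < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .assembly import FemSystem, epsilon_of, gamma_of

__all__ = [
    "SolveResult",
    "ContractionReport",
    "fixed_point_solve",
    "direct_solve",
    "contraction_norm",
    "suggest_mesh",
]

# ordering heuristic that keeps SuperLU fill-in moderate on 2D grids
_PERMC = "MMD_AT_PLUS_A"


@dataclass
class SolveResult:
    """Outcome of the fixed-point iteration.

    ``U`` holds nodal voltages on all mesh nodes (Dirichlet values
    re-attached); ``U_free`` is the raw unknown vector.  ``n_iter``
    counts the updates performed after the initial guess, and
    ``rel_changes[k]`` is ||U^(k+1) - U^(k)|| / ||U^(k)|| over the free
    nodes in the Euclidean norm.
    """

    U: np.ndarray
    U_free: np.ndarray
    n_iter: int
    rel_changes: np.ndarray
    converged: bool
    tol: float

    def save(self, directory, mesh=None) -> None:
        """Write a JSON run summary and, given the mesh, a voltage CSV."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        summary = {
            "n_iter": self.n_iter,
            "converged": bool(self.converged),
            "tol": self.tol,
            "rel_changes": [float(r) for r in self.rel_changes],
        }
        (d / "solve_summary.json").write_text(json.dumps(summary, indent=2))
        if mesh is not None:
            np.savetxt(
                d / "voltage.csv",
                np.column_stack([mesh.nodes, self.U]),
                delimiter=",",
                header="x,y,u",
                comments="",
            )


@dataclass
class ContractionReport:
    """Theoretical vs measured contraction of the iteration.

    ``bound = gamma * (1 - epsilon)`` is the a-priori contraction
    bound; ``measured_norm`` is the spectral norm of
    (sigma0*K)^{-1} K_tilde, which the bound must dominate.
    ``observed_ratio`` optionally records the asymptotic ratio of
    consecutive relative changes from an actual solve.
    """

    gamma: float
    epsilon: float
    bound: float
    measured_norm: float
    observed_ratio: float | None = None


def _factorize(sys: FemSystem) -> spla.SuperLU:
    return spla.splu(sp.csc_matrix(sys.sigma0 * sys.K), permc_spec=_PERMC)


def fixed_point_solve(
    sys: FemSystem,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    initial: str | np.ndarray = "uniform",
) -> SolveResult:
    """Run the fixed-point iteration until the relative change is small.

    The initial guess ``'uniform'`` is the homogeneous-conductivity
    solve (sigma0*K)^{-1} g; ``'zero'`` starts from the zero vector; an
    array is used as given.  Iteration stops when
    ||U^(n+1) - U^(n)|| / ||U^(n)|| <= tol, or flags ``converged=False``
    after ``max_iter`` updates.
    """
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if sys.sigmaA > sys.sigma0:
        raise ValueError("fixed-point splitting requires sigmaA <= sigma0")
    lu = _factorize(sys)
    if isinstance(initial, str):
        if initial == "uniform":
            U = lu.solve(sys.g)
        elif initial == "zero":
            U = np.zeros_like(sys.g)
        else:
            raise ValueError(f"unknown initial guess {initial!r}")
    else:
        U = np.asarray(initial, dtype=float).copy()
        if U.shape != sys.g.shape:
            raise ValueError("initial vector has wrong length")

    rel_changes: list[float] = []
    converged = False
    for _ in range(max_iter):
        U_next = lu.solve(sys.g + sys.K_tilde @ U)
        denom = np.linalg.norm(U)
        diff = np.linalg.norm(U_next - U)
        rel = diff / denom if denom > 0 else diff
        rel_changes.append(rel)
        U = U_next
        if rel <= tol:
            converged = True
            break
    return SolveResult(
        U=sys.attach_dirichlet(U),
        U_free=U,
        n_iter=len(rel_changes),
        rel_changes=np.asarray(rel_changes),
        converged=converged,
        tol=tol,
    )


def direct_solve(sys: FemSystem) -> np.ndarray:
    """One-shot sparse solve of (sigma0*K - K_tilde) U = g.

    This is the coupled Galerkin system itself and serves as the oracle
    the fixed-point iteration must converge to.  Returns nodal voltages
    on all mesh nodes with Dirichlet values attached.
    """
    A = sp.csc_matrix(sys.sigma0 * sys.K - sys.K_tilde)
    lu = spla.splu(A, permc_spec=_PERMC)
    U = lu.solve(sys.g)
    if not np.all(np.isfinite(U)):
        raise np.linalg.LinAlgError("direct solve produced non-finite values")
    return sys.attach_dirichlet(U)


def contraction_norm(
    sys: FemSystem,
    method: str = "dense",
    *,
    observed_ratio: float | None = None,
    power_tol: float = 1e-8,
    power_max_iter: int = 5000,
) -> ContractionReport:
    """Spectral norm of the iteration matrix M = (sigma0*K)^{-1} K_tilde.

    ``method='dense'`` forms M explicitly and takes its largest singular
    value (free-node counts up to a few thousand); ``method='power'``
    runs power iteration on M^T M using the sparse factorisation of K,
    to relative tolerance ``power_tol``.
    """
    gamma = gamma_of(sys.mesh, sys.geom, sys.quad_level)
    eps = epsilon_of(sys.sigma0, sys.sigmaA)
    if method == "dense":
        n = sys.K.shape[0]
        if n > 4000:
            raise ValueError(
                f"dense contraction norm limited to ~4000 unknowns, got {n}; "
                "use method='power'"
            )
        lu = _factorize(sys)
        M = lu.solve(sys.K_tilde.toarray())
        norm = float(np.linalg.svd(M, compute_uv=False)[0]) if n else 0.0
    elif method == "power":
        lu = _factorize(sys)
        Kt = sp.csc_matrix(sys.K_tilde)
        if Kt.nnz == 0:
            norm = 0.0
        else:
            rng = np.random.default_rng(0)
            v = rng.standard_normal(sys.K.shape[0])
            v /= np.linalg.norm(v)
            lam_old = 0.0
            for it in range(power_max_iter):
                # w = M^T M v; M^T = K_tilde (sigma0 K)^{-T} and K SPD
                w = Kt @ lu.solve(lu.solve(Kt @ v))
                lam = float(v @ w)
                nw = np.linalg.norm(w)
                if nw == 0.0:
                    lam = 0.0
                    break
                v = w / nw
                if abs(lam - lam_old) <= power_tol * max(lam, 1e-300):
                    break
                lam_old = lam
            else:
                raise RuntimeError(
                    f"power iteration did not converge in {power_max_iter} "
                    f"steps; last eigenvalue estimates {lam_old:.3e} -> {lam:.3e}"
                )
            norm = float(np.sqrt(max(lam, 0.0)))
    else:
        raise ValueError(f"method must be 'dense' or 'power', got {method!r}")
    return ContractionReport(
        gamma=gamma,
        epsilon=eps,
        bound=gamma * (1.0 - eps),
        measured_norm=norm,
        observed_ratio=observed_ratio,
    )


def suggest_mesh(delta: float, c: float) -> float:
    """Smallest mesh size h keeping the contraction bound below c.

    Since the bound behaves like (delta/h)(1 - epsilon) <= delta/h,
    choosing h >= delta/c guarantees a contraction factor of about c or
    better; c must lie in (0, 1).
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"c must lie in (0, 1), got {c}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    return delta / c
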