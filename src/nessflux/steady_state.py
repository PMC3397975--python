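"""Direct constrained minimization of H and thermodynamic feasibility.

``minimize_H`` solves the convex box-constrained quadratic program

    min_nu  H(nu) = sum_mu (sum_i xi[mu,i] nu_i + u[mu])**2 / cbar[mu]
    s.t.    -qmax_i <= nu_i <= qmax_i

exactly (it is a bounded-variable least-squares problem, so the global
minimum is attained and certified by the projected-gradient KKT residual).

When the minimum is (numerically) zero the minimizer set is an affine
subset of the box — a particular balanced flux vector plus the null space of
the stoichiometric matrix.  ``minimize_flux_norm`` selects the unique
minimum-Euclidean-norm point of the minimizer set, which removes
stoichiometrically closed cycles (infeasible loops) from the flux vector.

``check_thermo_feasibility`` decides, via the Gordan theorem of
alternatives, whether a flux configuration is thermodynamically realizable:
either species potentials g exist that make every active reaction run
downhill (xi' g strictly opposite in sign to its flux), or the flux vector
supports a closed cycle k (xi k = 0, sign-matching nu) certifying
infeasibility.  Exactly one of the two certificates exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, lsq_linear, minimize

from .coupling import build_couplings, hamiltonian_gradient, residual_form
from .netio import ReactionNetwork

__all__ = [
    "MinimizationResult",
    "SolutionSpace",
    "FeasibilityCertificate",
    "minimize_H",
    "solution_space",
    "minimize_flux_norm",
    "check_thermo_feasibility",
]


@dataclass
class MinimizationResult:
    """Certified minimizer of H over the flux box."""

    nu: np.ndarray
    H_min: float
    active_set: np.ndarray      # indices with |nu_i| at the bound
    kkt_residual: float         # max-norm of the projected gradient


@dataclass
class SolutionSpace:
    """Affine parametrization of the balanced minimizer set:
    nu = particular + basis @ t (basis columns orthonormal)."""

    particular: np.ndarray
    basis: np.ndarray           # (N, dim), orthonormal columns
    dim: int


@dataclass
class FeasibilityCertificate:
    """Gordan alternative: exactly one of ``potentials`` / ``cycle`` is set.

    feasible=True  -> ``potentials`` g satisfies (xi' g) * sign(nu_i) < 0
                      for every reaction with non-zero flux.
    feasible=False -> ``cycle`` k satisfies xi k = 0 with sign(k_i)
                      matching sign(nu_i) on its support.
    """

    feasible: bool
    potentials: np.ndarray | None = None
    cycle: np.ndarray | None = None
    trivial: bool = False       # all-zero flux vector: vacuously feasible


def _design(net: ReactionNetwork) -> tuple[np.ndarray, np.ndarray]:
    """H(nu) = ||A nu - b||^2 with A = xi / sqrt(cbar), b = -u / sqrt(cbar)."""
    S = net.stoichiometric_matrix()
    w = 1.0 / np.sqrt(net.cbar())
    return S * w[:, None], -net.uptake() * w


def _kkt_residual(net: ReactionNetwork, nu: np.ndarray, lo, hi, tol_bound=1e-9) -> tuple[float, np.ndarray]:
    g = hamiltonian_gradient(build_couplings(net), nu)
    at_lo = nu <= lo + tol_bound * np.maximum(1.0, np.abs(lo))
    at_hi = nu >= hi - tol_bound * np.maximum(1.0, np.abs(hi))
    proj = g.copy()
    proj[at_lo] = np.minimum(g[at_lo], 0.0)   # gradient may point outward (down)
    proj[at_hi] = np.maximum(g[at_hi], 0.0)
    active = np.flatnonzero(at_lo | at_hi)
    return float(np.max(np.abs(proj), initial=0.0)), active


def minimize_H(
    net: ReactionNetwork,
    tol: float = 1e-10,
    start: np.ndarray | None = None,
) -> MinimizationResult:
    """Globally minimize H over the box [-qmax, qmax]^N.

    The problem is convex, hence the attained value is the global minimum;
    ``start`` only matters for tie-breaking among degenerate minimizers (the
    bvls solver is deterministic, so identical inputs give identical output).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    A, b = _design(net)
    q = net.qmax()
    if start is not None:
        # shift coordinates so the given start is the origin: bvls itself
        # does not take an initial point, but the minimizer set is affine,
        # so re-centering keeps determinism while honoring the start.
        start = np.clip(np.asarray(start, dtype=float), -q, q)
        res = lsq_linear(A, b - A @ start, bounds=(-q - start, q - start), method="bvls", tol=tol)
        nu = res.x + start
    else:
        res = lsq_linear(A, b, bounds=(-q, q), method="bvls", tol=tol)
        nu = res.x
    nu = np.clip(nu, -q, q)
    H_min = residual_form(net, nu)
    kkt, active = _kkt_residual(net, nu, -q, q)
    return MinimizationResult(nu=nu, H_min=H_min, active_set=active, kkt_residual=kkt)


def solution_space(
    net: ReactionNetwork,
    eps_H: float | None = None,
    rtol: float = 1e-10,
) -> SolutionSpace:
    """Particular balanced solution plus an orthonormal null-space basis.

    Requires the balanced regime (min H below ``eps_H``); otherwise raises
    ``ValueError("no balanced solution")``.  The basis spans
    {k : sum_i xi[mu,i] k_i = 0 for all mu}; its dimension is N - rank(xi).
    """
    res = minimize_H(net)
    cs_const = build_couplings(net).const
    if eps_H is None:
        eps_H = 1e-9 * (1.0 + cs_const)
    if res.H_min >= eps_H:
        raise ValueError(
            f"no balanced solution: min H = {res.H_min:.3e} >= eps_H = {eps_H:.3e}"
        )
    S = net.stoichiometric_matrix()
    _, sv, Vt = np.linalg.svd(S, full_matrices=True)
    smax = sv[0] if sv.size else 0.0
    rank = int(np.sum(sv > rtol * max(smax, 1.0)))
    basis = Vt[rank:].T
    return SolutionSpace(particular=res.nu, basis=basis, dim=basis.shape[1])


def minimize_flux_norm(
    net: ReactionNetwork, result: MinimizationResult
) -> MinimizationResult:
    """Minimum-||nu||_2 point of the minimizer set of H (loop removal).

    The minimizer set of the convex problem is {nu in box : A nu = A nu*};
    minimizing the strictly convex ||nu||^2 over it has a unique solution.
    H is unchanged (within numerical tolerance) and the norm can only
    decrease.
    """
    A, _ = _design(net)
    q = net.qmax()
    target = A @ result.nu

    # minimum-norm point of the affine set {x : A x = target}; if it sits
    # inside the box the projection is exact and no iteration is needed.
    x0, *_ = np.linalg.lstsq(A, target, rcond=None)
    if np.all(np.abs(x0) <= q + 1e-12):
        nu = np.clip(x0, -q, q)
    else:

        def f(x):
            return float(x @ x), 2.0 * x

        cons = {"type": "eq", "fun": lambda x: A @ x - target, "jac": lambda x: A}
        res = minimize(
            f,
            np.clip(x0, -q * (1 - 1e-9), q * (1 - 1e-9)),
            jac=True,
            bounds=list(zip(-q, q)),
            constraints=[cons],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        nu = np.clip(res.x, -q, q)
        if not res.success or nu @ nu > result.nu @ result.nu:
            nu = result.nu   # solver failed to improve; keep input
    H_min = residual_form(net, nu)
    kkt, active = _kkt_residual(net, nu, -q, q)
    return MinimizationResult(nu=nu, H_min=H_min, active_set=active, kkt_residual=kkt)


def check_thermo_feasibility(
    net: ReactionNetwork,
    nu: np.ndarray,
    margin: float = 1e-6,
    flux_tol: float = 1e-9,
) -> FeasibilityCertificate:
    """Gordan-alternative feasibility check for a flux configuration.

    Searches species potentials g (normalized to |g|_inf <= 1) with
    (xi' g)_i * sign(nu_i) <= -margin for every reaction with
    |nu_i| > flux_tol.  If no such potentials exist, a certifying cycle is
    returned instead.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    nu = np.asarray(nu, dtype=float)
    S = net.stoichiometric_matrix()      # (M, N)
    active = np.flatnonzero(np.abs(nu) > flux_tol)
    if active.size == 0:
        return FeasibilityCertificate(
            feasible=True, potentials=np.zeros(net.M), trivial=True
        )
    signs = np.sign(nu[active])
    # LP 1: maximize t s.t. sign_i * (S[:, i]' g) <= -t, -1 <= g <= 1, t <= 1
    # variables: (g_1..g_M, t); objective min -t
    M = net.M
    A_ub = np.hstack([(S[:, active] * signs).T, np.ones((active.size, 1))])
    b_ub = np.zeros(active.size)
    c = np.zeros(M + 1)
    c[-1] = -1.0
    bounds = [(-1.0, 1.0)] * M + [(0.0, 1.0)]
    lp = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if lp.status == 0 and lp.x is not None and lp.x[-1] > margin:
        return FeasibilityCertificate(feasible=True, potentials=lp.x[:M])
    # LP 2 (Gordan alternative): find w >= 0, sum w = 1, S (signs*w) = 0
    A_eq = np.vstack([S[:, active] * signs, np.ones(active.size)])
    b_eq = np.zeros(M + 1)
    b_eq[-1] = 1.0
    lp2 = linprog(
        np.zeros(active.size),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0.0, None)] * active.size,
        method="highs",
    )
    if lp2.status != 0 or lp2.x is None:
        # numerically marginal case: accept a weakly positive margin from LP 1
        if lp.status == 0 and lp.x is not None and lp.x[-1] > 0:
            return FeasibilityCertificate(feasible=True, potentials=lp.x[:M])
        raise RuntimeError(
            "Gordan alternative violated numerically: neither potentials nor "
            "cycle found"
        )
    k = np.zeros(nu.size)
    k[active] = signs * lp2.x
    return FeasibilityCertificate(feasible=False, cycle=k)
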