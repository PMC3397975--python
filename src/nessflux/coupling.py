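"""Hebbian coupling system and the variational function H.

For a network with stoichiometric coefficients ``xi[mu, i]``, steady
concentrations ``cbar[mu]`` and boundary exchange rates ``u[mu]``, the
couplings are the Hopfield-like Gram structure

    J[i, j] = sum_mu xi[mu, i] * xi[mu, j] / cbar[mu]
    h[i]    = sum_mu xi[mu, i] * u[mu]     / cbar[mu]
    const   = sum_mu u[mu]**2              / cbar[mu]

and the variational function evaluated on a flux vector ``nu`` is the
concentration-weighted sum of squared per-species imbalance residuals

    H(nu) = sum_mu r_mu(nu)**2 / cbar[mu],
    r_mu(nu) = sum_i xi[mu, i] * nu_i + u[mu]

which equals the quadratic form ``nu' J nu + 2 h' nu + const``.  H >= 0
always, H = 0 exactly at strict mass balance (Kirchhoff-type scenario), and
stationary fluxes of the reactor minimize H.

The global prefactor of H is fixed to 1 (all results of interest — phase
transition location, minimizers, feasibility — are invariant under a
positive rescaling of H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import ReactionNetwork

__all__ = [
    "CouplingSystem",
    "build_couplings",
    "balance_residuals",
    "hamiltonian",
    "hamiltonian_gradient",
    "residual_form",
]


@dataclass(frozen=True)
class CouplingSystem:
    """Explicit quadratic form H(nu) = nu'J nu + 2 h'nu + const.

    ``J`` is symmetric positive semidefinite (a Gram matrix of the patterns
    ``xi[:, i] / sqrt(cbar)``), so H is convex and non-negative.
    """

    J: np.ndarray
    h: np.ndarray
    const: float

    @property
    def N(self) -> int:
        return self.h.shape[0]

    def __call__(self, nu: np.ndarray) -> float:
        return hamiltonian(self, nu)


def build_couplings(net: ReactionNetwork) -> CouplingSystem:
    """Assemble (J, h, const) from the network; the sparse stoichiometry is
    expanded to a dense matrix exactly once."""
    S = net.stoichiometric_matrix()          # (M, N)
    cbar = net.cbar()
    u = net.uptake()
    W = S / cbar[:, None]                    # xi / cbar, species-major
    J = S.T @ W
    J = 0.5 * (J + J.T)                      # enforce exact symmetry
    h = W.T @ u
    const = float(np.sum(u * u / cbar))
    return CouplingSystem(J=J, h=h, const=const)


def balance_residuals(net: ReactionNetwork, nu: np.ndarray) -> np.ndarray:
    """Per-species residual r_mu = sum_i xi[mu,i] nu_i + u[mu].

    r = 0 for every species is the strict mass-balance (flux-balance)
    condition; the weaker Von Neumann-type variant only requires r >= 0
    (no species consumed in excess of availability) — use
    ``balance_residuals(net, nu) >= 0`` for that test.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (net.N,):
        raise ValueError(f"flux vector has shape {nu.shape}, expected ({net.N},)")
    return net.stoichiometric_matrix() @ nu + net.uptake()


def residual_form(net: ReactionNetwork, nu: np.ndarray) -> float:
    """H evaluated directly from the residuals (independent of J, h)."""
    r = balance_residuals(net, nu)
    return float(np.sum(r * r / net.cbar()))


def hamiltonian(cs: CouplingSystem, nu: np.ndarray) -> float:
    """Quadratic-form evaluation of H; equals :func:`residual_form` to
    numerical precision."""
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (cs.N,):
        raise ValueError(f"flux vector has shape {nu.shape}, expected ({cs.N},)")
    val = float(nu @ cs.J @ nu + 2.0 * cs.h @ nu + cs.const)
    # clamp tiny negative round-off: H is a sum of squares
    return max(val, 0.0)


def hamiltonian_gradient(cs: CouplingSystem, nu: np.ndarray) -> np.ndarray:
    """grad H = 2 (J nu + h)."""
    nu = np.asarray(nu, dtype=float)
    return 2.0 * (cs.J @ nu + cs.h)
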