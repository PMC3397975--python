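"""Linear stability of the NESS dynamics via the bidirectional Gram spectrum.

Perturbations around a steady state only couple to the reactions that remain
bidirectional (frozen reactions are insensitive: their tanh response is
saturated).  To linear order the perturbations relax under the restricted
Gram matrix

    C[i, j] = (1/M) * sum_mu xi[mu, i] xi[mu, j] / cbar[mu],   i, j bidirectional,

so the steady state is linearly stable — and the dynamics ergodic — iff the
smallest eigenvalue of C is positive.  For random +-1 patterns of density p
(entry variance sigma2 = p) and aspect ratio r = N_bid / M, the
Marchenko-Pastur-type spectral edge is

    lambda_min -> sigma2 * (1 - sqrt(r))**2     (M -> infinity, r fixed)

which vanishes at r = 1: marginal stability, and the onset of ergodicity
breaking, occur when the number of bidirectional reactions equals the number
of species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ReactionClassification
from .netio import ReactionNetwork

__all__ = [
    "SpectrumReport",
    "bidirectional_spectrum",
    "stability_verdict",
    "marchenko_pastur_edge",
]

EIG_TOL = 1e-10


@dataclass
class SpectrumReport:
    r: float                    # aspect ratio N_bid / M
    lambda_min: float | None    # smallest eigenvalue; None if no bidirectional set
    lambda_edge: float          # theoretical edge sigma2 * (1 - sqrt(r))**2
    sigma2: float               # entry variance of xi (p for the +-1 ensemble)
    stable: bool
    eigenvalues: np.ndarray | None = None
    tanh_prefactor: np.ndarray | None = None   # diagonal 1 - nu*^2 factor, reported
                                               # separately (positive, does not
                                               # change eigenvalue signs)


def marchenko_pastur_edge(r: float, sigma2: float) -> float:
    """Smallest-eigenvalue edge sigma2 * (1 - sqrt(r))**2 of the Gram
    ensemble with aspect ratio r (0 for r >= 1)."""
    if r >= 1.0:
        return 0.0
    return sigma2 * (1.0 - np.sqrt(r)) ** 2


def estimate_sigma2(net: ReactionNetwork) -> float:
    """Empirical entry variance of the stoichiometric matrix."""
    S = net.stoichiometric_matrix()
    return float(np.mean(S**2) - np.mean(S) ** 2)


def bidirectional_spectrum(
    net: ReactionNetwork,
    classification: ReactionClassification,
    sigma2: float | None = None,
    fluxes: np.ndarray | None = None,
) -> SpectrumReport:
    """Spectrum of the Gram matrix restricted to bidirectional reactions.

    ``sigma2`` defaults to the empirical entry variance of the network's
    stoichiometric matrix; pass ``p`` explicitly for the standard random
    ensemble.  ``fluxes`` (optional, the NESS flux vector) only feeds the
    reported 1 - nu*^2 diagonal prefactor of the linearization.
    """
    if sigma2 is None:
        sigma2 = estimate_sigma2(net)
    bid = ~classification.unidirectional_mask()
    n_bid = int(bid.sum())
    M = net.M
    r = n_bid / M
    edge = marchenko_pastur_edge(r, sigma2)
    if n_bid == 0:
        return SpectrumReport(
            r=0.0, lambda_min=None, lambda_edge=marchenko_pastur_edge(0.0, sigma2),
            sigma2=sigma2, stable=True, eigenvalues=None,
        )
    S = net.stoichiometric_matrix()[:, bid]
    C = (S.T * (1.0 / net.cbar())) @ S / M
    eigs = np.linalg.eigvalsh(0.5 * (C + C.T))
    lam_min = float(eigs[0])
    pref = None
    if fluxes is not None:
        pref = 1.0 - np.asarray(fluxes, dtype=float)[bid] ** 2
    return SpectrumReport(
        r=r,
        lambda_min=lam_min,
        lambda_edge=edge,
        sigma2=sigma2,
        stable=lam_min > EIG_TOL,
        eigenvalues=eigs,
        tanh_prefactor=pref,
    )


def stability_verdict(report: SpectrumReport, grid_tol: float = 0.05) -> str:
    """Classify the steady state: ``ergodic_stable`` (r < 1 and positive
    spectrum), ``marginal`` (|r - 1| within grid tolerance), ``unstable``
    (r > 1)."""
    if abs(report.r - 1.0) < grid_tol:
        return "marginal"
    if report.r > 1.0:
        return "unstable"
    if report.lambda_min is None or report.lambda_min > EIG_TOL:
        return "ergodic_stable"
    return "marginal"
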