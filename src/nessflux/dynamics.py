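"""Stochastic resource-allocation dynamics of the reaction ensemble.

Each reaction ``i`` carries an accumulator ``y_i`` whose value sets the
log-ratio of the probabilities of a forward vs. reverse microscopic
transition at the next time step:

    P(m_i = +1) = (1 + tanh y_i) / 2        (so P(+)/P(-) = exp(2 y_i))

After all reactions sample a direction ``m``, the accumulators move downhill
along the (rescaled) gradient of the variational function H:

    y_i <- y_i - eta * rescale * ( sum_j J_ij m_j + h_i )

with ``rescale = 1/M`` by default so the drift stays O(1) as the network
grows.  This is the minority-game-like online dynamics; the "mean-field"
variant replaces the sampled ``m`` by its conditional mean ``tanh y`` and is
used as a deterministic oracle in tests.

The probability ratio exp(2 y_i) tracks the ratio of substrate to product
concentrations, hence ``y`` is (minus) the Gibbs energy of the reaction in
units of 2RT: DeltaG_i = -2 R T y_i.  Reactions whose ``y`` stays bounded
remain bidirectional (both microscopic directions persist, net flux
tanh y*); reactions whose ``y`` drifts linearly freeze into unidirectional
operation.  The fraction of frozen reactions, phi, is the order parameter of
the ergodicity-breaking transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coupling import CouplingSystem, build_couplings
from .netio import ReactionNetwork

__all__ = [
    "TrajectoryRecord",
    "ReactionClassification",
    "simulate",
    "estimate_fluxes",
    "classify_reactions",
    "deltaG_from_y",
    "BIDIRECTIONAL",
    "UNIDIRECTIONAL_FORWARD",
    "UNIDIRECTIONAL_REVERSE",
]

BIDIRECTIONAL = "bidirectional"
UNIDIRECTIONAL_FORWARD = "unidirectional_forward"
UNIDIRECTIONAL_REVERSE = "unidirectional_reverse"

Y_CLIP = 500.0  # tanh saturates to machine precision near |y| ~ 19; the clip
                # only guards against float overflow in pathological runs.


@dataclass
class TrajectoryRecord:
    """Checkpointed time series of one simulation run."""

    checkpoints: np.ndarray     # step indices (1-based), geometric schedule
    y: np.ndarray               # (n_checkpoints, N) accumulators
    m_mean: np.ndarray          # (n_checkpoints, N) running mean of sampled m
    H_series: np.ndarray        # H on the running flux average at checkpoints
    flux_mean_post: np.ndarray  # mean of m over post-burn-in steps, (N,)
    steps: int
    burnin: int
    eta: float
    rescale: float
    seed: int | None
    clipped: np.ndarray         # bool (N,): accumulator hit the overflow clip

    @property
    def y_final(self) -> np.ndarray:
        return self.y[-1]

    def checkpoint_at(self, step: int) -> int:
        """Index of the checkpoint closest to ``step``."""
        return int(np.argmin(np.abs(self.checkpoints - step)))


@dataclass
class ReactionClassification:
    """Per-reaction asymptotic labels and the frozen fraction phi."""

    labels: list[str]
    slope: np.ndarray
    phi: float

    def unidirectional_mask(self) -> np.ndarray:
        return np.array([lab != BIDIRECTIONAL for lab in self.labels], dtype=bool)


def _checkpoint_schedule(steps: int, n: int = 256) -> np.ndarray:
    if n >= steps:
        return np.arange(1, steps + 1)
    pts = np.unique(np.round(np.geomspace(1, steps, num=n)).astype(int))
    pts = np.union1d(pts, [max(1, steps // 2), steps])
    return pts


def simulate(
    net: ReactionNetwork,
    steps: int,
    eta: float = 1.0,
    y0: np.ndarray | float | None = None,
    seed: int | None = None,
    *,
    burnin: int | None = None,
    rescale: float | None = None,
    mode: str = "stochastic",
    couplings: CouplingSystem | None = None,
    n_checkpoints: int = 256,
) -> TrajectoryRecord:
    """Run the update dynamics for ``steps`` steps.

    Parameters
    ----------
    eta : learning rate (drift step size), > 0.
    y0 : initial accumulators; scalar is broadcast; default 0 (unbiased).
    burnin : steps discarded for flux averages; default ``steps // 2``.
    rescale : coupling rescale factor; default ``1 / M``.
    mode : ``"stochastic"`` samples m in {-1, +1}; ``"meanfield"`` uses
        m = tanh(y) deterministically (test oracle).
    couplings : precomputed coupling system (avoids rebuilding in sweeps).

    Identical inputs and seed give bit-for-bit identical trajectories.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if mode not in ("stochastic", "meanfield"):
        raise ValueError(f"unknown mode {mode!r}")
    N = net.N
    if burnin is None:
        burnin = steps // 2
    if not 0 <= burnin < steps:
        raise ValueError("burnin must satisfy 0 <= burnin < steps")
    if rescale is None:
        rescale = 1.0 / net.M
    cs = couplings if couplings is not None else build_couplings(net)
    step_size = eta * rescale

    if y0 is None:
        y = np.zeros(N)
    else:
        y = np.broadcast_to(np.asarray(y0, dtype=float), (N,)).copy()

    rng = np.random.default_rng(seed)
    checkpoints = _checkpoint_schedule(steps, n_checkpoints)
    n_cp = checkpoints.size
    y_series = np.empty((n_cp, N))
    m_mean_series = np.empty((n_cp, N))
    H_series = np.empty(n_cp)

    m_sum = np.zeros(N)        # cumulative over all steps
    m_sum_burn = np.zeros(N)   # snapshot of m_sum at the burn-in boundary
    clipped = np.zeros(N, dtype=bool)
    cp_iter = 0
    inv_vdt = 1.0 / (net.volume * net.dt)
    S = net.stoichiometric_matrix()
    cbar = net.cbar()
    u = net.uptake()

    for t in range(1, steps + 1):
        if mode == "stochastic":
            p_plus = 0.5 * (1.0 + np.tanh(y))
            m = np.where(rng.random(N) < p_plus, 1.0, -1.0)
        else:
            m = np.tanh(y)
        y -= step_size * (cs.J @ m + cs.h)
        over = np.abs(y) > Y_CLIP
        if over.any():
            if not clipped[over].all():
                warnings.warn(
                    "accumulator |y| exceeded the overflow clip; trajectory "
                    "is saturated for the clipped reactions",
                    stacklevel=2,
                )
            clipped |= over
            np.clip(y, -Y_CLIP, Y_CLIP, out=y)
        m_sum += m
        if t == burnin:
            m_sum_burn = m_sum.copy()
        if t == checkpoints[cp_iter]:
            y_series[cp_iter] = y
            m_mean_series[cp_iter] = m_sum / t
            if t > burnin:
                flux_avg = (m_sum - m_sum_burn) / (t - burnin)
            else:
                flux_avg = m_sum / t
            r = S @ (flux_avg * inv_vdt) + u
            H_series[cp_iter] = float(np.sum(r * r / cbar))
            cp_iter += 1

    flux_mean_post = (m_sum - m_sum_burn) / (steps - burnin)
    return TrajectoryRecord(
        checkpoints=checkpoints,
        y=y_series,
        m_mean=m_mean_series,
        H_series=H_series,
        flux_mean_post=flux_mean_post,
        steps=steps,
        burnin=burnin,
        eta=eta,
        rescale=rescale,
        seed=seed,
        clipped=clipped,
    )


def estimate_fluxes(traj: TrajectoryRecord, net: ReactionNetwork) -> np.ndarray:
    """Time-averaged net flux per reaction: mean of the sampled directions
    over the post-burn-in window, divided by V * dt."""
    if traj.burnin >= traj.steps:
        raise ValueError("burnin must be smaller than steps")
    return traj.flux_mean_post / (net.volume * net.dt)


def classify_reactions(
    traj: TrajectoryRecord,
    eps_slope: float = 1e-2,
    sat_transitions: float = 10.0,
) -> ReactionClassification:
    """Label each reaction from its asymptotic behavior.

    A reaction is unidirectional — its microscopic transitions occur in a
    single direction asymptotically — under either of two signatures:

    * drifting accumulator: |slope_i| > eps_slope, with
      slope_i = [y_i(T) - y_i(T/2)] / (T/2) (or a trajectory pinned at the
      overflow clip, where the slope estimate is flattened);
    * saturated sampling: the post-burn-in mean direction satisfies
      |m_mean_i| >= 1 - sat_transitions / (T - burnin), i.e. fewer than
      ~sat_transitions/2 reverse transitions were observed in the whole
      stationary window.  This catches reactions parked at a large finite y
      on a zero-gradient (H = 0) plateau, where the accumulator no longer
      drifts yet only one microscopic direction ever occurs — the typical
      outcome of a polarized initial condition in the non-ergodic phase.

    Everything else is bidirectional.
    """
    if traj.checkpoints.size < 4:
        raise ValueError("need at least 4 checkpoints to classify")
    i_half = traj.checkpoint_at(traj.steps // 2)
    t_half = int(traj.checkpoints[i_half])
    t_end = int(traj.checkpoints[-1])
    if t_end == t_half:
        raise ValueError("degenerate checkpoint schedule")
    slope = (traj.y[-1] - traj.y[i_half]) / (t_end - t_half)
    at_clip = np.abs(traj.y[-1]) >= 0.99 * Y_CLIP
    sat_tol = sat_transitions / max(traj.steps - traj.burnin, 1)
    saturated = np.abs(traj.flux_mean_post) >= 1.0 - sat_tol
    labels = []
    for i in range(slope.size):
        if abs(slope[i]) > eps_slope or at_clip[i] or saturated[i]:
            direction = slope[i] if abs(slope[i]) > eps_slope else traj.y[-1, i]
            labels.append(
                UNIDIRECTIONAL_FORWARD if direction > 0 else UNIDIRECTIONAL_REVERSE
            )
        else:
            labels.append(BIDIRECTIONAL)
    n_uni = sum(lab != BIDIRECTIONAL for lab in labels)
    return ReactionClassification(
        labels=labels, slope=slope, phi=n_uni / slope.size
    )


def deltaG_from_y(
    traj: TrajectoryRecord,
    gas_constant: float = 8.314,
    temperature: float = 310.0,
) -> np.ndarray:
    """Gibbs-energy estimate per reaction from the final accumulators:
    DeltaG_i = -2 R T y_i, consistent with P(+)/P(-) = exp(-DeltaG/(R T))."""
    return -2.0 * gas_constant * temperature * traj.y_final
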