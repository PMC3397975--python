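"""Random-network ensembles and the ergodicity-breaking phase transition.

Networks are drawn with i.i.d. stoichiometric coefficients
``xi[mu, i] = +-1`` each with probability ``p/2`` (0 otherwise), unit
reference concentrations and flux bounds, and boundary intakes ``u = b0``
assigned to each species independently with probability ``q``.  Running the
stochastic dynamics on such a reactor and averaging over realizations at a
fixed reaction-to-species ratio ``n = N / M`` yields one :class:`PhasePoint`
of the phase diagram:

* small n: too few reactions to balance every species — the stationary
  per-species H stays positive, most reactions freeze (phi -> 1), and the
  dynamics is ergodic;
* large n: the balanced set H = 0 is under-constrained — H vanishes, more
  than M reactions remain bidirectional, and different initial conditions
  reach different steady states (ergodicity breaking).

The critical ratio is marked both by the vanishing of <H> and by the point
where the number of bidirectional reactions per species, n * (1 - phi),
crosses 1; the two estimates agree within grid resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coupling import residual_form
from .dynamics import classify_reactions, estimate_fluxes, simulate
from .netio import ReactionNetwork, ReactionRecord, SpeciesRecord

__all__ = [
    "EnsembleSpec",
    "PhasePoint",
    "CriticalPointEstimate",
    "sample_random_network",
    "run_phase_point",
    "phase_sweep",
    "estimate_critical_point",
    "BIASED_Y0",
]

BIASED_Y0 = 5.0   # strongly polarized start (tanh(5) ~ 0.9999) for the
                  # ergodicity probe


@dataclass
class EnsembleSpec:
    """Study conditions for one ensemble experiment.

    Defaults are the scaled-down reference conditions used throughout the
    package: M = 50 species, coefficient density p = 0.25, boundary-species
    probability q = 0.5 with intake magnitude b0 = 1, T = 2e4 dynamics steps
    and 20 realizations per phase point.  ``reps=200`` reproduces the
    full-scale averaging protocol.
    """

    M: int = 50
    p: float = 0.25
    q: float = 0.5
    b0: float = 1.0
    reps: int = 20
    steps: int = 20_000
    eta: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must be in [0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class PhasePoint:
    """Ensemble-averaged order parameters at one ratio n = N / M."""

    n: float
    H_mean: float          # <H(nu_hat)> / M, per-species normalization
    H_se: float
    phi: float             # mean fraction of unidirectional reactions
    phi_se: float
    init: str = "unbiased"
    reps: int = 0

    @property
    def nbid(self) -> float:
        """Mean number of bidirectional reactions per species."""
        return self.n * (1.0 - self.phi)


def sample_random_network(
    spec: EnsembleSpec, n: float, seed=None
) -> ReactionNetwork:
    """Draw one random reactor at ratio n = N / M (N rounded to nearest
    integer, at least 1).  Reactions drawn with an all-zero coefficient
    vector are resampled."""
    rng = np.random.default_rng(seed)
    M = spec.M
    N = max(1, round(n * M))
    # xi: 0 w.p. 1-p, +-1 w.p. p/2 each
    xi = np.zeros((M, N))
    nonzero = rng.random((M, N)) < spec.p
    signs = np.where(rng.random((M, N)) < 0.5, 1.0, -1.0)
    xi[nonzero] = signs[nonzero]
    empty = np.flatnonzero(~np.any(xi != 0.0, axis=0))
    while empty.size:
        nz = rng.random((M, empty.size)) < spec.p
        sg = np.where(rng.random((M, empty.size)) < 0.5, 1.0, -1.0)
        xi[:, empty] = np.where(nz, sg, 0.0)
        empty = empty[~np.any(xi[:, empty] != 0.0, axis=0)]
    boundary = rng.random(M) < spec.q
    species = [
        SpeciesRecord(
            id=f"S{mu}",
            cbar=1.0,
            u=spec.b0 if boundary[mu] else 0.0,
            is_boundary=bool(boundary[mu]),
        )
        for mu in range(M)
    ]
    reactions = [
        ReactionRecord(
            id=f"R{i}",
            stoich={f"S{mu}": xi[mu, i] for mu in np.flatnonzero(xi[:, i])},
            qmax=1.0,
        )
        for i in range(N)
    ]
    return ReactionNetwork(species=species, reactions=reactions)


def _run_one(net: ReactionNetwork, spec: EnsembleSpec, y0, seed):
    traj = simulate(net, spec.steps, eta=spec.eta, y0=y0, seed=seed)
    nu_hat = estimate_fluxes(traj, net)
    cls = classify_reactions(traj)
    H_per_species = residual_form(net, nu_hat) / net.M
    return nu_hat, cls, H_per_species


def run_phase_point(
    spec: EnsembleSpec,
    n: float,
    init: str = "unbiased",
    seed=None,
) -> PhasePoint:
    """Simulate ``spec.reps`` independent realizations at ratio n and
    aggregate the order parameters.

    ``init="unbiased"`` starts every accumulator at y = 0 (equilibrium
    start); ``init="biased"`` starts at y = +5 (strongly polarized start),
    used to probe ergodicity.
    """
    if init not in ("unbiased", "biased"):
        raise ValueError(f"unknown init {init!r}")
    y0 = 0.0 if init == "unbiased" else BIASED_Y0
    if isinstance(seed, np.random.SeedSequence):
        # copy so spawning here never mutates the caller's sequence: repeated
        # calls with the same sequence (e.g. unbiased vs biased curves) get
        # identical realization seeds — the comparison is paired
        ss = np.random.SeedSequence(seed.entropy, spawn_key=seed.spawn_key)
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * spec.reps)
    H_vals = np.empty(spec.reps)
    phi_vals = np.empty(spec.reps)
    for rep in range(spec.reps):
        try:
            net = sample_random_network(spec, n, seed=children[2 * rep])
            _, cls, Hs = _run_one(net, spec, y0, children[2 * rep + 1])
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"realization {rep} at n={n} failed") from exc
        H_vals[rep] = Hs
        phi_vals[rep] = cls.phi
    sqrt_r = math.sqrt(spec.reps)
    return PhasePoint(
        n=n,
        H_mean=float(H_vals.mean()),
        H_se=float(H_vals.std(ddof=1) / sqrt_r) if spec.reps > 1 else 0.0,
        phi=float(phi_vals.mean()),
        phi_se=float(phi_vals.std(ddof=1) / sqrt_r) if spec.reps > 1 else 0.0,
        init=init,
        reps=spec.reps,
    )


def phase_sweep(
    spec: EnsembleSpec,
    n_grid,
    seed=None,
    inits: tuple[str, ...] = ("unbiased", "biased"),
) -> dict[str, list[PhasePoint]]:
    """Sweep the ratio grid for each initial condition.

    Realization seeds are paired across initial conditions (same master seed
    per grid point), so the unbiased/biased comparison runs on identical
    network ensembles, isolating the initial-condition effect.
    """
    n_grid = list(n_grid)
    if len(n_grid) < 3:
        raise ValueError("n_grid must have at least 3 points")
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be sorted strictly increasing")
    ss = np.random.SeedSequence(seed)
    point_seeds = ss.spawn(len(n_grid))
    out: dict[str, list[PhasePoint]] = {}
    for init in inits:
        out[init] = [
            run_phase_point(spec, n, init=init, seed=point_seeds[k])
            for k, n in enumerate(n_grid)
        ]
    return out


@dataclass
class CriticalPointEstimate:
    n_c_from_H: float | None       # first crossing of H_mean below eps_H
    n_c_from_nbid: float | None    # crossing of n (1 - phi) through 1
    grid_step: float               # resolution-level error bar
    bracketed_H: bool = True
    bracketed_nbid: bool = True


def _interp_crossing(x0, x1, y0, y1, target):
    if y1 == y0:
        return 0.5 * (x0 + x1)
    return x0 + (target - y0) * (x1 - x0) / (y1 - y0)


def estimate_critical_point(
    points: list[PhasePoint], eps_H: float = 1e-2
) -> CriticalPointEstimate:
    """Locate the transition from one phase curve (single init condition).

    ``n_c_from_H``: first grid interval where H_mean falls below eps_H
    (linear interpolation).  ``n_c_from_nbid``: interpolated crossing of the
    bidirectional count per species through 1 (requires a monotonically
    ordered grid; raises on shuffled input).
    """
    ns = [pt.n for pt in points]
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError("phase points must be sorted by strictly increasing n")
    if len(points) < 2:
        raise ValueError("need at least 2 phase points")
    steps = [b - a for a, b in zip(ns, ns[1:])]
    grid_step = max(steps)

    H = [pt.H_mean for pt in points]
    n_c_H, brack_H = None, False
    if H[0] >= eps_H:
        for k in range(len(points) - 1):
            if H[k] >= eps_H > H[k + 1]:
                n_c_H = _interp_crossing(ns[k], ns[k + 1], H[k], H[k + 1], eps_H)
                brack_H = True
                break

    nb = [pt.nbid for pt in points]
    n_c_nb, brack_nb = None, False
    if nb[0] < 1.0:
        for k in range(len(points) - 1):
            if nb[k] < 1.0 <= nb[k + 1]:
                n_c_nb = _interp_crossing(ns[k], ns[k + 1], nb[k], nb[k + 1], 1.0)
                brack_nb = True
                break

    return CriticalPointEstimate(
        n_c_from_H=n_c_H,
        n_c_from_nbid=n_c_nb,
        grid_step=grid_step,
        bracketed_H=brack_H,
        bracketed_nbid=brack_nb,
    )
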