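"""Glucose partitioning in the human red blood cell (hRBC).

The packaged fixture is a reconstruction, from textbook stoichiometry, of
the standard reduced erythrocyte network: glycolysis, the 2,3-DPG
(Rapoport-Leubering) shunt and the pentose phosphate pathway — 21 pathway
reactions among 30 metabolites plus the ATPase (Na+/K+ pump) and NADPHase
(glutathione-reduction proxy) pumps, 23 reactions in all.  At steady state
(strict mass balance on the 25 intracellular metabolites) only three of the
23 fluxes are independent; the conventional free coordinates are the glucose
uptake ``u_glc``, the Rapoport-Leubering shunt flux ``u_dpgm`` and the
oxidative pentose-phosphate flux ``u_g6pdh``.

Every steady flux state changes the extracellular concentrations of five
species — GLC, LAC, K+, Na+ and CO2 — at rates linear in the free fluxes.
The variational function of the extracellular medium,

    H_ext = sum_s rate_s**2 / x_s        (x_s = blood concentration),

is quadratic in ``u_g6pdh`` at fixed (u_glc, u_dpgm); its minimizer has the
closed form  u_g6pdh* = a * u_glc + b * u_dpgm  with

    a = 6 (wL + wP) / (9 wC + wL + wP),   b = -3 wP / (9 wC + wL + wP),
    wL = 1/x_LAC,  wC = 1/x_CO2,  wP = 4/x_K + 9/x_Na.

When CO2 dominates the medium (wC -> 0, u_dpgm = 0) the optimum approaches
u_g6pdh = 6 u_glc: the pentose phosphate pathway consumes essentially all of
the glucose, the factor 6 reflecting the carbon stoichiometry of GLC and
CO2.  The glucose fraction routed through the PPP is F = u_g6pdh/(6 u_glc).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from .netio import ReactionNetwork, read_network

__all__ = [
    "RBCFreeFluxes",
    "RBCEnvironment",
    "FreeFluxBasis",
    "load_hrbc_network",
    "free_flux_basis",
    "exchange_rates",
    "extracellular_H",
    "optimal_g6pdh",
    "ppp_fraction",
    "ppp_fraction_bounds",
    "FREE_FLUX_REACTIONS",
    "EXCHANGE_SPECIES",
]

# sha256 of the packaged fixture tables; a mismatch means the fixture was
# edited without re-deriving the constants that depend on it.
_CHECKSUMS = {
    "hrbc_species.tsv": "13769fa566f75cd6dc3ba44607a0fd4de632c32cfeefd0641b5c38aeb39dc621",
    "hrbc_reactions.tsv": "a4726554b72932b82d8c6cf32ec6a63c020e029d768f0c2b56e5744a6ac7ffe5",
}

FREE_FLUX_REACTIONS = ("GLCtr", "DPGM", "G6PDH")
#: extracellular species tracked by the environment: network boundary id -> key
EXCHANGE_SPECIES = {"GLCX": "GLC", "LACX": "LAC", "KX": "K", "NAX": "NA", "CO2X": "CO2"}


@dataclass(frozen=True)
class RBCFreeFluxes:
    """The three independent fluxes of the reduced model (mol/L/s)."""

    u_glc: float
    u_dpgm: float = 0.0
    u_g6pdh: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.u_glc, self.u_dpgm, self.u_g6pdh])


@dataclass(frozen=True)
class RBCEnvironment:
    """Extracellular (blood) concentrations, mol/L.

    Defaults are typical venous blood values: GLC 5 mM, LAC 1 mM, K+ 4 mM,
    Na+ 140 mM, dissolved CO2 1.2 mM.
    """

    x: dict = field(
        default_factory=lambda: {
            "GLC": 5.0e-3,
            "LAC": 1.0e-3,
            "K": 4.0e-3,
            "NA": 1.4e-1,
            "CO2": 1.2e-3,
        }
    )

    def __post_init__(self) -> None:
        missing = {"GLC", "LAC", "K", "NA", "CO2"} - set(self.x)
        if missing:
            raise ValueError(f"environment missing species: {sorted(missing)}")
        for name, val in self.x.items():
            if not val > 0:
                raise ValueError(f"concentration {name} = {val!r} must be > 0")

    def weights(self) -> tuple[float, float, float]:
        """(wL, wC, wP) entering the closed-form optimum."""
        wL = 1.0 / self.x["LAC"]
        wC = 1.0 / self.x["CO2"]
        wP = 4.0 / self.x["K"] + 9.0 / self.x["NA"]
        return wL, wC, wP


def load_hrbc_network() -> ReactionNetwork:
    """Load the packaged reduced hRBC network (30 species, 23 reactions).

    The fixture is a reconstruction from textbook pathway stoichiometry (see
    module docstring); its tables are checksummed to guard the constants
    derived from them.
    """
    pkg = resources.files("nessflux.data")
    handles = {}
    for fname in ("hrbc_species.tsv", "hrbc_reactions.tsv"):
        data = (pkg / fname).read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != _CHECKSUMS[fname]:
            raise RuntimeError(
                f"fixture checksum mismatch for {fname}: {digest}"
            )
        handles[fname] = data.decode()
    import io

    return read_network(
        io.StringIO(handles["hrbc_species.tsv"]),
        io.StringIO(handles["hrbc_reactions.tsv"]),
    )


@dataclass
class FreeFluxBasis:
    """Linear map from the three free fluxes to the full 23-flux vector.

    ``matrix`` has shape (N, 3); columns correspond to unit u_glc, u_dpgm,
    u_g6pdh.  Mass balance on every intracellular metabolite holds
    identically for any input, and the designated coordinates of the output
    reproduce the inputs.
    """

    matrix: np.ndarray
    reaction_ids: list[str]

    def __call__(self, fluxes: RBCFreeFluxes) -> np.ndarray:
        return self.matrix @ fluxes.as_array()

    def flux(self, fluxes: RBCFreeFluxes, reaction_id: str) -> float:
        return float(self(fluxes)[self.reaction_ids.index(reaction_id)])


def free_flux_basis(net: ReactionNetwork | None = None) -> FreeFluxBasis:
    """Construct the free-flux parametrization of the steady-state set.

    The steady-state system (mass balance on intracellular species) has a
    three-dimensional null space; the basis is normalized so that the
    coordinates (GLCtr, DPGM, G6PDH) equal the inputs exactly.
    """
    if net is None:
        net = load_hrbc_network()
    S_int = net.internal_stoichiometric_matrix()
    _, sv, Vt = np.linalg.svd(S_int)
    smax = sv[0]
    rank = int(np.sum(sv > 1e-10 * smax))
    null_dim = net.N - rank
    if null_dim != 3:
        raise ValueError(
            f"fixture error: steady-state null space has dimension {null_dim}, "
            "expected 3"
        )
    B = Vt[rank:].T                                    # (N, 3)
    rids = net.reaction_ids
    idx = [rids.index(r) for r in FREE_FLUX_REACTIONS]
    T = B @ np.linalg.inv(B[idx, :])
    T[idx, :] = np.eye(3)                              # exact on the coordinates
    return FreeFluxBasis(matrix=T, reaction_ids=list(rids))


def exchange_rates(
    fluxes: RBCFreeFluxes,
    net: ReactionNetwork | None = None,
    basis: FreeFluxBasis | None = None,
) -> dict[str, float]:
    """Rates of change of the five extracellular species (mol/L/s per cell
    volume), linear in the free fluxes.

    GLC rate is -u_glc (all consumed glucose is drawn from the exterior);
    carbon is conserved: 6 * u_glc = 3 * LAC rate + CO2 rate identically.
    """
    if net is None:
        net = load_hrbc_network()
    if basis is None:
        basis = free_flux_basis(net)
    v = basis(fluxes)
    S = net.stoichiometric_matrix()
    idx = net.species_index()
    return {
        key: float(S[idx[sp], :] @ v) for sp, key in EXCHANGE_SPECIES.items()
    }


def extracellular_H(
    fluxes: RBCFreeFluxes,
    env: RBCEnvironment | None = None,
    net: ReactionNetwork | None = None,
    basis: FreeFluxBasis | None = None,
) -> float:
    """Variational function of the extracellular medium:
    sum over the five exchanged species of (rate)^2 / x_s."""
    if env is None:
        env = RBCEnvironment()
    rates = exchange_rates(fluxes, net=net, basis=basis)
    return float(sum(rates[k] ** 2 / env.x[k] for k in rates))


def _ab_coefficients(env: RBCEnvironment) -> tuple[float, float]:
    wL, wC, wP = env.weights()
    denom = 9.0 * wC + wL + wP
    if denom <= 0:
        raise ValueError("degenerate environment: zero quadratic coefficient")
    a = 6.0 * (wL + wP) / denom
    b = -3.0 * wP / denom
    return a, b


def optimal_g6pdh(
    u_glc: float,
    u_dpgm: float = 0.0,
    env: RBCEnvironment | None = None,
) -> tuple[float, float, float]:
    """Pentose-phosphate flux minimizing the extracellular H at fixed
    (u_glc, u_dpgm).

    Returns ``(u_g6pdh_star, a, b)`` with the closed form
    ``u_g6pdh_star = a * u_glc + b * u_dpgm``; a and b are rational
    functions of the blood concentrations (see module docstring) and are
    invariant under a common rescaling of all five concentrations.
    """
    if u_glc <= 0:
        raise ValueError("u_glc must be > 0")
    if env is None:
        env = RBCEnvironment()
    a, b = _ab_coefficients(env)
    return a * u_glc + b * u_dpgm, a, b


def optimal_g6pdh_numeric(
    u_glc: float,
    u_dpgm: float = 0.0,
    env: RBCEnvironment | None = None,
    net: ReactionNetwork | None = None,
    basis: FreeFluxBasis | None = None,
) -> float:
    """One-dimensional numeric minimization of the extracellular H over
    u_g6pdh (golden-section/Brent); independent oracle for the closed form."""
    if env is None:
        env = RBCEnvironment()
    if net is None:
        net = load_hrbc_network()
    if basis is None:
        basis = free_flux_basis(net)

    def objective(z: float) -> float:
        return extracellular_H(
            RBCFreeFluxes(u_glc, u_dpgm, z), env=env, net=net, basis=basis
        )

    span = 12.0 * abs(u_glc) + 6.0 * abs(u_dpgm) + 1e-12
    res = minimize_scalar(
        objective, bounds=(-span, span), method="bounded",
        options={"xatol": 1e-10 * span},
    )
    # H is exactly quadratic in z, so a three-point parabolic polish around
    # the bracketing minimum recovers the vertex to machine precision
    # (plain bracketing search stalls at ~sqrt(eps) relative accuracy).
    z, h = float(res.x), 1e-3 * span
    lo, mid, hi = objective(z - h), objective(z), objective(z + h)
    denom = lo - 2.0 * mid + hi
    if denom > 0:
        z = z + 0.5 * h * (lo - hi) / denom
    return z


def ppp_fraction(u_g6pdh: float, u_glc: float) -> tuple[float, bool]:
    """Fraction of glucose consumption routed through the PPP:
    F = u_g6pdh / (6 u_glc).

    Returns ``(F, clipped)``; ``clipped`` flags a raw value outside [0, 1]
    (F is reported clipped to the unit interval in that case).
    """
    if u_glc <= 0:
        raise ValueError("u_glc must be > 0")
    F = u_g6pdh / (6.0 * u_glc)
    clipped = not (0.0 <= F <= 1.0)
    return (min(max(F, 0.0), 1.0), clipped)


def ppp_fraction_bounds(
    env: RBCEnvironment | None = None,
) -> tuple[float, float]:
    """Extremes of F over the admissible operating regime.

    At fixed glucose uptake the shunt flux u_dpgm ranges from 0 to its
    stoichiometric maximum (the point where the ATPase flux vanishes), with
    u_g6pdh at its optimal value throughout.  Since b < 0, F is maximal at
    u_dpgm = 0 (F_max = a / 6) and minimal at the shunt maximum
    (F_min = (a + 2 b) / (2 (3 + b))).  Always 0 <= F_min < F_max <= 1.
    """
    if env is None:
        env = RBCEnvironment()
    a, b = _ab_coefficients(env)
    F_max = a / 6.0
    F_min = (a + 2.0 * b) / (2.0 * (3.0 + b))
    return F_min, F_max
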