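import numpy as np
import pytest

from nessflux.netio import ReactionNetwork, ReactionRecord, SpeciesRecord


@pytest.fixture
def toy_m2() -> ReactionNetwork:
    """A -> B with supply of A and drain of B (u_A = +2, u_B = -2,
    cbar = (1, 2)); the balanced flux is nu = 2."""
    return ReactionNetwork(
        species=[
            SpeciesRecord("A", cbar=1.0, u=2.0, is_boundary=True),
            SpeciesRecord("B", cbar=2.0, u=-2.0, is_boundary=True),
        ],
        reactions=[ReactionRecord("R1", {"A": -1.0, "B": 1.0}, qmax=3.0)],
    )


@pytest.fixture
def toy_m2_bounded(toy_m2) -> ReactionNetwork:
    """Same reactor with the flux bound tightened to 1 (bound active)."""
    return ReactionNetwork(
        species=toy_m2.species,
        reactions=[ReactionRecord("R1", {"A": -1.0, "B": 1.0}, qmax=1.0)],
    )


@pytest.fixture
def cycle3() -> ReactionNetwork:
    """Closed 3-cycle A -> B -> C -> A (u = 0): a pure infeasible loop."""
    return ReactionNetwork(
        species=[SpeciesRecord(x) for x in "ABC"],
        reactions=[
            ReactionRecord("R1", {"A": -1.0, "B": 1.0}),
            ReactionRecord("R2", {"B": -1.0, "C": 1.0}),
            ReactionRecord("R3", {"C": -1.0, "A": 1.0}),
        ],
    )


@pytest.fixture
def chain() -> ReactionNetwork:
    """Driven linear chain A -> B -> C with supply of A and drain of C."""
    return ReactionNetwork(
        species=[
            SpeciesRecord("A", u=1.0, is_boundary=True),
            SpeciesRecord("B"),
            SpeciesRecord("C", u=-1.0, is_boundary=True),
        ],
        reactions=[
            ReactionRecord("R1", {"A": -1.0, "B": 1.0}),
            ReactionRecord("R2", {"B": -1.0, "C": 1.0}),
        ],
    )


def one_reaction_reactor(u0: float) -> ReactionNetwork:
    """Single species consumed by a single reaction, supplied at rate u0.

    Mean-field fixed point: tanh y* = u0 for |u0| < 1 (bidirectional,
    balanced); for |u0| > 1 the accumulator drifts and the reaction freezes
    forward with residual u0 - 1, i.e. H = (u0 - 1)**2.
    """
    return ReactionNetwork(
        species=[SpeciesRecord("A", cbar=1.0, u=u0, is_boundary=True)],
        reactions=[ReactionRecord("R1", {"A": -1.0})],
    )


@pytest.fixture(scope="session")
def hrbc_net():
    from nessflux.hrbc import load_hrbc_network

    return load_hrbc_network()


def random_network(rng: np.random.Generator, M=None, N=None,
                   boundary_prob=0.5, coeff_density=0.4) -> ReactionNetwork:
    """Small random network with generic concentrations and uptakes (used by
    property tests; distinct from the standard +-1 ensemble)."""
    M = M if M is not None else int(rng.integers(2, 7))
    N = N if N is not None else int(rng.integers(1, 6))
    species = []
    for mu in range(M):
        boundary = rng.random() < boundary_prob
        species.append(
            SpeciesRecord(
                id=f"S{mu}",
                cbar=float(rng.uniform(0.2, 3.0)),
                u=float(rng.normal(0, 1.5)) if boundary else 0.0,
                is_boundary=boundary,
            )
        )
    reactions = []
    for i in range(N):
        stoich = {}
        while not stoich:
            for mu in range(M):
                if rng.random() < coeff_density:
                    coef = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
                    stoich[f"S{mu}"] = coef
        reactions.append(
            ReactionRecord(id=f"R{i}", stoich=stoich, qmax=float(rng.uniform(0.5, 3.0)))
        )
    return ReactionNetwork(species=species, reactions=reactions)
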