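"""Reaction-network domain types and plain-text (TSV) input/output.

A :class:`ReactionNetwork` is the single source of truth consumed by every
other module: an ordered list of chemical species with reference (steady)
concentrations ``cbar`` and boundary exchange rates ``u``, plus an ordered
list of reactions given by sparse signed stoichiometries and a flux bound
``qmax``.

Sign conventions
----------------
* Stoichiometric coefficients: negative = substrate, positive = product, in
  the forward direction of the reaction as written.
* ``u > 0`` means net intake of the species into the reactor, so the
  stationary mass balance for species ``mu`` reads
  ``sum_i xi[mu, i] * nu_i + u[mu] = 0``.
* Reverse operation of a reaction is a negative flux ``nu_i``.

File format
-----------
Species table (TSV, ``#`` comments allowed)::

    id<TAB>cbar<TAB>u<TAB>is_boundary

Reactions table::

    id<TAB>formula<TAB>qmax

Formulas use ``coef id + ... -> coef id + ...`` with optional integer or
float coefficients (default 1). One side may be empty, denoting exchange
with the exterior (e.g. ``GLCX ->`` for a pure drain).
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesRecord",
    "ReactionRecord",
    "ReactionNetwork",
    "NetworkFormatError",
    "Diagnostic",
    "parse_reaction_formula",
    "format_reaction_formula",
    "read_network",
    "write_network",
    "validate_network",
]


class NetworkFormatError(ValueError):
    """Malformed network file or reaction formula."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One chemical species.

    Parameters
    ----------
    id : short label.
    cbar : reference (steady) concentration, mol/L, strictly positive.
    u : boundary exchange rate, mol/L/s; positive = net intake.
    is_boundary : True iff ``u`` may be non-zero / the species is exchanged
        with (or belongs to) the exterior and its internal balance is not
        enforced by steady-state analyses.
    """

    id: str
    cbar: float = 1.0
    u: float = 0.0
    is_boundary: bool = False


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: sparse signed stoichiometry and a flux bound."""

    id: str
    stoich: Mapping[str, float]
    qmax: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoich", dict(self.stoich))


@dataclass
class ReactionNetwork:
    """Ordered species + reactions; ``volume`` and ``dt`` default to the
    dimensionless mode (V = dt = 1) used for ensemble work."""

    species: list[SpeciesRecord]
    reactions: list[ReactionRecord]
    volume: float = 1.0
    dt: float = 1.0

    # -- derived views -------------------------------------------------
    @property
    def M(self) -> int:
        return len(self.species)

    @property
    def N(self) -> int:
        return len(self.reactions)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self) -> dict[str, int]:
        return {s.id: k for k, s in enumerate(self.species)}

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense stoichiometric matrix, species-major: shape (M, N)."""
        S = np.zeros((self.M, self.N))
        idx = self.species_index()
        for i, rxn in enumerate(self.reactions):
            for sp, coef in rxn.stoich.items():
                S[idx[sp], i] = coef
        return S

    def cbar(self) -> np.ndarray:
        return np.array([s.cbar for s in self.species])

    def uptake(self) -> np.ndarray:
        return np.array([s.u for s in self.species])

    def qmax(self) -> np.ndarray:
        return np.array([r.qmax for r in self.reactions])

    def boundary_mask(self) -> np.ndarray:
        return np.array([s.is_boundary for s in self.species], dtype=bool)

    def internal_stoichiometric_matrix(self) -> np.ndarray:
        """Rows of the stoichiometric matrix for non-boundary species only."""
        return self.stoichiometric_matrix()[~self.boundary_mask()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and self.volume == other.volume
            and self.dt == other.dt
        )


# ---------------------------------------------------------------------------
# formula parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?([A-Za-z_]\w*)$")


def _parse_side(side: str, formula: str) -> dict[str, float]:
    side = side.strip()
    out: dict[str, float] = {}
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise NetworkFormatError(
                f"malformed formula {formula!r}: empty term near '+'"
            )
        m = _TOKEN_RE.match(term)
        if m is None:
            raise NetworkFormatError(
                f"malformed formula {formula!r}: cannot parse term {term!r}"
            )
        coef = float(m.group(1)) if m.group(1) else 1.0
        sp = m.group(2)
        out[sp] = out.get(sp, 0.0) + coef
    return out


def parse_reaction_formula(text: str) -> dict[str, float]:
    """Parse ``"a A + b B -> c C"`` into ``{A: -a, B: -b, C: +c}``.

    Left-hand species get negative coefficients (substrates), right-hand
    positive (products); duplicates are summed and net-zero species are
    dropped with a warning.
    """
    parts = text.split("->")
    if len(parts) != 2:
        raise NetworkFormatError(
            f"malformed formula {text!r}: expected exactly one '->'"
        )
    lhs = _parse_side(parts[0], text)
    rhs = _parse_side(parts[1], text)
    if not lhs and not rhs:
        raise NetworkFormatError(f"malformed formula {text!r}: no species")
    stoich: dict[str, float] = {}
    for sp, coef in lhs.items():
        stoich[sp] = stoich.get(sp, 0.0) - coef
    for sp, coef in rhs.items():
        stoich[sp] = stoich.get(sp, 0.0) + coef
    for sp in [s for s, c in stoich.items() if c == 0.0]:
        warnings.warn(
            f"species {sp!r} cancels to net zero in {text!r}; dropped",
            stacklevel=2,
        )
        del stoich[sp]
    return stoich


def format_reaction_formula(stoich: Mapping[str, float]) -> str:
    """Inverse of :func:`parse_reaction_formula` (up to term order)."""

    def side(items: Iterable[tuple[str, float]]) -> str:
        terms = []
        for sp, coef in items:
            coef = abs(coef)
            if coef == 1.0:
                terms.append(sp)
            elif coef == int(coef):
                terms.append(f"{int(coef)} {sp}")
            else:
                terms.append(f"{coef!r} {sp}")
        return " + ".join(terms)

    lhs = [(s, c) for s, c in stoich.items() if c < 0]
    rhs = [(s, c) for s, c in stoich.items() if c > 0]
    return f"{side(lhs)} -> {side(rhs)}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """Machine-readable validation finding."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def validate_network(net: ReactionNetwork) -> list[Diagnostic]:
    """Check all type invariants; returns an empty list iff the network is
    valid.  Diagnostics, not exceptions — callers decide severity."""
    diags: list[Diagnostic] = []
    seen: set[str] = set()
    for s in net.species:
        if s.id in seen:
            diags.append(Diagnostic("DUPLICATE_SPECIES", f"species {s.id!r} declared twice"))
        seen.add(s.id)
        if not (s.cbar > 0) or not math.isfinite(s.cbar):
            diags.append(Diagnostic("NONPOSITIVE_CBAR", f"species {s.id!r} has cbar={s.cbar!r}"))
        if not s.is_boundary and s.u != 0.0:
            diags.append(Diagnostic("BOUNDARY_FLAG", f"non-boundary species {s.id!r} has u={s.u!r}"))
    known = {s.id for s in net.species}
    rseen: set[str] = set()
    touched: set[str] = set()
    for r in net.reactions:
        if r.id in rseen:
            diags.append(Diagnostic("DUPLICATE_REACTION", f"reaction {r.id!r} declared twice"))
        rseen.add(r.id)
        if not r.stoich or all(c == 0.0 for c in r.stoich.values()):
            diags.append(Diagnostic("EMPTY_REACTION", f"reaction {r.id!r} has all-zero stoichiometry"))
        for sp, coef in r.stoich.items():
            if sp not in known:
                diags.append(Diagnostic("UNKNOWN_SPECIES", f"reaction {r.id!r} references undeclared species {sp!r}"))
            if coef == 0.0:
                diags.append(Diagnostic("ZERO_COEFFICIENT", f"reaction {r.id!r} stores zero coefficient for {sp!r}"))
            touched.add(sp)
        if not (r.qmax > 0):
            diags.append(Diagnostic("NONPOSITIVE_QMAX", f"reaction {r.id!r} has qmax={r.qmax!r}"))
    if net.M < 1:
        diags.append(Diagnostic("NO_SPECIES", "network declares no species"))
    if net.N < 1:
        diags.append(Diagnostic("NO_REACTIONS", "network declares no reactions"))
    for s in net.species:
        if s.u == 0.0 and s.id not in touched:
            diags.append(Diagnostic("ISOLATED_SPECIES", f"species {s.id!r} has u=0 and no reactions attached"))
    return diags


# ---------------------------------------------------------------------------
# TSV reader / writer
# ---------------------------------------------------------------------------

def _read_rows(path_or_buf, expected_header: Sequence[str], what: str) -> list[list[str]]:
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        text = Path(path_or_buf).read_text()
    rows: list[list[str]] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = [f.strip() for f in line.rstrip("\n").split("\t")]
        if not header_seen:
            if fields != list(expected_header):
                raise NetworkFormatError(
                    f"{what} table line {lineno}: expected header "
                    f"{list(expected_header)}, got {fields}"
                )
            header_seen = True
            continue
        if len(fields) != len(expected_header):
            raise NetworkFormatError(
                f"{what} table line {lineno}: expected {len(expected_header)} "
                f"columns, got {len(fields)}"
            )
        rows.append(fields)
    if not header_seen:
        raise NetworkFormatError(f"{what} table is empty (no header)")
    return rows


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def read_network(
    species_table,
    reactions_table,
    *,
    volume: float = 1.0,
    dt: float = 1.0,
    strict: bool = True,
) -> ReactionNetwork:
    """Read a network from the two TSV tables (paths or open text files).

    With ``strict`` (default), any validation diagnostic raises
    :class:`NetworkFormatError`.
    """
    species: list[SpeciesRecord] = []
    for fields in _read_rows(species_table, ("id", "cbar", "u", "is_boundary"), "species"):
        sid, cbar, u, isb = fields
        low = isb.lower()
        if low not in _TRUE | _FALSE:
            raise NetworkFormatError(f"species {sid!r}: bad is_boundary flag {isb!r}")
        species.append(
            SpeciesRecord(id=sid, cbar=float(cbar), u=float(u), is_boundary=low in _TRUE)
        )
    reactions: list[ReactionRecord] = []
    for fields in _read_rows(reactions_table, ("id", "formula", "qmax"), "reactions"):
        rid, formula, qmax = fields
        reactions.append(
            ReactionRecord(id=rid, stoich=parse_reaction_formula(formula), qmax=float(qmax))
        )
    net = ReactionNetwork(species=species, reactions=reactions, volume=volume, dt=dt)
    if strict:
        diags = validate_network(net)
        fatal = [d for d in diags if d.code != "ISOLATED_SPECIES"]
        if fatal:
            raise NetworkFormatError(
                "invalid network: " + "; ".join(str(d) for d in fatal)
            )
    return net


def write_network(net: ReactionNetwork, species_table, reactions_table) -> None:
    """Write the two TSV tables (paths or open text files)."""

    def _open(target):
        if hasattr(target, "write"):
            return target, False
        return open(target, "w"), True

    f, close = _open(species_table)
    try:
        f.write("id\tcbar\tu\tis_boundary\n")
        for s in net.species:
            f.write(f"{s.id}\t{s.cbar!r}\t{s.u!r}\t{str(s.is_boundary).lower()}\n")
    finally:
        if close:
            f.close()
    f, close = _open(reactions_table)
    try:
        f.write("id\tformula\tqmax\n")
        for r in net.reactions:
            f.write(f"{r.id}\t{format_reaction_formula(r.stoich)}\t{r.qmax!r}\n")
    finally:
        if close:
            f.close()


def network_roundtrip(net: ReactionNetwork) -> ReactionNetwork:
    """write -> read through in-memory buffers (used by property tests)."""
    sbuf, rbuf = io.StringIO(), io.StringIO()
    write_network(net, sbuf, rbuf)
    sbuf.seek(0)
    rbuf.seek(0)
    return read_network(sbuf, rbuf, volume=net.volume, dt=net.dt, strict=False)
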