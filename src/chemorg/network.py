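"""Reaction-network data model and plain-text ``.rn`` reaction-list I/O.

A reaction network is a pair of an ordered species list and an ordered
reaction list.  Each reaction has a reactant multiset, a product multiset
and a mass-action rate constant.  Networks are read from and written to a
line-oriented text format::

    # comment
    species: KinU KinA A I        # optional explicit species order
    KinU -> KinA ; 0.01 ; attachment
    A + KinU -> KinU + I ; 1.0
    2 A -> B ; 0.5                # prefix integers or repetition for coefficients
    O-Mad2 -> ; 0.01              # empty right-hand side: decay
    -> A ; 0.1                    # empty left-hand side: inflow

Species names may contain ``:``, ``/`` and ``-`` (protein-complex names such
as ``APC/C:Cdc20:BubR1:Bub3``) but no whitespace, ``+``, ``;`` or ``->``.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "NetworkFormatError",
    "parse_network",
    "write_network",
    "stoichiometric_matrix",
    "restrict",
    "load_fixture",
    "FIXTURE_NAMES",
]


class NetworkFormatError(ValueError):
    """Raised for malformed ``.rn`` documents (carries the line number)."""


_INT_RE = re.compile(r"^\d+$")
_FORBIDDEN_IN_NAME = re.compile(r"[\s+;]|->")


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``reactants`` and ``products`` map species name -> positive integer
    stoichiometric coefficient; ``rate_constant`` is the per-time-unit
    kinetic constant (lambda_r).
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ValueError(f"reaction {self.id!r}: both sides empty")
        if self.rate_constant <= 0:
            raise ValueError(f"reaction {self.id!r}: rate must be positive")
        for name, coeff in self.reactants + self.products:
            if coeff <= 0:
                raise ValueError(f"reaction {self.id!r}: non-positive coefficient for {name}")

    @property
    def reactant_counts(self) -> Counter:
        return Counter(dict(self.reactants))

    @property
    def product_counts(self) -> Counter:
        return Counter(dict(self.products))

    @property
    def reactant_species(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.reactants)

    @property
    def product_species(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.products)


@dataclass
class ReactionNetwork:
    """Ordered species list plus ordered reaction list."""

    species: list[str]
    reactions: list[Reaction]
    name: str = ""
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        for s in self.species:
            if not s or _FORBIDDEN_IN_NAME.search(s):
                raise ValueError(f"illegal species name {s!r}")
        declared = set(self.species)
        for r in self.reactions:
            for n in r.reactant_species | r.product_species:
                if n not in declared:
                    raise ValueError(f"reaction {r.id!r} references undeclared species {n!r}")
        self._index = {s: i for i, s in enumerate(self.species)}

    def species_index(self, name: str) -> int:
        return self._index[name]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions


def _parse_side(text: str, lineno: int) -> tuple[tuple[str, int], ...]:
    counts: Counter = Counter()
    text = text.strip()
    if not text:
        return ()
    for chunk in text.split("+"):
        tokens = chunk.split()
        if not tokens:
            raise NetworkFormatError(f"line {lineno}: empty term between '+' signs")
        if _INT_RE.match(tokens[0]):
            if len(tokens) != 2:
                raise NetworkFormatError(
                    f"line {lineno}: coefficient must be followed by exactly one species"
                )
            counts[tokens[1]] += int(tokens[0])
        else:
            for tok in tokens:
                counts[tok] += 1
    return tuple(sorted(counts.items()))


def parse_network(text: str, name: str = "") -> ReactionNetwork:
    """Parse a ``.rn`` reaction-list document into a :class:`ReactionNetwork`.

    Species order is declaration order (from ``species:`` lines) followed by
    first appearance in reaction lines.  Reactions without an explicit id get
    ``r1``, ``r2``, ... by position.
    """
    species: list[str] = []
    seen: set[str] = set()
    reactions: list[Reaction] = []
    used_ids: set[str] = set()

    def add_species(n: str, lineno: int) -> None:
        if not n or _FORBIDDEN_IN_NAME.search(n):
            raise NetworkFormatError(f"line {lineno}: illegal species name {n!r}")
        if n not in seen:
            seen.add(n)
            species.append(n)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species:"):
            for n in line[len("species:"):].split():
                add_species(n, lineno)
            continue
        if "->" not in line:
            raise NetworkFormatError(f"line {lineno}: missing '->'")
        head, *meta = [p.strip() for p in line.split(";")]
        if not meta:
            raise NetworkFormatError(f"line {lineno}: missing '; rate'")
        lhs_text, sep, rhs_text = head.partition("->")
        if "->" in rhs_text:
            raise NetworkFormatError(f"line {lineno}: more than one '->'")
        try:
            rate = float(meta[0])
        except ValueError:
            raise NetworkFormatError(f"line {lineno}: unreadable rate {meta[0]!r}") from None
        if rate <= 0:
            raise NetworkFormatError(f"line {lineno}: rate must be positive, got {rate}")
        rid = meta[1] if len(meta) > 1 and meta[1] else f"r{len(reactions) + 1}"
        if rid in used_ids:
            raise NetworkFormatError(f"line {lineno}: duplicate reaction id {rid!r}")
        used_ids.add(rid)
        reactants = _parse_side(lhs_text, lineno)
        products = _parse_side(rhs_text, lineno)
        if not reactants and not products:
            raise NetworkFormatError(f"line {lineno}: both sides empty")
        for n, _ in reactants + products:
            add_species(n, lineno)
        reactions.append(Reaction(rid, reactants, products, rate))

    return ReactionNetwork(species=species, reactions=reactions, name=name)


def _format_side(side: tuple[tuple[str, int], ...]) -> str:
    if not side:
        return ""
    return " + ".join(n if c == 1 else f"{c} {n}" for n, c in side)


def write_network(net: ReactionNetwork) -> str:
    """Serialise a network to the ``.rn`` text format (round-trip safe)."""
    lines = []
    if net.species:
        lines.append("species: " + " ".join(net.species))
    for r in net.reactions:
        lines.append(
            f"{_format_side(r.reactants)} -> {_format_side(r.products)} ; {r.rate_constant:g} ; {r.id}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Net-production matrix N with N[i, r] = products - reactants of species i in reaction r."""
    mat = np.zeros((len(net.species), len(net.reactions)), dtype=int)
    for j, r in enumerate(net.reactions):
        for n, c in r.reactants:
            mat[net.species_index(n), j] -= c
        for n, c in r.products:
            mat[net.species_index(n), j] += c
    return mat


def restrict(net: ReactionNetwork, removed_reaction_ids) -> ReactionNetwork:
    """Return a copy of the network without the listed reactions.

    The species list is unchanged; used to derive the short-timescale
    ("pro-metaphase") model variants in which kinetochore attachment (and,
    in the full model, O-Mad2 decay) is switched off.
    """
    removed = set(removed_reaction_ids)
    known = {r.id for r in net.reactions}
    unknown = removed - known
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    return ReactionNetwork(
        species=list(net.species),
        reactions=[r for r in net.reactions if r.id not in removed],
        name=f"{net.name}-restricted" if net.name else "",
    )


# ---------------------------------------------------------------------------
# Bundled spindle-assembly-checkpoint fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("model1", "model1b", "model2", "model2b", "model3", "model3b")


def _read_data(filename: str) -> str:
    return resources.files("chemorg.data").joinpath(filename).read_text(encoding="utf-8")


def load_fixture(name: str) -> ReactionNetwork:
    """Load one of the bundled SAC networks.

    ``model1`` is the full checkpoint network (14 species, 21 reactions),
    ``model2`` the lumped Promotor/Activator/Inhibitor network (7 species,
    9 reactions) and ``model3`` the coarsest network (4 species, 3
    reactions).  The ``b`` variants are the short-timescale networks with the
    attachment reaction (and O-Mad2 decay, for model1b) removed, per the
    removal manifest shipped next to the ``.rn`` files.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose one of {FIXTURE_NAMES}")
    base = name.rstrip("b")
    net = parse_network(_read_data(f"{base}.rn"), name=base)
    if name.endswith("b"):
        manifest = json.loads(_read_data("variants.json"))
        net = restrict(net, manifest[name]["remove"])
        net.name = name
    return net
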