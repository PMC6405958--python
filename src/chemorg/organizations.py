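"""Static chemical-organization analysis.

A species set A of a reaction network is *closed* when every reaction whose
reactants all lie in A produces only species of A, and *self-maintaining*
when a flux vector v exists with v_r >= 1 on every reaction fireable in A,
v_r = 0 elsewhere, and non-negative net production N v >= 0 of every species
of A.  Sets that are both are *organizations*: the only candidate species
combinations in which the mass-action dynamics can have fixed points or
other limit sets.  This module enumerates all organizations of a network,
arranges them in their Hasse diagram, and filters them with boolean
"interesting-organization" predicates over species presence.

Self-maintenance is decided by linear programming (scipy's HiGHS solver);
strict positivity v_r > 0 is encoded as v_r >= 1, which loses nothing
because the constraint system is homogeneous.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import ReactionNetwork, stoichiometric_matrix

__all__ = [
    "fireable",
    "directly_produced",
    "is_closed",
    "closure",
    "is_self_maintaining",
    "generate_self_maintaining",
    "generate_organization",
    "enumerate_organizations",
    "Organization",
    "OrgLattice",
    "InterestingPredicate",
    "parse_predicate",
    "filter_interesting",
    "PREDICATE_PRESETS",
    "lattice_to_json",
    "lattice_to_dot",
]

FEASIBILITY_TOL = 1e-9
DEFAULT_SPECIES_CAP = 25
# exhaustive closure-of-every-subset enumeration up to this many species,
# closure-driven upward exploration beyond
EXHAUSTIVE_LIMIT = 14


# ---------------------------------------------------------------------------
# Bitmask view of a network (speed: organization enumeration is subset-heavy)
# ---------------------------------------------------------------------------

class _Masks:
    def __init__(self, net: ReactionNetwork):
        idx = {s: i for i, s in enumerate(net.species)}
        self.n_species = len(net.species)
        self.full = (1 << self.n_species) - 1
        self.lhs = []
        self.rhs = []
        for r in net.reactions:
            lm = 0
            for s in r.reactant_species:
                lm |= 1 << idx[s]
            rm = 0
            for s in r.product_species:
                rm |= 1 << idx[s]
            self.lhs.append(lm)
            self.rhs.append(rm)
        self.index = idx
        self.names = list(net.species)
        self.N = stoichiometric_matrix(net)

    def to_mask(self, A) -> int:
        m = 0
        for s in A:
            if s not in self.index:
                raise KeyError(f"unknown species {s!r}")
            m |= 1 << self.index[s]
        return m

    def to_set(self, mask: int) -> frozenset[str]:
        return frozenset(n for i, n in enumerate(self.names) if mask >> i & 1)

    def fireable_mask(self, amask: int) -> list[int]:
        return [j for j, lm in enumerate(self.lhs) if lm & amask == lm]

    def dp_mask(self, amask: int) -> int:
        out = 0
        for j, lm in enumerate(self.lhs):
            if lm & amask == lm:
                out |= self.rhs[j]
        return out

    def closure_mask(self, bmask: int) -> int:
        cur = bmask
        while True:
            nxt = cur | self.dp_mask(cur)
            if nxt == cur:
                return cur
            cur = nxt


_mask_cache: dict[int, _Masks] = {}


def _masks(net: ReactionNetwork) -> _Masks:
    key = id(net)
    m = _mask_cache.get(key)
    if m is None or m.names != net.species or len(m.lhs) != len(net.reactions):
        m = _Masks(net)
        _mask_cache[key] = m
    return m


# ---------------------------------------------------------------------------
# Elementary set operations
# ---------------------------------------------------------------------------

def fireable(net: ReactionNetwork, A) -> list:
    """Reactions whose reactant species are all contained in A.

    Inflow reactions (empty left-hand side) are fireable in every set,
    including the empty one.
    """
    m = _masks(net)
    am = m.to_mask(A)
    return [net.reactions[j] for j in m.fireable_mask(am)]


def directly_produced(net: ReactionNetwork, A) -> frozenset[str]:
    """Union of the product species of all reactions fireable in A."""
    m = _masks(net)
    return m.to_set(m.dp_mask(m.to_mask(A)))


def is_closed(net: ReactionNetwork, A) -> bool:
    """True when no reaction fireable in A produces a species outside A."""
    m = _masks(net)
    am = m.to_mask(A)
    return m.dp_mask(am) & ~am == 0


def closure(net: ReactionNetwork, B) -> frozenset[str]:
    """Smallest closed superset of B (iterate direct production to a fixed point)."""
    m = _masks(net)
    return m.to_set(m.closure_mask(m.to_mask(B)))


# ---------------------------------------------------------------------------
# Self-maintenance (linear programming)
# ---------------------------------------------------------------------------

def _sm_feasible(m: _Masks, amask: int) -> tuple[bool, np.ndarray | None]:
    """Feasibility of {v >= 1 on fireable reactions, N_A v >= 0}.

    Rows are restricted to the species of A.  For closed A this is
    equivalent to constraining all species rows, because a reaction
    fireable in a closed set touches no outside species.
    """
    cols = m.fireable_mask(amask)
    if not cols:
        return True, np.zeros(len(m.lhs))
    rows = [i for i in range(m.n_species) if amask >> i & 1]
    sub = m.N[np.ix_(rows, cols)] if rows else np.zeros((0, len(cols)), dtype=int)
    res = linprog(
        c=np.zeros(len(cols)),
        A_ub=-sub,
        b_ub=np.zeros(len(rows)),
        bounds=[(1.0, None)] * len(cols),
        method="highs",
    )
    if not res.success:
        return False, None
    if rows and (sub @ res.x < -FEASIBILITY_TOL).any():
        return False, None
    v = np.zeros(len(m.lhs))
    v[cols] = res.x
    return True, v


def is_self_maintaining(net: ReactionNetwork, A) -> tuple[bool, np.ndarray | None]:
    """Decide self-maintenance of A; return (flag, flux witness or None).

    The witness is a full-length flux vector (indexed like
    ``net.reactions``) with entries >= 1 on reactions fireable in A and 0
    elsewhere, satisfying N v >= 0 on the rows of A.
    """
    m = _masks(net)
    return _sm_feasible(m, m.to_mask(A))


def _shrink_step(m: _Masks, amask: int) -> int:
    """One removal round of the self-maintaining-set generator.

    Solves max t s.t. (N v)_i >= t for species i of A, v >= 1 on fireable
    reactions, t <= 1.  If the optimum is negative, every species with
    negative net production at the optimum is removed.  Returns the new mask
    (== input when A is already self-maintaining).
    """
    cols = m.fireable_mask(amask)
    rows = [i for i in range(m.n_species) if amask >> i & 1]
    if not cols or not rows:
        return amask
    sub = m.N[np.ix_(rows, cols)]
    # variables: v (len cols) then t
    n = len(cols)
    A_ub = np.hstack([-sub, np.ones((len(rows), 1))])  # t - (Nv)_i <= 0
    b_ub = np.zeros(len(rows))
    res = linprog(
        c=np.concatenate([np.zeros(n), [-1.0]]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(1.0, None)] * n + [(None, 1.0)],
        method="highs",
    )
    if not res.success:  # pragma: no cover - bounded feasible LP cannot fail
        raise RuntimeError(f"self-maintenance LP failed: {res.message}")
    t = res.x[-1]
    if t >= -FEASIBILITY_TOL:
        return amask
    prod = sub @ res.x[:n]
    out = amask
    for i, p in zip(rows, prod):
        if p < -FEASIBILITY_TOL:
            out &= ~(1 << i)
    if out == amask:  # pragma: no cover - the minimum row attains t < 0
        raise RuntimeError("removal round made no progress")
    return out


def _generate_sm_mask(m: _Masks, amask: int) -> int:
    while True:
        nxt = _shrink_step(m, amask)
        if nxt == amask:
            return amask
        amask = nxt


def generate_self_maintaining(net: ReactionNetwork, A) -> frozenset[str]:
    """Self-maintaining subset of A by iterative removal.

    Each round maximises the worst-case net production over the remaining
    species (flux >= 1 on currently fireable reactions) and drops every
    species that is strictly consumed at the optimum; fireable reactions are
    recomputed and the rounds repeat until nothing is removed.  A
    self-maintaining input is returned unchanged.
    """
    m = _masks(net)
    return m.to_set(_generate_sm_mask(m, m.to_mask(A)))


# ---------------------------------------------------------------------------
# Organizations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Organization:
    """A closed and self-maintaining species set with its LP flux witness."""

    members: frozenset[str]
    flux_witness: tuple[float, ...]
    closed: bool = True
    self_maintaining: bool = True
    consistent_fixed_point: bool = True

    def __contains__(self, species: str) -> bool:
        return species in self.members

    def __len__(self) -> int:
        return len(self.members)


def _org_sort_key(members: frozenset[str]):
    return (len(members), tuple(sorted(members)))


def generate_organization(net: ReactionNetwork, B) -> Organization:
    """Organization generated by B: alternate closure and self-maintaining
    generation until the set is a fixed point of both.

    In consistent networks this equals the single pass G_SM(G_CL(B)); when
    the alternation has to run further (the self-maintaining shrink of a
    closed set need not itself be closed), ``consistent_fixed_point`` is
    False on the result to flag that uniqueness is not guaranteed.
    """
    m = _masks(net)
    cur = m.closure_mask(m.to_mask(B))
    single_pass = _generate_sm_mask(m, cur)
    cur = single_pass
    while True:
        cl = m.closure_mask(cur)
        sm = _generate_sm_mask(m, cl)
        if sm == cur:
            break
        cur = sm
    ok, witness = _sm_feasible(m, cur)
    assert ok and m.dp_mask(cur) & ~cur == 0
    return Organization(
        members=m.to_set(cur),
        flux_witness=tuple(witness),
        consistent_fixed_point=(cur == single_pass),
    )


@dataclass
class OrgLattice:
    """All organizations of a network plus the Hasse cover edges."""

    network: ReactionNetwork
    organizations: list[Organization]
    cover_edges: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.organizations)

    def member_sets(self) -> list[frozenset[str]]:
        return [o.members for o in self.organizations]


def _hasse_edges(sets: list[frozenset[str]]) -> list[tuple[int, int]]:
    edges = []
    for i, small in enumerate(sets):
        for j, large in enumerate(sets):
            if small >= large or not small < large:
                continue
            if any(small < mid < large for mid in sets):
                continue
            edges.append((i, j))
    return sorted(edges)


def _closed_masks_exhaustive(m: _Masks) -> set[int]:
    return {m.closure_mask(s) for s in range(1 << m.n_species)}


def _closed_masks_upward(m: _Masks) -> set[int]:
    # closures form a closure system: every closed set is reached from
    # closure(empty) by adding one species at a time and re-closing
    start = m.closure_mask(0)
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for cm in frontier:
            for i in range(m.n_species):
                if cm >> i & 1:
                    continue
                c2 = m.closure_mask(cm | 1 << i)
                if c2 not in seen:
                    seen.add(c2)
                    nxt.append(c2)
        frontier = nxt
    return seen


def enumerate_organizations(
    net: ReactionNetwork,
    species_cap: int = DEFAULT_SPECIES_CAP,
    strategy: str = "auto",
) -> OrgLattice:
    """Enumerate every organization of the network, with Hasse cover edges.

    ``strategy`` is ``"auto"`` (exhaustive closures of all subsets up to 14
    species, upward exploration beyond), ``"exhaustive"`` or ``"upward"``.
    Output order is deterministic: by size, then lexicographic.
    """
    if len(net.species) > species_cap:
        raise ValueError(
            f"{len(net.species)} species exceeds the enumeration cap {species_cap}"
        )
    m = _masks(net)
    if strategy == "auto":
        strategy = "exhaustive" if m.n_species <= EXHAUSTIVE_LIMIT else "upward"
    if strategy == "exhaustive":
        closed = _closed_masks_exhaustive(m)
    elif strategy == "upward":
        closed = _closed_masks_upward(m)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    orgs = []
    for cm in closed:
        ok, witness = _sm_feasible(m, cm)
        if ok:
            orgs.append(Organization(members=m.to_set(cm), flux_witness=tuple(witness)))
    orgs.sort(key=lambda o: _org_sort_key(o.members))
    edges = _hasse_edges([o.members for o in orgs])
    return OrgLattice(network=net, organizations=orgs, cover_edges=edges)


# ---------------------------------------------------------------------------
# Interesting-organization predicates
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|AND\b|OR\b|[^\s()]+)")


@dataclass(frozen=True)
class InterestingPredicate:
    """Boolean species-presence formula: atoms joined by AND/OR with parentheses."""

    expression: str
    _ast: tuple = field(repr=False, compare=False, default=())

    def atoms(self) -> frozenset[str]:
        out = set()

        def walk(node):
            if node[0] == "atom":
                out.add(node[1])
            else:
                for child in node[1:]:
                    walk(child)

        walk(self._ast)
        return frozenset(out)

    def evaluate(self, members) -> bool:
        present = set(members)

        def walk(node) -> bool:
            kind = node[0]
            if kind == "atom":
                return node[1] in present
            if kind == "and":
                return all(walk(c) for c in node[1:])
            return any(walk(c) for c in node[1:])

        return walk(self._ast)

    def __call__(self, members) -> bool:
        return self.evaluate(members)


class PredicateSyntaxError(ValueError):
    pass


def _tokenize(text: str):
    pos = 0
    tokens = []
    while pos < len(text):
        mobj = _TOKEN_RE.match(text, pos)
        if not mobj:
            break
        tokens.append((mobj.group(1), mobj.start(1)))
        pos = mobj.end()
    return tokens


def parse_predicate(text: str, net: ReactionNetwork | None = None) -> InterestingPredicate:
    """Parse ``expr := term (OR term)*; term := factor (AND factor)*;
    factor := species | '(' expr ')'``.  Species atoms are case-sensitive;
    when a network is given, unknown atoms are rejected with their position.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def expr():
        nonlocal pos
        terms = [term()]
        while peek() == "OR":
            pos += 1
            terms.append(term())
        return terms[0] if len(terms) == 1 else ("or", *terms)

    def term():
        nonlocal pos
        factors = [factor()]
        while peek() == "AND":
            pos += 1
            factors.append(factor())
        return factors[0] if len(factors) == 1 else ("and", *factors)

    def factor():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise PredicateSyntaxError(f"unexpected end of predicate: {text!r}")
        if tok == "(":
            pos += 1
            node = expr()
            if peek() != ")":
                raise PredicateSyntaxError(f"missing ')' in predicate at offset {tokens[pos - 1][1]}")
            pos += 1
            return node
        if tok in (")", "AND", "OR"):
            raise PredicateSyntaxError(
                f"unexpected {tok!r} at offset {tokens[pos][1]} in {text!r}"
            )
        pos += 1
        name, offset = tokens[pos - 1]
        if net is not None and name not in net.species:
            raise PredicateSyntaxError(f"unknown species {name!r} at offset {offset}")
        return ("atom", name)

    ast = expr()
    if pos != len(tokens):
        raise PredicateSyntaxError(
            f"trailing input at offset {tokens[pos][1]} in {text!r}"
        )
    return InterestingPredicate(expression=text, _ast=ast)


# The paper-model "interesting organization" conditions: an organization must
# contain a kinetochore in some form, plus (for the finer models) the
# regulator proteins in bound or unbound form.
PREDICATE_PRESETS: dict[str, str] = {
    "model1": (
        "(KinA OR KinU) AND "
        "(Cdc20 OR Cdc20:C-Mad2 OR MCC OR Cdc20:BubR1:Bub3 OR APC/C:Cdc20 OR APC/C:MCC OR "
        "APC/C:Cdc20:C-Mad2 OR APC/C:Cdc20:BubR1:Bub3) AND "
        "(BubR1:Bub3 OR MCC OR Cdc20:BubR1:Bub3 OR APC/C:MCC OR APC/C:Cdc20:BubR1:Bub3)"
    ),
    "model2": (
        "(KinA OR KinU) AND (Activator OR Inhibitor) AND "
        "(Promotor OR Promotor_A OR Promotor_I)"
    ),
    "model3": "(KinA OR KinU) AND (Activator OR Inhibitor)",
}


def filter_interesting(lattice: OrgLattice, pred: InterestingPredicate) -> list[Organization]:
    """Organizations of the lattice whose member set satisfies the predicate,
    in lattice order."""
    unknown = pred.atoms() - set(lattice.network.species)
    if unknown:
        raise KeyError(f"predicate references unknown species: {sorted(unknown)}")
    return [o for o in lattice.organizations if pred(o.members)]


# ---------------------------------------------------------------------------
# Lattice export
# ---------------------------------------------------------------------------

def lattice_to_json(lattice: OrgLattice) -> str:
    payload = {
        "network": lattice.network.name,
        "organizations": [sorted(o.members) for o in lattice.organizations],
        "cover_edges": [list(e) for e in lattice.cover_edges],
    }
    return json.dumps(payload, indent=2)


def lattice_to_dot(lattice: OrgLattice, highlight: list[int] | None = None) -> str:
    """Hasse diagram in Graphviz DOT form (smaller organizations at the bottom)."""
    hi = set(highlight or [])
    lines = ["digraph organizations {", "  rankdir=BT;", "  node [shape=box];"]
    for i, o in enumerate(lattice.organizations):
        label = "{" + ", ".join(sorted(o.members)) + "}" if o.members else "{}"
        style = ' style=filled fillcolor="palegreen"' if i in hi else ""
        lines.append(f'  n{i} [label="{label}"{style}];')
    for a, b in lattice.cover_edges:
        lines.append(f"  n{a} -> n{b};")
    lines.append("}")
    return "\n".join(lines) + "\n"
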