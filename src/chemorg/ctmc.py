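"""Bounded-population continuous-time Markov chain analysis of reaction networks.

A reaction network with a molecule cap N_max induces a finite CTMC whose
states are all population count vectors q with sum(q) <= N_max and whose
transition rates follow stochastic mass action
(rate_r(q) = lambda_r * prod_{s in LHS(r)} q(s) for unit stoichiometry,
falling factorials in general).  The chain's strongly connected components
link the dynamics back to chemical organizations:

* a bottom SCC (no outgoing transition) always has a closed species
  footprint that is a *discrete organization*;
* a non-bottom SCC is "good" when every reaction whose reactants are
  present somewhere in the component actually fires inside it, and a good
  SCC with a closed footprint is again a discrete organization, its states
  being the internal generators.

The module also lumps states by their present-species set phi(q), computes
expected block leaving times (first-passage linear systems) and inter-block
jump probabilities — the organization-level coarse-grained Markov chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import ReactionNetwork

__all__ = [
    "CTMC",
    "build_ctmc",
    "SCCDecomposition",
    "scc_decomposition",
    "good_sccs",
    "DiscreteOrganization",
    "discrete_organizations",
    "is_internal_generator",
    "SearchBudgetExceeded",
    "lump_by_phi",
    "expected_leaving_time",
    "block_transition_probabilities",
    "CoarseChain",
    "state_graph_to_dot",
    "coarse_chain_to_json",
]

DEFAULT_STATE_CAP = 2_000_000
PROB_TOL = 1e-9
DENSE_LIMIT = 20_000


def _enumerate_states(n_species: int, n_max: int):
    """All count vectors with total <= n_max, in lexicographic order."""
    states = []

    def rec(prefix, remaining):
        if len(prefix) == n_species:
            states.append(tuple(prefix))
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c)

    rec([], n_max)
    states.sort()
    return states


def _propensity(rate_constant: float, reactant_counts, q) -> float:
    """Stochastic mass-action propensity; falling factorial per reactant."""
    a = rate_constant
    for idx, coeff in reactant_counts:
        n = q[idx]
        if n < coeff:
            return 0.0
        for k in range(coeff):
            a *= n - k
    return a


@dataclass
class CTMC:
    """Explicit bounded-population chain for a reaction network."""

    network: ReactionNetwork
    n_max: int
    states: list[tuple[int, ...]]
    index: dict[tuple[int, ...], int] = field(repr=False)
    # transitions[i] = list of (target index, reaction index, rate)
    transitions: list[list[tuple[int, int, float]]] = field(repr=False)
    initial: tuple[int, ...] | None = None

    def __len__(self) -> int:
        return len(self.states)

    def phi(self, i: int) -> frozenset[str]:
        """Present-species set of state i."""
        q = self.states[i]
        return frozenset(s for s, c in zip(self.network.species, q) if c > 0)

    def rate_matrix(self) -> sp.csr_matrix:
        """Off-diagonal transition rate matrix (rates summed per state pair)."""
        rows, cols, vals = [], [], []
        for i, outs in enumerate(self.transitions):
            acc: dict[int, float] = {}
            for j, _, rate in outs:
                acc[j] = acc.get(j, 0.0) + rate
            for j, rate in acc.items():
                rows.append(i)
                cols.append(j)
                vals.append(rate)
        n = len(self.states)
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def total_exit_rate(self, i: int) -> float:
        return sum(rate for _, _, rate in self.transitions[i])

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.states)))
        for i, outs in enumerate(self.transitions):
            for j, r, rate in outs:
                if g.has_edge(i, j):
                    g[i][j]["rate"] += rate
                    g[i][j]["reactions"].add(r)
                else:
                    g.add_edge(i, j, rate=rate, reactions={r})
        return g


def build_ctmc(
    net: ReactionNetwork,
    n_max: int,
    initial: dict[str, int] | None = None,
    state_cap: int = DEFAULT_STATE_CAP,
) -> CTMC:
    """Construct the full bounded-population CTMC.

    The state space is every count vector over the network's species with
    total population <= ``n_max`` (|Q| = C(n_max + |M|, |M|)); a reaction
    fires in q when its reactant counts are available and the successor
    state respects the cap.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    m = len(net.species)
    n_states = math.comb(n_max + m, m)
    if n_states > state_cap:
        raise ValueError(
            f"state space of {n_states} states exceeds the cap {state_cap}"
        )
    states = _enumerate_states(m, n_max)
    index = {q: i for i, q in enumerate(states)}

    sidx = {s: i for i, s in enumerate(net.species)}
    rx = []
    for r in net.reactions:
        rcounts = tuple((sidx[s], c) for s, c in r.reactants)
        delta = [0] * m
        for s, c in r.reactants:
            delta[sidx[s]] -= c
        for s, c in r.products:
            delta[sidx[s]] += c
        rx.append((rcounts, tuple(delta), r.rate_constant))

    transitions: list[list[tuple[int, int, float]]] = [[] for _ in states]
    for i, q in enumerate(states):
        total = sum(q)
        for ridx, (rcounts, delta, lam) in enumerate(rx):
            a = _propensity(lam, rcounts, q)
            if a <= 0:
                continue
            q2 = tuple(c + d for c, d in zip(q, delta))
            if any(c < 0 for c in q2) or sum(q2) > n_max:
                continue
            if q2 == q:
                continue  # null net transitions carry no dynamics
            transitions[i].append((index[q2], ridx, a))

    init_state = None
    if initial is not None:
        unknown = set(initial) - set(net.species)
        if unknown:
            raise KeyError(f"unknown species in initial counts: {sorted(unknown)}")
        init_state = tuple(initial.get(s, 0) for s in net.species)
        if sum(init_state) > n_max:
            raise ValueError("initial counts exceed n_max")
    return CTMC(network=net, n_max=n_max, states=states, index=index,
                transitions=transitions, initial=init_state)


# ---------------------------------------------------------------------------
# SCC decomposition and discrete organizations
# ---------------------------------------------------------------------------

@dataclass
class SCCDecomposition:
    components: list[list[int]]           # state indices, sorted
    component_of: np.ndarray              # state -> component id
    bottom: list[bool]
    footprint: list[frozenset[str]]       # phi(T) per component

    def bsccs(self) -> list[int]:
        return [k for k, b in enumerate(self.bottom) if b]


def scc_decomposition(ctmc: CTMC) -> SCCDecomposition:
    """Partition the chain into SCCs; flag bottom components (no exits)."""
    g = ctmc.graph()
    comps = [sorted(c) for c in nx.strongly_connected_components(g)]
    comps.sort(key=lambda c: c[0])
    comp_of = np.empty(len(ctmc.states), dtype=int)
    for k, c in enumerate(comps):
        for i in c:
            comp_of[i] = k
    bottom = []
    footprint = []
    for k, c in enumerate(comps):
        members = set(c)
        is_bottom = all(j in members for i in c for j, _, _ in ctmc.transitions[i])
        bottom.append(is_bottom)
        fp: set[str] = set()
        for i in c:
            fp |= ctmc.phi(i)
        footprint.append(frozenset(fp))
    return SCCDecomposition(components=comps, component_of=comp_of,
                            bottom=bottom, footprint=footprint)


def good_sccs(decomp: SCCDecomposition, ctmc: CTMC) -> list[int]:
    """Component ids whose internal transitions realize every reaction that is
    'possible' in the component.

    A reaction counts as possible in component T when it actually labels a
    transition out of some state of T (this is the cap-aware reading:
    reactant species merely appearing somewhere in the footprint is not
    enough to ever fire the reaction, e.g. when the volume limit suppresses
    it or the reactants never coexist in one state).  T is good when each
    possible reaction labels at least one transition between two states of
    T — any internal transition of an SCC lies on a cycle.  Under this
    reading every BSCC is good, as the organization correspondence requires.
    """
    good = []
    for k, comp in enumerate(decomp.components):
        members = set(comp)
        possible: set[int] = set()
        fired: set[int] = set()
        for i in comp:
            for j, ridx, _ in ctmc.transitions[i]:
                possible.add(ridx)
                if j in members:
                    fired.add(ridx)
        if possible <= fired:
            good.append(k)
    return good


@dataclass(frozen=True)
class DiscreteOrganization:
    members: frozenset[str]
    internal_generators: frozenset[int]   # state indices


def discrete_organizations(ctmc: CTMC, decomp: SCCDecomposition | None = None) -> list[DiscreteOrganization]:
    """Species footprints of good SCCs whose footprint is closed, deduplicated.

    Closure is checked at the chain level: no state reachable from the
    component may present a species outside the footprint (phi(Acc(T)) =
    phi(T)).  For statically closed footprints the two notions coincide;
    they differ only through volume-cap artifacts, where a reaction fireable
    in the footprint has its transition suppressed by N_max — there the
    chain-level notion is the one the discrete-organization definition
    actually uses, and it keeps every BSCC a discrete organization.

    The internal generators of each organization are the union of the member
    states of every contributing good component.
    """
    if decomp is None:
        decomp = scc_decomposition(ctmc)

    # phi(Acc(T)) per component, via the condensation DAG in reverse
    # topological order
    n_comp = len(decomp.components)
    succ: list[set[int]] = [set() for _ in range(n_comp)]
    for i, outs in enumerate(ctmc.transitions):
        ki = decomp.component_of[i]
        for j, _, _ in outs:
            kj = decomp.component_of[j]
            if ki != kj:
                succ[ki].add(kj)
    dag = nx.DiGraph()
    dag.add_nodes_from(range(n_comp))
    for k, targets in enumerate(succ):
        dag.add_edges_from((k, t) for t in targets)
    reach_fp: dict[int, frozenset[str]] = {}
    for k in reversed(list(nx.topological_sort(dag))):
        fp = set(decomp.footprint[k])
        for t in succ[k]:
            fp |= reach_fp[t]
        reach_fp[k] = frozenset(fp)

    found: dict[frozenset[str], set[int]] = {}
    for k in good_sccs(decomp, ctmc):
        fp = decomp.footprint[k]
        if reach_fp[k] != fp:
            continue
        found.setdefault(fp, set()).update(decomp.components[k])
    out = [
        DiscreteOrganization(members=fp, internal_generators=frozenset(states))
        for fp, states in found.items()
    ]
    out.sort(key=lambda d: (len(d.members), tuple(sorted(d.members))))
    return out


class SearchBudgetExceeded(RuntimeError):
    """The bounded firing-sequence search ran out of budget (result unknown)."""


def _reachable(ctmc: CTMC, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        i = stack.pop()
        for j, _, _ in ctmc.transitions[i]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return seen


def is_internal_generator(ctmc: CTMC, q: tuple[int, ...], D, budget_factor: int = 4) -> bool:
    """Literal check of the discrete-organization definition (test oracle).

    State q is an internal generator of D when (i) the species producible
    from q, phi(Acc(q)), equal D, and (ii) some firing sequence from q uses
    every reaction of R_q (those that can eventually fire from q) and ends
    in a state q' with q'(s) >= q(s) for every s in D.  The sequence search
    is a breadth-first walk over (state, reactions-fired-so-far) pairs,
    bounded at |R_q| * N_max * budget_factor steps; exhausting the budget
    raises :class:`SearchBudgetExceeded` rather than silently failing.
    """
    i0 = ctmc.index[tuple(q)]
    D = frozenset(D)
    acc = _reachable(ctmc, i0)
    fp: set[str] = set()
    for i in acc:
        fp |= ctmc.phi(i)
    if frozenset(fp) != D:
        return False
    r_q: set[int] = set()
    for i in acc:
        for _, ridx, _ in ctmc.transitions[i]:
            r_q.add(ridx)
    didx = [k for k, s in enumerate(ctmc.network.species) if s in D]
    q0 = ctmc.states[i0]

    def satisfied(i: int) -> bool:
        qi = ctmc.states[i]
        return all(qi[k] >= q0[k] for k in didx)

    if not r_q:
        return satisfied(i0)  # empty sequence
    max_len = max(1, len(r_q)) * ctmc.n_max * budget_factor
    frontier = {(i0, frozenset())}
    seen = set(frontier)
    for _depth in range(max_len):
        nxt = set()
        for i, fired in frontier:
            for j, ridx, _ in ctmc.transitions[i]:
                key = (j, fired | {ridx})
                if key in seen:
                    continue
                if key[1] == frozenset(r_q) and satisfied(j):
                    return True
                seen.add(key)
                nxt.add(key)
        if not nxt:
            return False
        frontier = nxt
    raise SearchBudgetExceeded(
        f"no verdict for state {q} within {max_len} firing steps"
    )


# ---------------------------------------------------------------------------
# Coarse-grained chain
# ---------------------------------------------------------------------------

@dataclass
class CoarseChain:
    """Partition of the state space with leaving times and jump probabilities."""

    ctmc: CTMC
    blocks: list[list[int]]
    labels: list[frozenset[str]]
    leaving_times: list[np.ndarray]       # per block, per member state (inf allowed)
    jump_probabilities: list[dict[int, float]]  # block -> {target block: prob}

    def block_of(self) -> dict[int, int]:
        return {i: b for b, states in enumerate(self.blocks) for i in states}


def lump_by_phi(ctmc: CTMC) -> tuple[list[list[int]], list[frozenset[str]]]:
    """Partition states by present-species set; empty blocks omitted.

    Blocks are ordered by footprint size then lexicographic species names,
    so block ids are stable across runs.
    """
    groups: dict[frozenset[str], list[int]] = {}
    for i in range(len(ctmc.states)):
        groups.setdefault(ctmc.phi(i), []).append(i)
    labels = sorted(groups, key=lambda m: (len(m), tuple(sorted(m))))
    return [groups[m] for m in labels], labels


def _block_linear_systems(ctmc: CTMC, block: list[int]):
    """Exit probability and expected exit time per member state.

    For state i in the block with total exit rate lambda_i > 0:
        p_i = sum_{j in block} P_ij p_j + sum_{j not in block} P_ij
        t_i = 1/lambda_i + sum_{j in block} P_ij t_j       (when p_i = 1)
    Absorbing member states have p = 0 and infinite t.
    """
    members = {s: k for k, s in enumerate(block)}
    n = len(block)
    rows_in = sp.lil_matrix((n, n))
    exit_prob_rhs = np.zeros(n)
    hold = np.zeros(n)
    direct_exit = np.zeros(n, dtype=bool)
    for k, i in enumerate(block):
        lam = ctmc.total_exit_rate(i)
        if lam <= 0:
            continue
        hold[k] = 1.0 / lam
        acc: dict[int, float] = {}
        for j, _, rate in ctmc.transitions[i]:
            acc[j] = acc.get(j, 0.0) + rate
        for j, rate in acc.items():
            pij = rate / lam
            if j in members:
                rows_in[k, members[j]] = pij
            else:
                exit_prob_rhs[k] += pij
                direct_exit[k] = True

    # states that cannot reach any exit are trapped: p = 0, t = inf; solving
    # only on the escaping part keeps the system nonsingular even when the
    # block contains recurrent sets
    rows_in = rows_in.tocsr()
    can_exit = direct_exit.copy()
    pred = rows_in.T.tocsr()  # pred[j, k] > 0 when k -> j inside the block
    frontier = list(np.nonzero(can_exit)[0])
    while frontier:
        j = frontier.pop()
        for k in pred.indices[pred.indptr[j]:pred.indptr[j + 1]]:
            if not can_exit[k]:
                can_exit[k] = True
                frontier.append(k)

    p = np.zeros(n)
    t = np.full(n, np.inf)
    sub = np.nonzero(can_exit)[0]
    if sub.size:
        eye = sp.identity(len(sub), format="csr")
        A = eye - rows_in[sub][:, sub]
        rhs = exit_prob_rhs[sub]
        if len(sub) <= DENSE_LIMIT:
            p_sub = np.linalg.solve(A.toarray(), rhs)
        else:
            p_sub = spla.spsolve(A.tocsc(), rhs)
        p[sub] = np.clip(p_sub, 0.0, 1.0)

        certain = p >= 1.0 - PROB_TOL
        if certain.any():
            sub2 = np.nonzero(certain)[0]
            A2 = sp.identity(len(sub2), format="csr") - rows_in[sub2][:, sub2]
            rhs2 = hold[sub2]
            if len(sub2) <= DENSE_LIMIT:
                t_sub = np.linalg.solve(A2.toarray(), rhs2)
            else:
                t_sub = spla.spsolve(A2.tocsc(), rhs2)
            t[sub2] = t_sub
    return p, t


def expected_leaving_time(ctmc: CTMC, block) -> np.ndarray:
    """Expected time to first leave the block, per member state.

    Infinite whenever the exit probability is below 1 (the state can get
    trapped inside the block), which sidesteps solving a singular
    expected-time system.
    """
    block = sorted(block)
    _, t = _block_linear_systems(ctmc, block)
    return t


def block_transition_probabilities(
    ctmc: CTMC,
    blocks: list[list[int]] | None = None,
    labels: list[frozenset[str]] | None = None,
    entry: str = "uniform",
) -> CoarseChain:
    """Coarse-grained chain over the given partition (default: phi-lumping).

    For each block the jump distribution is the probability, starting from
    the entry distribution over the block's states (uniform by default),
    that the first state visited outside the block belongs to each other
    block.  Rows of non-absorbing blocks sum to the overall exit
    probability (1 when escape is certain).
    """
    if blocks is None:
        blocks, labels = lump_by_phi(ctmc)
    if labels is None:
        labels = [frozenset().union(*(ctmc.phi(i) for i in b)) if b else frozenset()
                  for b in blocks]
    block_of = {}
    for b, states in enumerate(blocks):
        for i in states:
            block_of[i] = b

    leaving = []
    jumps: list[dict[int, float]] = []
    for b, block in enumerate(blocks):
        block = sorted(block)
        p_exit, t = _block_linear_systems(ctmc, block)
        leaving.append(t)

        # absorption probabilities into each foreign block, per member state
        members = {s: k for k, s in enumerate(block)}
        n = len(block)
        targets = sorted({block_of[j]
                          for i in block for j, _, _ in ctmc.transitions[i]
                          if block_of[j] != b})
        if not targets:
            jumps.append({})
            continue
        rows_in = sp.lil_matrix((n, n))
        rhs = np.zeros((n, len(targets)))
        tpos = {tb: c for c, tb in enumerate(targets)}
        absorbing = np.zeros(n, dtype=bool)
        for k, i in enumerate(block):
            lam = ctmc.total_exit_rate(i)
            if lam <= 0:
                absorbing[k] = True
                continue
            acc: dict[int, float] = {}
            for j, _, rate in ctmc.transitions[i]:
                acc[j] = acc.get(j, 0.0) + rate
            for j, rate in acc.items():
                pij = rate / lam
                if j in members:
                    rows_in[k, members[j]] = pij
                else:
                    rhs[k, tpos[block_of[j]]] += pij
        eye = sp.identity(n, format="csr")
        A = (eye - rows_in.tocsr()).tolil()
        for k in np.nonzero(absorbing)[0]:
            A[k, :] = 0.0
            A[k, k] = 1.0
            rhs[k, :] = 0.0
        H = np.linalg.solve(A.tocsc().toarray(), rhs) if n <= DENSE_LIMIT else \
            np.column_stack([spla.spsolve(A.tocsc(), rhs[:, c]) for c in range(rhs.shape[1])])
        if entry == "uniform":
            w = np.full(n, 1.0 / n)
        else:
            raise ValueError(f"unknown entry distribution {entry!r}")
        probs = w @ H
        jumps.append({tb: float(pv) for tb, pv in zip(targets, probs) if pv > PROB_TOL})
    return CoarseChain(ctmc=ctmc, blocks=[sorted(b) for b in blocks], labels=list(labels),
                       leaving_times=leaving, jump_probabilities=jumps)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def state_graph_to_dot(ctmc: CTMC) -> str:
    """State graph in DOT form; labels follow the 'index (c1,c2,...)' convention."""
    lines = ["digraph ctmc {", "  node [shape=ellipse];"]
    for i, q in enumerate(ctmc.states):
        lines.append(f'  s{i} [label="{i} ({",".join(map(str, q))})"];')
    for i, outs in enumerate(ctmc.transitions):
        acc: dict[int, float] = {}
        for j, _, rate in outs:
            acc[j] = acc.get(j, 0.0) + rate
        for j, rate in acc.items():
            lines.append(f'  s{i} -> s{j} [label="{rate:g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def coarse_chain_to_json(chain: CoarseChain) -> str:
    payload = []
    for b, label in enumerate(chain.labels):
        t = chain.leaving_times[b]
        mean_t = float(np.mean(t)) if np.isfinite(t).all() else None
        payload.append({
            "block": b,
            "species": sorted(label),
            "n_states": len(chain.blocks[b]),
            "mean_leaving_time": mean_t,   # null = infinite
            "jumps": {str(k): v for k, v in chain.jump_probabilities[b].items()},
        })
    return json.dumps(payload, indent=2)
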