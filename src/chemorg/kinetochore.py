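"""Quasi-spatial 4-state kinetochore model of the spindle assembly checkpoint.

Each kinetochore is a node on a plane (or a vertex of an explicit graph)
with one of four states: unattached, attached, about_to_exit, exit.  Per
synchronous time step, reading all neighbor states from the pre-step
configuration:

* unattached -> attached with probability ``p_attach`` (default 0.005);
* attached -> about_to_exit with probability ``p_exit`` (the swept p);
* about_to_exit -> exit iff every neighbor is about_to_exit or exit
  (vacuously true for isolated nodes), else falls back to attached;
* exit is irreversible.

A trial fails when, after a step, one node is in exit while another is
still unattached — the checkpoint dysfunction.  With a complete
neighborhood this cannot happen: a node exits only when no neighbor is
unattached, and no node ever returns to unattached.  Monte-Carlo trials
estimate the checkpoint success probability over a (p_exit, radius) grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "UNATTACHED", "ATTACHED", "ABOUT_TO_EXIT", "EXIT",
    "LatticeParams", "LatticeModel", "TrialOutcome",
    "init_lattice", "neighbors", "step", "run_trial",
    "success_probability", "sweep", "enumerate_success_probability",
]

UNATTACHED, ATTACHED, ABOUT_TO_EXIT, EXIT = 0, 1, 2, 3
STATE_NAMES = ("unattached", "attached", "about_to_exit", "exit")


@dataclass(frozen=True)
class LatticeParams:
    """Simulation parameters.

    ``radius`` is the Euclidean neighborhood range on the ``extent`` x
    ``extent`` plane (0–10 scale); ``graph`` selects an explicit topology
    instead ("line", "ring", or "knn:<k>" for a ring with k nearest
    neighbors per node).
    """

    n: int = 92
    p_attach: float = 0.005
    p_exit: float = 0.5
    radius: float = 10.0 * math.sqrt(2.0)
    extent: float = 10.0
    graph: str | None = None
    max_steps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one kinetochore")
        if not (0.0 <= self.p_attach <= 1.0 and 0.0 <= self.p_exit <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


@dataclass
class LatticeModel:
    params: LatticeParams
    positions: np.ndarray | None          # (n, 2) or None in graph mode
    adjacency: list[np.ndarray]           # neighbor index arrays, self excluded
    states: np.ndarray                    # (n,) int8

    def flat_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in flattened CSR-like form for the vectorized update."""
        degrees = np.fromiter((len(a) for a in self.adjacency), dtype=np.int64,
                              count=len(self.adjacency))
        ptr = np.concatenate([[0], np.cumsum(degrees)])
        flat = (np.concatenate(self.adjacency).astype(np.int64)
                if degrees.sum() else np.empty(0, dtype=np.int64))
        return flat, ptr


def _graph_adjacency(n: int, spec: str) -> list[np.ndarray]:
    if spec == "line":
        return [np.array([j for j in (i - 1, i + 1) if 0 <= j < n], dtype=int)
                for i in range(n)]
    if spec == "ring":
        spec = "knn:2"
    if spec.startswith("knn:"):
        k = int(spec.split(":", 1)[1])
        half = k // 2
        adj = []
        for i in range(n):
            nb = {(i + d) % n for d in range(-half, half + 1)} - {i}
            # odd k: add one extra forward neighbor
            if k % 2 == 1:
                nb.add((i + half + 1) % n)
            adj.append(np.array(sorted(nb), dtype=int))
        return adj
    raise ValueError(f"unknown graph spec {spec!r}")


def init_lattice(params: LatticeParams, rng: np.random.Generator | None = None) -> LatticeModel:
    """Place n kinetochores (uniform on the plane, or on the explicit graph),
    all unattached.  Placement is driven by ``params.seed`` unless an rng is
    passed explicitly."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.graph is not None:
        positions = None
        adjacency = _graph_adjacency(params.n, params.graph)
    else:
        positions = rng.uniform(0.0, params.extent, size=(params.n, 2))
        adjacency = neighbors(positions, params.radius)
    states = np.full(params.n, UNATTACHED, dtype=np.int8)
    return LatticeModel(params=params, positions=positions,
                        adjacency=adjacency, states=states)


def neighbors(positions: np.ndarray, radius: float) -> list[np.ndarray]:
    """Symmetric adjacency by Euclidean distance <= radius, self excluded."""
    n = len(positions)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    mask = (d <= radius)
    np.fill_diagonal(mask, False)
    return [np.nonzero(mask[i])[0] for i in range(n)]


def step(model: LatticeModel, rng: np.random.Generator,
         flat_adj: tuple[np.ndarray, np.ndarray] | None = None) -> None:
    """One synchronous update, in place (neighbor states read pre-step)."""
    old = model.states
    new = old.copy()
    p = model.params
    u = rng.random(p.n)

    unatt = old == UNATTACHED
    new[unatt & (u < p.p_attach)] = ATTACHED

    att = old == ATTACHED
    new[att & (u < p.p_exit)] = ABOUT_TO_EXIT

    ready = old == ABOUT_TO_EXIT
    if ready.any():
        flat, ptr = flat_adj if flat_adj is not None else model.flat_adjacency()
        # number of neighbors NOT in {about_to_exit, exit}, per node
        holding = (old < ABOUT_TO_EXIT).astype(np.int64)
        if flat.size:
            vals = np.append(holding[flat], 0)  # sentinel keeps ptr == size valid
            blocked = np.add.reduceat(vals, ptr[:-1])
            blocked[ptr[:-1] == ptr[1:]] = 0   # reduceat quirk on empty segments
        else:
            blocked = np.zeros(p.n, dtype=np.int64)
        new[ready & (blocked == 0)] = EXIT
        new[ready & (blocked > 0)] = ATTACHED
    model.states = new


@dataclass(frozen=True)
class TrialOutcome:
    result: str                           # "success" | "failure" | "timeout"
    steps: int

    @property
    def failed(self) -> bool:
        return self.result == "failure"


def run_trial(params: LatticeParams, rng: np.random.Generator | None = None,
              stop_on_safety: bool = False) -> TrialOutcome:
    """Simulate until every node exits (success), the dysfunction predicate
    holds (failure), or ``max_steps`` elapse (timeout).  The failure check —
    some node in exit while another is unattached — runs after every
    synchronous step.

    With ``stop_on_safety`` the trial ends in success as soon as no node is
    unattached any more: attachment is irreversible, so the dysfunction
    predicate is unreachable from then on and the checkpoint outcome is
    decided.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    model = init_lattice(params, rng)
    flat_adj = model.flat_adjacency()
    for k in range(1, params.max_steps + 1):
        step(model, rng, flat_adj)
        s = model.states
        if (s == EXIT).any() and (s == UNATTACHED).any():
            return TrialOutcome("failure", k)
        if (s == EXIT).all():
            return TrialOutcome("success", k)
        if stop_on_safety and not (s == UNATTACHED).any():
            return TrialOutcome("success", k)
    return TrialOutcome("timeout", params.max_steps)


def _wilson(successes: int, n: int, z: float = 1.959963984540054):
    if n == 0:
        return 0.0, 1.0
    phat = successes / n
    denom = 1 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


@dataclass(frozen=True)
class SuccessEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    trials: int
    failures: int
    timeouts: int


def success_probability(params: LatticeParams, trials: int) -> SuccessEstimate:
    """Monte-Carlo success estimate with a Wilson 95% interval.

    A trial counts as a success when no dysfunction is observed; timeouts
    (e.g. every trial at p_exit = 0, where no exit channel exists) are
    therefore successes, and their count is reported separately.  Trials are
    cut short once every node has attached, because the dysfunction
    predicate can never hold after that.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    root = np.random.default_rng(params.seed)
    seeds = root.integers(0, 2**31 - 1, size=trials)
    failures = timeouts = 0
    for s in seeds:
        out = run_trial(params, np.random.default_rng(int(s)), stop_on_safety=True)
        if out.result == "failure":
            failures += 1
        elif out.result == "timeout":
            timeouts += 1
    ok = trials - failures
    lo, hi = _wilson(ok, trials)
    return SuccessEstimate(ok / trials, lo, hi, trials, failures, timeouts)


def sweep(p_values, radii, params: LatticeParams, trials: int) -> pd.DataFrame:
    """Success probability over the (p_exit, radius) grid, one row per pair."""
    rows = []
    for p in p_values:
        for r in radii:
            est = success_probability(
                replace(params, p_exit=float(p), radius=float(r)), trials
            )
            rows.append({
                "p_exit": float(p), "radius": float(r),
                "success": est.estimate,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "timeouts": est.timeouts,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exhaustive oracle for tiny instances
# ---------------------------------------------------------------------------

def enumerate_success_probability(params: LatticeParams, adjacency: list | None = None) -> float:
    """Exact success probability by full enumeration of the synchronous
    Markov chain (test oracle; feasible for n <= 3 and small max_steps).

    Success here mirrors :func:`success_probability`: the probability that
    the dysfunction predicate never holds within ``max_steps`` steps.
    """
    n = params.n
    if adjacency is None:
        model = init_lattice(params)
        adjacency = model.adjacency
    pa, pe = params.p_attach, params.p_exit

    def transitions(cfg: tuple) -> dict[tuple, float]:
        per_node = []
        for i, s in enumerate(cfg):
            if s == ABOUT_TO_EXIT:
                nb = adjacency[i]
                ok = all(cfg[j] in (ABOUT_TO_EXIT, EXIT) for j in nb)
                per_node.append([(EXIT if ok else ATTACHED, 1.0)])
            elif s == UNATTACHED:
                per_node.append([(ATTACHED, pa), (UNATTACHED, 1 - pa)] if pa > 0
                                else [(UNATTACHED, 1.0)])
            elif s == ATTACHED:
                per_node.append([(ABOUT_TO_EXIT, pe), (ATTACHED, 1 - pe)] if pe > 0
                                else [(ATTACHED, 1.0)])
            else:
                per_node.append([(EXIT, 1.0)])
        out: dict[tuple, float] = {}

        def rec(i, acc, prob):
            if prob == 0.0:
                return
            if i == n:
                out[tuple(acc)] = out.get(tuple(acc), 0.0) + prob
                return
            for s2, p2 in per_node[i]:
                rec(i + 1, acc + [s2], prob * p2)

        rec(0, [], 1.0)
        return out

    def failed(cfg: tuple) -> bool:
        return EXIT in cfg and UNATTACHED in cfg

    dist = {tuple([UNATTACHED] * n): 1.0}
    p_fail = 0.0
    for _ in range(params.max_steps):
        nxt: dict[tuple, float] = {}
        for cfg, p in dist.items():
            for cfg2, p2 in transitions(cfg).items():
                q = p * p2
                if failed(cfg2):
                    p_fail += q
                else:
                    nxt[cfg2] = nxt.get(cfg2, 0.0) + q
        dist = nxt
        if not dist:
            break
    return 1.0 - p_fail
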