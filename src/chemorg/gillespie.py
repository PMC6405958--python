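"""Exact stochastic simulation (Gillespie direct method) of reaction networks.

The well-mixed counterpart of the particle simulations: propensities follow
stochastic mass action (lambda_r times the falling factorial of each
reactant count), there is no population cap, and a trajectory ends at t_max
or in an absorbing state (total propensity zero).  For the coarsest
checkpoint network this reproduces the switch into the single interesting
organization {Activator, KinA}: attachment eventually consumes every
unattached kinetochore, after which the inhibitor relaxes away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ReactionNetwork

__all__ = ["Trajectory", "simulate", "occupancy", "trajectory_to_csv"]


@dataclass
class Trajectory:
    """Event times and population counts of one stochastic realization."""

    network: ReactionNetwork
    times: np.ndarray                    # shape (k,), strictly increasing from 0
    counts: np.ndarray                   # shape (k, |M|)
    seed: int
    initial: dict[str, int]
    t_max: float
    absorbed: bool = False

    def final_counts(self) -> dict[str, int]:
        return dict(zip(self.network.species, self.counts[-1]))

    def __len__(self) -> int:
        return len(self.times)


def simulate(
    net: ReactionNetwork,
    initial: dict[str, int],
    t_max: float,
    seed: int,
) -> Trajectory:
    """Run the direct-method SSA from the given counts until ``t_max``.

    Returns the jump chain (state after every reaction event, prepended with
    the initial state at t = 0).  Reproducible: the same seed yields an
    identical trajectory.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    unknown = set(initial) - set(net.species)
    if unknown:
        raise KeyError(f"unknown species in initial counts: {sorted(unknown)}")
    if any(v < 0 for v in initial.values()):
        raise ValueError("initial counts must be non-negative")

    m = len(net.species)
    sidx = {s: i for i, s in enumerate(net.species)}
    rx = []
    for r in net.reactions:
        rcounts = tuple((sidx[s], c) for s, c in r.reactants)
        delta = np.zeros(m, dtype=np.int64)
        for s, c in r.reactants:
            delta[sidx[s]] -= c
        for s, c in r.products:
            delta[sidx[s]] += c
        rx.append((rcounts, delta, r.rate_constant))

    rng = np.random.default_rng(seed)
    q = np.zeros(m, dtype=np.int64)
    for s, c in initial.items():
        q[sidx[s]] = c

    times = [0.0]
    states = [q.copy()]
    t = 0.0
    absorbed = False
    props = np.empty(len(rx))
    while True:
        for k, (rcounts, _, lam) in enumerate(rx):
            a = lam
            for idx, coeff in rcounts:
                n = q[idx]
                if n < coeff:
                    a = 0.0
                    break
                for d in range(coeff):
                    a *= n - d
            props[k] = a
        total = props.sum()
        if total <= 0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        k = rng.choice(len(rx), p=props / total)
        q += rx[k][1]
        times.append(t)
        states.append(q.copy())

    return Trajectory(
        network=net,
        times=np.asarray(times),
        counts=np.vstack(states),
        seed=seed,
        initial=dict(initial),
        t_max=t_max,
        absorbed=absorbed,
    )


def occupancy(traj: Trajectory, species, t_grid) -> np.ndarray:
    """Counts of the given species on a time grid.

    Right-continuous step interpolation: the value at grid point t is the
    count after the last event at or before t.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and (t_grid.min() < 0 or t_grid.max() > traj.t_max):
        raise ValueError("grid extends outside [0, t_max]")
    if isinstance(species, str):
        cols = traj.network.species_index(species)
    else:
        cols = [traj.network.species_index(s) for s in species]
    pos = np.searchsorted(traj.times, t_grid, side="right") - 1
    pos = np.clip(pos, 0, len(traj.times) - 1)
    return traj.counts[pos][..., cols] if not isinstance(cols, int) else traj.counts[pos, cols]


def trajectory_to_csv(traj: Trajectory) -> str:
    """CSV with a time column and one column per species."""
    df = pd.DataFrame(traj.counts, columns=traj.network.species)
    df.insert(0, "time", traj.times)
    return df.to_csv(index=False)
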