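# chemorg

Organization-oriented coarse-graining of chemical reaction networks,
demonstrated on the human mitotic spindle assembly checkpoint (SAC).

The SAC is the surveillance mechanism that blocks anaphase while any
kinetochore is still unattached to the spindle: unattached kinetochores
(KinU) catalyze production of a diffusible inhibitor that keeps the
anaphase-promoting complex (APC/C) inactive; once the last kinetochore
attaches (KinA), the inhibitor relaxes away and the cell commits to
division. `chemorg` analyses reaction-network models of this mechanism at
several levels of granularity — from a 14-species biochemical network down
to a 4-state-per-kinetochore automaton — and links the levels through
*chemical organizations*.

## The core concepts

For a reaction network with species set M, stoichiometric matrix
N = (n_{i,r}) and fireable reactions R_A = { r : LHS(r) ⊆ A }:

* a species set A ⊆ M is **closed** when dp(A) = ⋃_{r ∈ R_A} RHS(r) ⊆ A;
* A is **self-maintaining** when a flux vector v exists with v_r > 0 for
  r ∈ R_A, v_r = 0 otherwise, and N v ≥ 0 (decided here by linear
  programming with v_r ≥ 1, which is equivalent because the system is
  homogeneous);
* a closed and self-maintaining set is an **organization** — the only
  species combinations in which mass-action dynamics can have fixed points
  or other limit sets.

On top of the static analysis, the package builds the bounded-population
continuous-time Markov chain of a network (all count vectors with
Σ q(s) ≤ N_max, mass-action rates λ_r·Π_{s∈LHS(r)} q(s)), decomposes it
into strongly connected components, and identifies **discrete
organizations** — species footprints of "good" SCCs, the finite-population
counterpart of organizations — together with expected leaving times and an
organization-level coarse-grained Markov chain.

Spatial aspects are covered twice: a quasi-spatial 4-state kinetochore
automaton (unattached → attached → about-to-exit → exit, with
neighborhood-gated exit) for Monte-Carlo checkpoint-success estimation,
and a compartment-graph mapping that assigns each compartment the
organization generated by the species in its diffusion neighborhood.

## Bundled models

| fixture | species | reactions | organizations |
|---|---|---|---|
| `model1` (full SAC) | 14 | 21 | 16 |
| `model1b` (no attachment, no O-Mad2 decay) | 14 | 19 | 64 |
| `model2` (lumped Promotor/Activator/Inhibitor) | 7 | 9 | 8 |
| `model2b` (no attachment) | 7 | 8 | 16 |
| `model3` (coarsest) | 4 | 3 | 4 |
| `model3b` (no attachment) | 4 | 2 | 8 |

`model3` is fully specified by three reactions: `KinU -> KinA`,
`Activator + KinU -> KinU + Inhibitor`, `Inhibitor -> Activator`.
Models 1 and 2 are transcriptions (their sources are network diagrams, not
reaction lists); the organization counts above validate the
transcriptions. They ship as editable `.rn` text files under
`src/chemorg/data/`.

## Worked example

```
$ chemorg orgs --model model3 --interesting preset:model3
4 organizations, 1 interesting
```

The coarsest model has organizations {}, {Activator}, {KinA},
{Activator, KinA}; requiring a kinetochore and a regulator
(`(KinA OR KinU) AND (Activator OR Inhibitor)`) singles out
{Activator, KinA} — the checkpoint-inactivated "go" state the cell must
reach, and the only subspace where it can settle.

```
$ chemorg ctmc --model model3 --nmax 10
1001 states
4 discrete organizations
```

With at most 10 molecules the chain has C(14,4) = 1001 states; its good
SCCs yield exactly the four static organizations, none of which is ever
left (infinite expected leaving times) — the finite-population dynamics
agree with the static lattice.

```
$ chemorg ssa --model model3 --init "KinU=92,Activator=1000" --tmax 10000 --seed 7
70622 events; final {'KinU': 0, 'KinA': 92, 'Activator': 1000, 'Inhibitor': 0}
```

A stochastic trajectory from 92 unattached kinetochores absorbs in the
"go" organization: every kinetochore attached, the inhibitor gone, and
both conservation laws (KinU+KinA, Activator+Inhibitor) intact.

```
$ chemorg kinetochore --n 92 --p-exit 0.5 --trials 200 --seed 11
success 1.000 [0.981, 1.000] (0 failures, 0 timeouts)
```

With a global neighborhood the 4-state checkpoint never fails; shrinking
the neighborhood radius (`--sweep-radius 0,2,4,6,8,10`) shows how local
signaling breaks the checkpoint.

```
$ chemorg spatial
compartment 1: ['Activator', 'Inhibitor', 'KinU']
...
compartment 4: ['Activator', 'KinA']
```

On the bundled five-compartment diffusion path, compartments 3 and 4 hold
identical species but map to different organizations because their
neighborhoods differ — the spatial-organization view of the transition.

## Layout

- `src/chemorg/network.py` — reaction-network model, `.rn` text format, fixtures
- `src/chemorg/organizations.py` — closure, LP self-maintenance, lattice, predicates
- `src/chemorg/ctmc.py` — bounded-population chain, SCC/discrete-organization analysis
- `src/chemorg/gillespie.py` — exact stochastic simulation
- `src/chemorg/kinetochore.py` — 4-state quasi-spatial checkpoint model
- `src/chemorg/spatial.py` — compartment-graph spatial organizations
- `src/chemorg/cli.py` — `chemorg` command-line interface
- `docs/methods.md` — model definitions, conventions, numerical choices, limitations
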