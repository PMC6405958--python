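# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, and what the bundled fixtures and tests do
and do not establish.

## Reaction networks and the `.rn` format

A network is an ordered species list plus an ordered list of mass-action
reactions (reactant/product multisets, positive rate constant, per time
unit). The text format is one reaction per line,
`LHS -> RHS ; rate [; id]`, `#` comments, species tokens separated by `+`;
stoichiometric coefficients may be written as a prefix integer (`2 A`) or
by repetition (`A + A`), and the writer emits prefix form. Species names
may contain `:`, `/` and `-` so that protein-complex names such as
`APC/C:Cdc20:BubR1:Bub3` are single tokens; whitespace, `+`, `;` and `->`
are excluded. Empty sides encode inflow (`-> A`) and decay (`A ->`).
All bundled networks use reactant coefficients of at most one.

## Static organization analysis

Definitions as in the README. Decisions and conventions:

* **Strict positivity.** Self-maintenance requires v_r > 0 on fireable
  reactions; the LP uses v_r ≥ 1, with no loss since the constraint system
  is homogeneous (any strictly positive solution scales to one with
  entries ≥ 1). Feasibility tolerance 1e-9 (scipy HiGHS).
* **Row convention.** N v ≥ 0 is imposed on the rows of the species in A.
  For closed A this equals constraining all rows, because reactions
  fireable in a closed set touch only species of A. For non-closed A
  (the generator's intermediate steps) the restriction to A's rows is the
  documented semantics.
* **Self-maintaining shrinkage.** The generated self-maintaining subset is
  computed by repeated removal rounds: maximize the minimum net production
  t over the current species (variables v ≥ 1 on currently fireable
  reactions, t ≤ 1 to keep the LP bounded); if t < 0, every species with
  negative net production at the optimum is removed and the fireable set
  recomputed. Each round removes at least the minimum-attaining species,
  so the loop terminates. The removal-batch rule makes the procedure
  deterministic given the solver; in consistent networks the result is the
  unique largest self-maintaining subset.
* **Organization generation** alternates closure and shrinkage to a joint
  fixed point. In consistent networks (all bundled models) this equals the
  single pass G_SM(G_CL(B)); when further alternation was needed the
  result carries `consistent_fixed_point=False`, flagging that uniqueness
  is not guaranteed.
* **Enumeration.** Up to 14 species, all 2^|M| subset closures are taken
  (bitmask arithmetic) and deduplicated; beyond that, closed sets are
  explored upward from closure(∅) by single-species additions (the closed
  sets form a closure system, so this reaches all of them). Each closed
  set gets one feasibility LP. Both strategies are available and tested to
  agree. Output order is by size then lexicographic, so results are
  byte-stable. Default species cap 25.
* **Interesting-organization predicates** are boolean formulas over
  species-presence atoms with AND/OR and parentheses (AND binds tighter).
  The three bundled presets encode the domain conditions for the SAC
  models: an organization should retain a kinetochore in some form plus
  the regulator proteins in bound or unbound form.

## Bundled SAC model hierarchy

`model3` is specified verbatim by its three reactions. `model1`
(14 species, 21 reactions) and `model2` (7 species, 9 reactions) are
transcriptions: their sources are network diagrams and a lumping table,
not printed reaction lists. The transcriptions were constructed from the
standard SAC biochemistry — Mad2 template activation at unattached
kinetochores, MCC assembly (C-Mad2 + Cdc20 → Cdc20:C-Mad2, + BubR1:Bub3 →
MCC), APC/C activation by Cdc20 and sequestration by the MCC, BubR1
extraction of Cdc20, and checkpoint silencing at attached kinetochores
(KinA-catalyzed Mad2 release from APC/C-bound MCC, producing
APC/C:Cdc20:BubR1:Bub3 and O-Mad2) — and validated against the published
organization counts (16/64 for the full model with/without attachment and
O-Mad2 decay, 8/16 for the reduced model with/without attachment). The
counts are exact under the package's enumeration and act as the
transcription's acceptance test.

Two structural observations fix otherwise-free choices in `model1`:

* The reported initial organization of the short-timescale variant
  contains APC/C:MCC, APC/C:Cdc20 and BubR1:Bub3 but not
  APC/C:Cdc20:BubR1:Bub3; it can only be closed if the formation of that
  complex requires attached kinetochores. The transcription therefore
  makes BCC formation the KinA-catalyzed silencing step
  `KinA + APC/C:MCC -> KinA + APC/C:Cdc20:BubR1:Bub3 + O-Mad2`, which
  also reproduces the observation that this complex lives only in the top
  organization of the lattice, and that its formation releases O-Mad2.
* `model1` has O-Mad2 decay but no O-Mad2 synthesis, so on the long
  timescale open Mad2 persists only where the KinU-driven template cycle
  regenerates it; removing the decay (short timescale) makes O-Mad2 an
  inert, freely-maintained species, which is exactly why the
  short-timescale lattice is larger.

**Known limitation.** Under the published "interesting" condition for the
full model, this transcription yields two interesting organizations on
the long timescale (and twelve on the short) where the reference analysis
reports one (three). The discrepancy is structural, not a tuning matter:
any mass-action network whose lattice contains the reported
go-organization — free Cdc20, free BubR1:Bub3 and their complex
coexisting with the APC/C machinery — also admits either an inert
{Cdc20, BubR1:Bub3}-type organization or a balanced
{Cdc20, BubR1:Bub3, Cdc20:BubR1:Bub3} organization, and since nothing
consumes KinA, adding KinA to it yields a second organization satisfying
the condition. The reference reaction list would be needed to resolve
this; the counts, which are the published validation quantities, are
unaffected. All interesting-organization results for `model2` and
`model3` match the reference exactly (1/3 interesting with/without
attachment for both).

Rate constants for all fixtures are package defaults chosen to display
the checkpoint switching on convenient time scales (attachment slowest,
binding fastest); every organization-level result is rate-independent,
and rates are overridable in the `.rn` files.

## Bounded-population CTMC

States are all count vectors with total ≤ N_max
(|Q| = C(N_max+|M|, |M|)); transitions follow stochastic mass action
(falling-factorial propensities, which reduce to λ_r·Π q(s) for unit
coefficients), and a firing whose target would exceed N_max is absent.
Reactions with zero net stoichiometry induce self-loops and are omitted
from the transition relation (they carry no dynamics).

* **Good SCCs.** A reaction is *possible* in a component T when it labels
  a transition out of some state of T; T is good when every possible
  reaction also labels an internal transition (any internal transition of
  an SCC lies on a cycle). This cap-aware reading — rather than "reactant
  species appear somewhere in the footprint" — is the one under which
  every bottom SCC is good, as the organization correspondence requires:
  a reaction can be unfireable in every state of a component even though
  its reactants appear in the footprint (cap saturation, or reactants
  never jointly present).
* **Discrete organizations** are footprints of good SCCs whose footprint
  is closed at chain level: no state reachable from the component
  presents an outside species (computed on the condensation DAG). For
  statically closed footprints the two notions coincide; they differ only
  through volume-cap artifacts, where the chain-level notion is the one
  the definition of a discrete organization actually uses.
* **Internal-generator oracle.** The literal definition — a firing
  sequence from q covering every eventually-fireable reaction and ending
  count-wise ≥ q on the organization — is implemented as a bounded
  breadth-first search over (state, fired-set) pairs, budgeted at
  |R_q|·N_max·4 steps; exceeding the budget raises rather than returning
  false. It serves as a test oracle, not as part of the pipeline.
* **Leaving times and coarse chain.** For a block of states, exit
  probabilities are solved first (states that cannot reach an exit are
  trapped and get p = 0); the expected leaving time is solved only on
  states with exit probability 1 and reported infinite elsewhere,
  avoiding singular systems. The coarse-grained chain lumps states by
  present-species set φ (or any supplied partition) and reports, from a
  uniform entry distribution over each block (an explicit approximation
  knob; the aggregation the original figure used is not specified), the
  probability that each other block is entered first. Dense linear
  algebra below 20,000 states, sparse above. State indexing is
  lexicographic by counts, so ids are stable across runs.

## Stochastic simulation

The Gillespie direct method with the same propensities and no population
cap. Trajectories are reproducible from the seed; conservation laws (for
`model3`: KinU+KinA and Activator+Inhibitor) hold along every sample
path, and every finite-kinetochore trajectory is eventually absorbed in
the go-organization — the dynamic face of the static result.

## 4-state kinetochore model

92 kinetochores (default) on a 10×10 plane, neighborhood = Euclidean
distance ≤ radius (so the 0–10 radius axis is meaningful), or an explicit
line/ring/k-nearest-ring graph. Synchronous updates read all neighbor
states from the pre-step configuration: unattached→attached with
probability 0.005 per step; attached→about-to-exit with probability
p_exit; about-to-exit→exit iff every neighbor is about-to-exit or exit
(vacuously true for isolated nodes — this is what makes small radii
fail), else fall back to attached; exit is irreversible. A trial fails
when an exited node coexists with an unattached one after a step;
timeouts (max_steps = 10,000) without dysfunction count as successes
(the p_exit = 0 regime can end no other way), and trials end early once
no unattached node remains, since attachment is irreversible and the
dysfunction predicate is then unreachable. Success estimates carry Wilson
95% intervals; an exact oracle enumerates the synchronous chain for ≤3
nodes. An asynchronous update mode is deliberately not provided.

With a complete neighborhood the failure predicate is unreachable (a node
exits only when no neighbor is unattached, and unattached is never
re-entered); the tests verify this exhaustively for n ≤ 4 and by 200
seeded trials at n = 92.

## Spatial organizations

Compartments form an undirected diffusion graph (JSON/YAML), each holding
a species set; at most one kinetochore per compartment, so KinU and KinA
never co-occur. The spatial organization of a compartment is
`generate_organization` of the species union over its hop-distance-r
neighborhood (default r = 1, default network `model3b` — the
transition-phase setting). Neighborhood radius is hop distance, not
geometry; the geometric setting lives in the kinetochore module. The
bundled five-compartment path reproduces the worked example: compartments
with identical contents but different neighborhoods map to different
organizations.

## Problem sizes used in tests and the acceptance script

Organization enumeration runs the full 2^14 subset scan for the
14-species model (seconds); CTMC analyses use N_max ≤ 10 (≤ 1001 states);
SSA checks use up to 92 kinetochores and 1000 regulator molecules;
checkpoint success uses 200 trials of 92 nodes. Random-network property
tests use ≤ 8 species so the brute-force subset oracle stays exact.

## What the fixtures do not show

The bundled networks are transcriptions validated by organization counts;
they are not guaranteed to reproduce rate-dependent quantities of the
original particle-based simulations (diffusion, crowding, spatial
gradients are all absent from the well-mixed SSA). The coarse-chain jump
probabilities depend on the entry-distribution choice documented above
and have no published numeric reference. The 4-state model's
success-probability surface is reported with confidence intervals rather
than compared to curve values, which exist only in figure form.
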