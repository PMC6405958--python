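"""Bounded-population CTMC construction, SCCs, discrete organizations,
leaving times and the coarse-grained chain."""

import math

import numpy as np
import pytest

import chemorg as co
from chemorg.ctmc import (
    block_transition_probabilities,
    build_ctmc,
    discrete_organizations,
    expected_leaving_time,
    good_sccs,
    is_internal_generator,
    lump_by_phi,
    scc_decomposition,
    state_graph_to_dot,
)

from conftest import random_network


class TestBuild:
    def test_model3_state_counts(self, model3):
        assert len(build_ctmc(model3, 10)) == 1001
        assert len(build_ctmc(model3, 5)) == math.comb(9, 4) == 126

    @pytest.mark.parametrize("n_species, n_max", [(2, 3), (3, 4), (4, 2)])
    def test_state_count_identity_random(self, n_species, n_max):
        rng = np.random.default_rng(n_species * 10 + n_max)
        while True:
            net = random_network(rng, max_species=n_species, max_reactions=5)
            if len(net.species) == n_species:
                break
        assert len(build_ctmc(net, n_max)) == math.comb(n_max + n_species, n_species)

    def test_specific_state_encodable(self, model3):
        chain = build_ctmc(model3, 5)
        q = (1, 0, 1, 1)  # 1 KinU, 0 KinA, 1 Activator, 1 Inhibitor
        assert q in chain.index
        assert chain.phi(chain.index[q]) == {"KinU", "Activator", "Inhibitor"}

    def test_rates_recomputable_from_mass_action(self, model3):
        chain = build_ctmc(model3, 4)
        sidx = {s: i for i, s in enumerate(model3.species)}
        for i, outs in enumerate(chain.transitions):
            q = chain.states[i]
            for j, ridx, rate in outs:
                r = model3.reactions[ridx]
                expected = r.rate_constant
                for s, c in r.reactants:
                    expected *= q[sidx[s]]
                assert rate == pytest.approx(expected)

    def test_cap_respected(self):
        net = co.parse_network("A -> A + A ; 1.0")
        chain = build_ctmc(net, 3)
        # state (3,) cannot grow further: its only transition would exceed the cap
        assert chain.transitions[chain.index[(3,)]] == []

    def test_state_cap_guard(self, model3):
        with pytest.raises(ValueError, match="cap"):
            build_ctmc(model3, 100, state_cap=1000)

    def test_initial_state_validated(self, model3):
        chain = build_ctmc(model3, 5, initial={"KinU": 2, "Activator": 3})
        assert chain.initial == (2, 0, 3, 0)
        with pytest.raises(ValueError):
            build_ctmc(model3, 5, initial={"KinU": 6})


class TestSCC:
    def test_pure_decay_network(self):
        net = co.parse_network("A -> ; 1.0")
        chain = build_ctmc(net, 1)
        d = scc_decomposition(chain)
        assert len(d.components) == 2
        assert sum(d.bottom) == 1
        bottom_fp = [d.footprint[k] for k in d.bsccs()]
        assert bottom_fp == [frozenset()]

    def test_reversible_pair_single_bottom_scc(self):
        net = co.parse_network("A -> B ; 1.0\nB -> A ; 1.0")
        chain = build_ctmc(net, 1)
        d = scc_decomposition(chain)
        two_state = [c for c in d.components if len(c) == 2]
        assert len(two_state) == 1
        k = d.components.index(two_state[0])
        assert d.bottom[k]
        assert d.footprint[k] == {"A", "B"}

    def test_model3_states_without_kinu_inhibitor_are_absorbing(self, model3):
        chain = build_ctmc(model3, 3)
        d = scc_decomposition(chain)
        for i, q in enumerate(chain.states):
            if q[0] == 0 and q[3] == 0:  # KinU = Inhibitor = 0
                k = d.component_of[i]
                assert d.components[k] == [i] and d.bottom[k]

    def test_every_bscc_is_good(self, model3):
        chain = build_ctmc(model3, 5)
        d = scc_decomposition(chain)
        good = set(good_sccs(d, chain))
        assert set(d.bsccs()) <= good

    def test_transient_singleton_with_exit_not_good(self):
        net = co.parse_network("A -> B ; 1.0")
        chain = build_ctmc(net, 1)
        d = scc_decomposition(chain)
        good = set(good_sccs(d, chain))
        i = chain.index[(1, 0)]
        assert d.component_of[i] not in good

    def test_reversible_component_is_good(self):
        net = co.parse_network("A -> B ; 1.0\nB -> A ; 1.0")
        chain = build_ctmc(net, 1)
        d = scc_decomposition(chain)
        two_state = [k for k, c in enumerate(d.components) if len(c) == 2]
        assert set(two_state) <= set(good_sccs(d, chain))


class TestDiscreteOrganizations:
    def test_model3_matches_static_analysis(self, model3):
        chain = build_ctmc(model3, 5)
        dorgs = {o.members for o in discrete_organizations(chain)}
        static = {o.members for o in co.enumerate_organizations(model3).organizations}
        assert dorgs == static == {
            frozenset(), frozenset({"Activator"}), frozenset({"KinA"}),
            frozenset({"Activator", "KinA"})}

    def test_decay_chain(self):
        net = co.parse_network("A -> B ; 1.0")
        chain = build_ctmc(net, 1)
        assert {o.members for o in discrete_organizations(chain)} == {
            frozenset(), frozenset({"B"})}

    def test_no_reaction_singletons(self):
        net = co.parse_network("species: X\nX -> X ; 1.0")
        chain = build_ctmc(net, 1)
        assert {o.members for o in discrete_organizations(chain)} == {
            frozenset(), frozenset({"X"})}

    def test_bscc_footprints_always_returned(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_network(rng, max_species=3, max_reactions=4)
            chain = build_ctmc(net, 3)
            d = scc_decomposition(chain)
            dorgs = {o.members for o in discrete_organizations(chain, d)}
            for k in d.bsccs():
                assert d.footprint[k] in dorgs


class TestInternalGenerator:
    def test_bscc_states_generate_their_footprint(self, model3):
        chain = build_ctmc(model3, 3)
        d = scc_decomposition(chain)
        for k in d.bsccs():
            fp = d.footprint[k]
            for i in d.components[k][:3]:
                assert is_internal_generator(chain, chain.states[i], fp)

    def test_lone_activator_state(self, model3):
        chain = build_ctmc(model3, 3)
        assert is_internal_generator(chain, (0, 0, 1, 0), {"Activator"})

    def test_kinu_state_does_not_generate_kinu_set(self, model3):
        chain = build_ctmc(model3, 3)
        assert not is_internal_generator(chain, (1, 0, 1, 0), {"Activator", "KinU"})


class TestCoarseChain:
    def test_phi_blocks_cover_and_bound(self, model3):
        chain = build_ctmc(model3, 10)
        blocks, labels = lump_by_phi(chain)
        assert sum(len(b) for b in blocks) == 1001
        assert len(blocks) <= 16
        empty = labels.index(frozenset())
        assert blocks[empty] == [chain.index[(0, 0, 0, 0)]]

    def test_nmax1_blocks_are_singletons(self, model3):
        chain = build_ctmc(model3, 1)
        blocks, _ = lump_by_phi(chain)
        assert all(len(b) == 1 for b in blocks)

    def test_exponential_holding_time(self):
        net = co.parse_network("A -> B ; 2.0")
        chain = build_ctmc(net, 1)
        i = chain.index[(1, 0)]
        t = expected_leaving_time(chain, [i])
        assert t[0] == pytest.approx(0.5)

    def test_two_state_transient_chain_closed_form(self):
        # A=2 -> A=1 -> A=0 with rates 2*lam, lam: E[T_exit from top] = 1/(2lam) + 1/lam
        net = co.parse_network("A -> ; 0.5")
        chain = build_ctmc(net, 2)
        block = [chain.index[(2,)], chain.index[(1,)]]
        t = expected_leaving_time(chain, block)
        by_state = dict(zip(sorted(block), t))  # results follow sorted state order
        assert by_state[chain.index[(1,)]] == pytest.approx(2.0)
        assert by_state[chain.index[(2,)]] == pytest.approx(1.0 + 2.0)

    def test_model3_organization_blocks_never_left(self, model3):
        chain = build_ctmc(model3, 5)
        blocks, labels = lump_by_phi(chain)
        for o in discrete_organizations(chain):
            t = expected_leaving_time(chain, blocks[labels.index(o.members)])
            assert np.isinf(t).all()

    def test_jump_rows_sum_to_one_for_escaping_blocks(self, model3):
        chain = build_ctmc(model3, 4)
        coarse = block_transition_probabilities(chain)
        for b, jumps in enumerate(coarse.jump_probabilities):
            t = coarse.leaving_times[b]
            if np.isfinite(t).all() and jumps:
                assert sum(jumps.values()) == pytest.approx(1.0, abs=1e-9)

    def test_absorbing_block_has_no_jumps(self, model3):
        chain = build_ctmc(model3, 4)
        coarse = block_transition_probabilities(chain)
        b = coarse.labels.index(frozenset({"Activator", "KinA"}))
        assert coarse.jump_probabilities[b] == {}
        assert np.isinf(coarse.leaving_times[b]).all()

    def test_single_event_reachability_from_i_kinu_block(self, model3):
        chain = build_ctmc(model3, 6)
        coarse = block_transition_probabilities(chain)
        b = coarse.labels.index(frozenset({"Inhibitor", "KinU"}))
        successors = {frozenset(coarse.labels[t]) for t in coarse.jump_probabilities[b]}
        # one reaction event from {I, KinU} states can only add KinA (attachment)
        # or turn I into A (relaxation)
        for s in successors:
            assert s <= {"Inhibitor", "KinU", "KinA", "Activator"}
            assert ("KinA" in s) or ("Activator" in s)

    def test_three_block_linear_chain_absorption(self):
        # one-directional chain A=2 -> A=1 -> A=0; from block {A=2} the first
        # foreign block visited is always {A=1}
        net = co.parse_network("A -> ; 1.0")
        chain = build_ctmc(net, 2)
        blocks = [[chain.index[(2,)]], [chain.index[(1,)]], [chain.index[(0,)]]]
        labels = [frozenset({"A2"}), frozenset({"A1"}), frozenset({"A0"})]
        coarse = block_transition_probabilities(chain, blocks, labels)
        assert coarse.jump_probabilities[0] == pytest.approx({1: 1.0})
        assert coarse.jump_probabilities[1] == pytest.approx({2: 1.0})
        assert coarse.jump_probabilities[2] == {}


class TestExport:
    def test_dot_uses_index_and_counts_convention(self, model3):
        chain = build_ctmc(model3, 1)
        dot = state_graph_to_dot(chain)
        assert '0 (0,0,0,0)' in dot
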