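"""Synchronous Boolean dynamics: rule construction, updates, attractors."""

import itertools

import numpy as np
import pytest
import sympy

import boolprune as bp
from boolprune import CYCLE, FIXED_POINT, TRUNCATED
from boolprune.engine import build_rules, run_to_attractor, update_state


def all_states(nodes):
    for bits in itertools.product((0, 1), repeat=len(nodes)):
        yield dict(zip(nodes, bits))


class TestToySystem:
    """The didactic three-node system a=b AND c, b=NOT b, c=a OR b."""

    def test_printed_polynomials(self, toy_model):
        a, b, c = toy_model.symbols
        assert sympy.expand(toy_model.polynomials["a"] - b * c) == 0
        assert sympy.expand(toy_model.polynomials["b"] - (1 - b)) == 0
        assert sympy.expand(toy_model.polynomials["c"] - (a + b - a * b)) == 0

    def test_hand_evaluated_step(self, toy_model):
        nxt = update_state(toy_model, {"a": 0, "b": 0, "c": 1})
        assert nxt == {"a": 0, "b": 1, "c": 0}

    def test_every_initial_state_is_cyclic(self, toy_model):
        # the negation self-loop b' = 1 - b denies any fixed point
        for state in all_states(toy_model.nodes):
            traj = run_to_attractor(toy_model, state)
            assert traj.outcome == CYCLE
            assert traj.cycle_length >= 2


class TestBuildRules:
    def test_activators_and_inhibitors_from_edges(self):
        pkn = bp.SignedDigraph.from_edges(
            [("u", "x", 1), ("v", "x", 1), ("w", "x", -1)]
        )
        rules = build_rules(pkn)
        assert rules.activators["x"] == {"u", "v"}
        assert rules.inhibitors["x"] == {"w"}

    def test_inputs_from_pkn_in_degree(self, small_instance):
        rules = build_rules(small_instance.pkn)
        deg = small_instance.pkn.in_degree()
        assert rules.inputs == frozenset(n for n, d in deg.items() if d == 0)

    def test_input_flags_inherited_by_pruned_subnetwork(self, small_instance):
        empty = small_instance.pkn.with_edges([])
        rules = build_rules(small_instance.pkn, empty)
        # pruning away all regulators must not promote nodes to inputs
        assert rules.inputs == build_rules(small_instance.pkn).inputs

    def test_foreign_edge_rejected(self, small_instance):
        pkn = small_instance.pkn
        nodes = sorted(pkn.nodes)
        foreign = None
        for s in nodes:
            for t in nodes:
                for g in (1, -1):
                    if (s, t, g) not in pkn.edges:
                        foreign = (s, t, g)
                        break
        sub = bp.SignedDigraph(nodes=pkn.nodes, edges=frozenset({foreign}))
        with pytest.raises(ValueError, match="absent from the PKN"):
            build_rules(pkn, sub)

    def test_node_set_must_match(self, small_instance):
        smaller = bp.SignedDigraph.from_edges([], nodes=["G01"])
        with pytest.raises(ValueError, match="node set"):
            build_rules(small_instance.pkn, smaller)


class TestUpdateState:
    def test_active_inhibitor_dominates(self):
        pkn = bp.SignedDigraph.from_edges([("u", "x", 1), ("w", "x", -1)])
        rules = build_rules(pkn)
        nxt = update_state(rules, {"u": 1, "w": 1, "x": 0})
        assert nxt["x"] == 0
        nxt = update_state(rules, {"u": 1, "w": 0, "x": 0})
        assert nxt["x"] == 1

    def test_dual_sign_edge_inhibitor_wins(self):
        pkn = bp.SignedDigraph.from_edges([("u", "x", 1), ("u", "x", -1)])
        rules = build_rules(pkn)
        assert update_state(rules, {"u": 1, "x": 0})["x"] == 0

    def test_no_activators_means_constant_zero(self):
        pkn = bp.SignedDigraph.from_edges([("u", "x", 1), ("x", "y", 1)])
        rules = build_rules(pkn, pkn.with_edges([("u", "x", 1)]))
        # y kept its PKN regulator status but lost all activators
        assert update_state(rules, {"u": 1, "x": 1, "y": 1})["y"] == 0

    def test_input_holds_state(self):
        pkn = bp.SignedDigraph.from_edges([("u", "x", 1)])
        rules = build_rules(pkn)
        assert update_state(rules, {"u": 1, "x": 0})["u"] == 1
        assert update_state(rules, {"u": 0, "x": 1})["u"] == 0

    def test_inputs_hold_state_false_forces_strict_rule(self):
        pkn = bp.SignedDigraph.from_edges([("u", "x", 1)])
        rules = build_rules(pkn, inputs_hold_state=False)
        assert update_state(rules, {"u": 1, "x": 0})["u"] == 0

    def test_missing_gene_raises(self):
        pkn = bp.SignedDigraph.from_edges([("u", "x", 1)])
        rules = build_rules(pkn)
        with pytest.raises(KeyError, match="x"):
            update_state(rules, {"u": 1})

    def test_determinism(self, small_instance):
        rules = build_rules(small_instance.pkn)
        state = {n: i % 2 for i, n in enumerate(rules.nodes)}
        assert update_state(rules, state) == update_state(rules, dict(state))


class TestRunToAttractor:
    def test_all_inputs_fixed_in_zero_steps(self):
        pkn = bp.SignedDigraph.from_edges([], nodes=["a", "b"])
        rules = build_rules(pkn)
        traj = run_to_attractor(rules, {"a": 1, "b": 0})
        assert traj.outcome == FIXED_POINT
        assert traj.steps_taken == 0
        assert traj.attractor_state == {"a": 1, "b": 0}

    def test_two_node_chain_reaches_fixed_point_in_one_step(self):
        pkn = bp.SignedDigraph.from_edges([("A", "B", 1)])
        rules = build_rules(pkn)
        traj = run_to_attractor(rules, {"A": 1, "B": 0})
        assert traj.outcome == FIXED_POINT
        assert traj.steps_taken == 1
        assert traj.attractor_state == {"A": 1, "B": 1}

    def test_truncation_reports_max_steps(self):
        # a 4-node activation chain needs 3 updates from (1,0,0,0)
        pkn = bp.SignedDigraph.from_edges(
            [("A", "B", 1), ("B", "C", 1), ("C", "D", 1)]
        )
        rules = build_rules(pkn)
        x0 = {"A": 1, "B": 0, "C": 0, "D": 0}
        traj = run_to_attractor(rules, x0, max_steps=2)
        assert traj.outcome == TRUNCATED
        assert traj.steps_taken == 2
        # the fixed point emerges after 3 updates; a 4th certifies it
        confirmed = run_to_attractor(rules, x0, max_steps=4)
        assert confirmed.outcome == FIXED_POINT
        assert confirmed.steps_taken == 3

    def test_mutual_activation_period_two_cycle(self):
        pkn = bp.SignedDigraph.from_edges([("A", "B", 1), ("B", "A", 1)])
        rules = build_rules(pkn)
        traj = run_to_attractor(rules, {"A": 1, "B": 0})
        assert traj.outcome == CYCLE
        assert traj.cycle_length == 2

    def test_fixed_point_certificate(self, small_instance):
        """One extra update leaves every reported fixed point unchanged."""
        rules = build_rules(small_instance.pkn)
        for state in all_states(rules.nodes):
            traj = run_to_attractor(rules, state)
            if traj.outcome == FIXED_POINT:
                assert update_state(rules, traj.attractor_state) == traj.attractor_state

    def test_trajectory_length_bounded(self, small_instance):
        rules = build_rules(small_instance.pkn)
        for state in itertools.islice(all_states(rules.nodes), 16):
            traj = run_to_attractor(rules, state, max_steps=5)
            assert traj.steps_taken <= 5


def _brute_force_classify(model, x0, nodes):
    """Independent oracle: explicit walk storing every visited state."""
    seen = {tuple(x0[n] for n in nodes): 0}
    state = dict(x0)
    t = 0
    while True:
        nxt = update_state(model, state)
        if nxt == state:
            return FIXED_POINT, state
        key = tuple(nxt[n] for n in nodes)
        if key in seen:
            return CYCLE, None
        t += 1
        seen[key] = t
        state = nxt


@pytest.mark.parametrize("subnetwork_seed", [0, 1, 2])
def test_attractor_classification_matches_brute_force(
    small_instance, subnetwork_seed
):
    """Full state-space agreement with an explicit reachability walk."""
    rng = np.random.default_rng(subnetwork_seed)
    sub = bp.random_subnetwork(small_instance.pkn, 0.6, rng)
    rules = build_rules(small_instance.pkn, sub)
    for state in all_states(rules.nodes):
        expected_outcome, expected_fp = _brute_force_classify(
            rules, state, rules.nodes
        )
        traj = run_to_attractor(rules, state)
        assert traj.outcome == expected_outcome
        if expected_outcome == FIXED_POINT:
            assert traj.attractor_state == expected_fp


def test_polynomial_and_logical_updates_agree(small_instance, toggle):
    """The algebraic encoding (OR as a+b-ab, NOT as 1-x) equals the logical
    rule on every state of every small network."""
    nets = [
        (small_instance.pkn, small_instance.pkn),
        (small_instance.pkn, small_instance.true_subnetwork),
        (toggle[0], toggle[0]),
    ]
    for pkn, sub in nets:
        rules = build_rules(pkn, sub)
        for state in all_states(rules.nodes):
            x = rules.state_to_array(state)
            assert np.array_equal(
                rules.update_array(x), rules.polynomial_update_array(x)
            )


def test_rules_text_export(small_instance):
    rules = build_rules(small_instance.pkn)
    text = rules.to_text()
    for node in rules.inputs:
        assert f"{node} = INPUT" in text
    assert text.count("\n") == len(rules.nodes)
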