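"""Synchronous update rule, attractor computation, and the perturbation screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pluriscreen.boolean_dynamics import (
    Clamp,
    DynamicCoreTooLarge,
    UpdateSemantics,
    compute_attractors,
    node_columns,
    perturbation_screen,
    synchronous_step,
)
from pluriscreen.network import SignedNetwork, network_from_edges

from conftest import attractor_keys, brute_force_attractors, random_signed_network


@pytest.fixture
def mutual_pair():
    return network_from_edges([("A", "B", "+"), ("B", "A", "+")])


class TestSynchronousStep:
    def test_mutual_activation_all_on_is_fixed(self, mutual_pair):
        assert synchronous_step({"A": 1, "B": 1}, mutual_pair) == {"A": 1, "B": 1}

    def test_mutual_activation_swaps_mixed_state(self, mutual_pair):
        assert synchronous_step({"A": 0, "B": 1}, mutual_pair) == {"A": 1, "B": 0}

    def test_inhibitor_dominates_active_activator(self):
        net = network_from_edges([("A", "X", "+"), ("B", "X", "-")])
        nxt = synchronous_step({"A": 1, "B": 1, "X": 0}, net)
        assert nxt["X"] == 0

    def test_input_free_node_keeps_value(self):
        net = network_from_edges([("A", "X", "+")])
        assert synchronous_step({"A": 1, "X": 0}, net)["A"] == 1
        assert synchronous_step({"A": 0, "X": 0}, net)["A"] == 0

    def test_clamped_node_holds_clamp_value(self, mutual_pair):
        nxt = synchronous_step({"A": 1, "B": 1}, mutual_pair, (Clamp("A", 0),))
        assert nxt["A"] == 0

    def test_inhibitor_only_node_semantics_switch(self):
        net = network_from_edges([("A", "X", "-")])
        state = {"A": 0, "X": 0}
        assert synchronous_step(state, net)["X"] == 0
        sustain = UpdateSemantics(inhibitor_only_sustain=True)
        assert synchronous_step(state, net, semantics=sustain)["X"] == 1
        assert synchronous_step({"A": 1, "X": 1}, net, semantics=sustain)["X"] == 0

    def test_partial_state_rejected(self, mutual_pair):
        with pytest.raises(ValueError, match="not total"):
            synchronous_step({"A": 1}, mutual_pair)


class TestComputeAttractors:
    def test_mutual_pair_has_two_fixed_points_and_a_cycle(self, mutual_pair):
        found = attractor_keys(compute_attractors(mutual_pair), mutual_pair.nodes)
        assert found == {
            (((0, 0)),),
            (((1, 1)),),
            ((0, 1), (1, 0)),
        }

    def test_mutual_pair_clamped_high_collapses_to_one_fixed_point(self, mutual_pair):
        found = compute_attractors(mutual_pair, (Clamp("A", 1),))
        assert len(found) == 1
        assert found[0].kind == "fixed"
        assert found[0].states[0] == {"A": 1, "B": 1}

    def test_free_inputs_conditioned_over_both_values(self):
        net = network_from_edges([("I", "X", "+"), ("X", "X", "+")])
        found = compute_attractors(net)
        # input off: X off or on (self-loop); input on: X on after transient
        keys = attractor_keys(found, net.nodes)
        assert keys == {((0, 0),), ((0, 1),), ((1, 1),)}

    def test_ceiling_raises_instead_of_partial_result(self):
        edges = [(f"N{i}", f"N{(i + 1) % 8}", "+") for i in range(8)]
        net = network_from_edges(edges)
        with pytest.raises(DynamicCoreTooLarge, match="core_ceiling"):
            compute_attractors(net, core_ceiling=4)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_attractors(SignedNetwork())

    def test_matches_brute_force_on_random_networks(self):
        """Reduced-core enumeration is exact on random signed networks."""
        rng = np.random.default_rng(2024)
        for _ in range(30):
            net = random_signed_network(rng, n_min=3, n_max=9)
            clamps = ()
            if rng.random() < 0.5:
                node = net.nodes[int(rng.integers(0, len(net)))]
                clamps = (Clamp(node, int(rng.integers(0, 2))),)
            expected = brute_force_attractors(net, clamps)
            found = attractor_keys(compute_attractors(net, clamps), net.nodes)
            assert found == expected

    def test_matches_brute_force_under_sustain_semantics(self):
        rng = np.random.default_rng(77)
        semantics = UpdateSemantics(inhibitor_only_sustain=True)
        for _ in range(10):
            net = random_signed_network(rng, n_min=3, n_max=8)
            expected = brute_force_attractors(net, inhibitor_only_sustain=True)
            found = attractor_keys(
                compute_attractors(net, semantics=semantics), net.nodes
            )
            assert found == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_attractors_are_closed_and_recurrent(self, seed):
        """Stepping any attractor state |states| times returns to itself."""
        rng = np.random.default_rng(seed)
        net = random_signed_network(rng, n_min=3, n_max=8)
        clamps = ()
        if rng.random() < 0.5:
            node = net.nodes[int(rng.integers(0, len(net)))]
            clamps = (Clamp(node, int(rng.integers(0, 2))),)
        for attractor in compute_attractors(net, clamps):
            for i, state in enumerate(attractor.states):
                expected_next = attractor.states[(i + 1) % len(attractor.states)]
                assert synchronous_step(state, net, clamps) == expected_next
            rolled = dict(attractor.states[0])
            for _ in range(len(attractor.states)):
                rolled = synchronous_step(rolled, net, clamps)
            assert rolled == attractor.states[0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_clamped_nodes_hold_their_value_in_every_state(self, seed):
        rng = np.random.default_rng(seed)
        net = random_signed_network(rng, n_min=3, n_max=8)
        node = net.nodes[int(rng.integers(0, len(net)))]
        value = int(rng.integers(0, 2))
        for attractor in compute_attractors(net, (Clamp(node, value),)):
            for state in attractor.states:
                assert state[node] == value

    def test_deterministic_output_order(self):
        rng = np.random.default_rng(5)
        net = random_signed_network(rng, n_min=6, n_max=6)
        first = compute_attractors(net)
        second = compute_attractors(net)
        assert first == second


class TestPerturbationScreen:
    def test_row_count_for_unique_fixed_points(self):
        """Every clamp of a simple cascade yields exactly one fixed point."""
        net = network_from_edges([("A", "B", "+"), ("B", "C", "+")])
        matrix = perturbation_screen(net, model_id="toy")
        # regulatory nodes: A, B; 2 clamps each; A clamped leaves B..: need
        # every run to give exactly one attractor for the count to be 2*2
        assert set(matrix["clamped_node"]) == {"A", "B"}
        grouped = matrix.groupby(["clamped_node", "clamp_value"]).size()
        assert (grouped >= 1).all()

    def test_clamped_column_equals_clamp_value(self, core_network):
        matrix = perturbation_screen(core_network, model_id="core")
        for (node, value), group in matrix.groupby(["clamped_node", "clamp_value"]):
            assert (group[node] == value).all()

    def test_matrix_equals_brute_force_on_toy_model(self):
        """Screen rows match a naive full-state-space oracle, run by run."""
        net = network_from_edges(
            [("A", "B", "+"), ("B", "A", "+"), ("A", "C", "-"), ("C", "D", "+")]
        )
        matrix = perturbation_screen(net, model_id="toy4")
        nodes = net.nodes
        for node in net.regulatory_nodes():
            for value in (0, 1):
                expected = brute_force_attractors(net, (Clamp(node, value),))
                got = matrix[
                    (matrix["clamped_node"] == node) & (matrix["clamp_value"] == value)
                ]
                got_states = {
                    tuple(row) for row in got[nodes].itertuples(index=False)
                }
                expected_states = {s for cycle in expected for s in cycle}
                assert got_states == expected_states

    def test_identical_runs_are_byte_identical(self, core_network):
        a = perturbation_screen(core_network, model_id="core")
        b = perturbation_screen(core_network, model_id="core")
        assert a.equals(b)

    def test_summary_encoding_marks_oscillations(self, mutual_pair):
        matrix = perturbation_screen(mutual_pair, model_id="pair", encoding="summary")
        assert set(np.unique(matrix[node_columns(matrix)].to_numpy())) <= {0.0, 0.5, 1.0}

    def test_unknown_encoding_rejected(self, mutual_pair):
        with pytest.raises(ValueError, match="encoding"):
            perturbation_screen(mutual_pair, encoding="ternary")
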