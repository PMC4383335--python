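"""Network model: transfer function, propagation, plasticity, resets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modevo.network import (NetworkState, activation_function, decide_eat,
                            random_genome, zero_genome, LAYER_SIZES,
                            MAX_CONNECTIONS, N_LAYERS)

from conftest import chain_genome, genome_with


class TestActivationFunction:
    def test_zero_maps_to_zero(self):
        assert activation_function(0.0) == 0.0

    @given(st.floats(-50, 50, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_odd_and_bounded(self, x):
        y = activation_function(x)
        assert -1.0 <= y <= 1.0
        assert activation_function(-x) == pytest.approx(-y)

    def test_monotone(self):
        xs = np.linspace(-3, 3, 101)
        ys = [activation_function(x) for x in xs]
        assert all(a < b for a, b in zip(ys, ys[1:]))

    def test_saturates(self):
        assert activation_function(100.0) == pytest.approx(1.0, abs=1e-6)
        assert activation_function(-100.0) == pytest.approx(-1.0, abs=1e-6)

    def test_rejects_non_finite(self):
        for bad in (float("nan"), float("inf"), -float("inf")):
            with pytest.raises(ValueError):
                activation_function(bad)


def _phi(x, lam=5.0):
    return math.tanh(lam * x)


class TestForwardPass:
    def test_all_zero_network_outputs_zero(self):
        state = NetworkState(zero_genome())
        assert state.forward_pass(np.ones(10)) == 0.0

    def test_single_chain_composition(self):
        state = NetworkState(chain_genome(1.0))
        x = np.zeros(10)
        x[0] = 1.0
        expected = _phi(_phi(_phi(_phi(1.0))))
        assert state.forward_pass(x) == pytest.approx(expected, abs=1e-12)

    def test_wrong_input_length_rejected(self):
        state = NetworkState(zero_genome())
        with pytest.raises(ValueError):
            state.forward_pass(np.zeros(9))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_matrix_oracle(self, seed):
        """Independent oracle: explicit dense per-layer matrix evaluation."""
        rng = np.random.default_rng(seed)
        genome = random_genome(rng, connection_prob=20 / 150,
                               modulatory_prob=0.3)
        state = NetworkState(genome)
        inputs = rng.uniform(-1, 1, 10)

        # oracle: build dense matrices straight from the genome
        acts = {(0, i): inputs[i] for i in range(10)}
        mods = {}
        is_mod = {(n.layer, n.index): n.is_modulatory for n in genome.neurons}
        bias = {(n.layer, n.index): n.bias for n in genome.neurons}
        for layer in range(1, N_LAYERS):
            for i in range(LAYER_SIZES[layer]):
                s_act, s_mod = bias[(layer, i)], 0.0
                for c in genome.connections:
                    if c.target == (layer, i):
                        if is_mod[c.source]:
                            s_mod += c.weight * acts[c.source]
                        else:
                            s_act += c.weight * acts[c.source]
                acts[(layer, i)] = _phi(s_act)
                mods[(layer, i)] = _phi(s_mod)

        out = state.forward_pass(inputs)
        assert out == pytest.approx(acts[(N_LAYERS - 1, 0)], abs=1e-12)
        for (layer, i), a in acts.items():
            assert state.activations[layer, i] == pytest.approx(a, abs=1e-12)
        for (layer, i), m in mods.items():
            assert state.modulation[layer, i] == pytest.approx(m, abs=1e-12)


class TestModulation:
    def test_no_modulatory_inputs_gives_zero(self):
        state = NetworkState(chain_genome())
        state.forward_pass(np.ones(10))
        assert state.compute_modulation(1, 0) == 0.0
        assert np.all(state.modulation[1:, :] == 0.0)

    def test_single_modulatory_connection(self):
        # input 0 is modulatory and drives neuron (1, 0) with weight 1
        genome = genome_with([((0, 0), (1, 0), 1.0)], modulatory=[(0, 0)])
        state = NetworkState(genome)
        x = np.zeros(10)
        x[0] = 1.0
        state.forward_pass(x)
        assert state.compute_modulation(1, 0) == pytest.approx(_phi(1.0))
        assert state.modulation[1, 0] == pytest.approx(_phi(1.0))

    def test_disabled_neuromodulation_forces_one(self):
        genome = genome_with([((0, 0), (1, 0), 1.0)], modulatory=[(0, 0)])
        state = NetworkState(genome, neuromodulation_enabled=False)
        state.forward_pass(np.zeros(10))
        assert state.compute_modulation(1, 0) == 1.0
        for layer in range(1, len(LAYER_SIZES)):
            assert np.all(state.modulation[layer, :LAYER_SIZES[layer]] == 1.0)


class TestPlasticity:
    def _state_with_plastic_connection(self, weight=0.0):
        genome = genome_with([((0, 0), (1, 0), weight)])
        return NetworkState(genome)

    def test_zero_modulation_freezes_all_weights(self):
        rng = np.random.default_rng(0)
        genome = random_genome(rng, connection_prob=0.4, modulatory_prob=0.0)
        state = NetworkState(genome)
        before = state.plastic_weights()
        for _ in range(10):
            state.forward_pass(rng.uniform(-1, 1, 10))
            state.apply_plasticity()
        # no modulatory neurons anywhere -> m = phi(0) = 0 -> frozen
        assert np.array_equal(state.plastic_weights(), before)

    def test_hebbian_worked_example_positive(self):
        state = self._state_with_plastic_connection(0.0)
        state.activations[0, 0] = 1.0
        state.activations[1, 0] = 1.0
        state.modulation[1, 0] = 1.0
        state.apply_plasticity()
        assert state.w_act[0, 0, 0] == pytest.approx(0.04)

    def test_hebbian_worked_example_negative(self):
        state = self._state_with_plastic_connection(0.0)
        state.activations[0, 0] = -1.0
        state.activations[1, 0] = 1.0
        state.modulation[1, 0] = 1.0
        state.apply_plasticity()
        assert state.w_act[0, 0, 0] == pytest.approx(-0.04)

    def test_update_clamps_at_one(self):
        state = self._state_with_plastic_connection(0.99)
        state.activations[0, 0] = 1.0
        state.activations[1, 0] = 1.0
        state.modulation[1, 0] = 1.0
        state.apply_plasticity()
        assert state.w_act[0, 0, 0] == 1.0

    def test_modulatory_connections_never_change(self):
        genome = genome_with([((0, 0), (1, 0), 0.5), ((0, 1), (1, 0), 0.25)],
                             modulatory=[(0, 1)])
        state = NetworkState(genome)
        rng = np.random.default_rng(3)
        for _ in range(20):
            state.forward_pass(rng.uniform(-1, 1, 10))
            state.apply_plasticity()
        assert state.w_mod[0, 0, 1] == 0.25

    def test_learning_disabled_is_identity(self):
        rng = np.random.default_rng(1)
        genome = random_genome(rng, connection_prob=0.3, modulatory_prob=0.3)
        state = NetworkState(genome, learning_enabled=False)
        before = state.plastic_weights()
        outs = [state.forward_pass(np.ones(10)) for _ in range(5)]
        state.apply_plasticity()
        assert np.array_equal(state.plastic_weights(), before)
        assert len(set(outs)) == 1

    def test_pure_hebbian_mode(self):
        """Without neuromodulation the update is dw = eta * a_i * a_j."""
        genome = genome_with([((0, 0), (1, 0), 0.0)])
        state = NetworkState(genome, neuromodulation_enabled=False)
        x = np.zeros(10)
        x[0] = 0.5
        state.forward_pass(x)
        a_post = state.activations[1, 0]
        state.apply_plasticity()
        assert state.w_act[0, 0, 0] == pytest.approx(0.04 * a_post * 0.5)


class TestBounds:
    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_state_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        genome = random_genome(rng, connection_prob=0.5, modulatory_prob=0.3)
        state = NetworkState(genome)
        for _ in range(30):
            state.forward_pass(rng.uniform(-1, 1, 10))
            state.apply_plasticity()
        assert np.all(np.abs(state.activations) <= 1.0)
        assert np.all(np.abs(state.modulation) <= 1.0)
        assert np.all(np.abs(state.plastic_weights()) <= 1.0)


class TestDecideEat:
    @pytest.mark.parametrize("output,expected",
                             [(0.3, True), (0.0, False), (-0.7, False),
                              (1e-9, True)])
    def test_threshold(self, output, expected):
        assert decide_eat(output) is expected


class TestReset:
    def test_genetic_reset_restores_genome_weights(self, rng):
        genome = random_genome(rng, connection_prob=0.4, modulatory_prob=0.2)
        state = NetworkState(genome)
        state.reset_plastic_weights("randomize", rng)
        state.reset_plastic_weights("genetic")
        expected = {(c.source, c.target): c.weight for c in genome.connections}
        for c in genome.connections:
            (sl, si), (_, ti) = c.source, c.target
            if not state.modulatory[sl, si]:
                assert state.w_act[sl, ti, si] == expected[(c.source, c.target)]

    def test_randomize_is_reproducible_and_bounded(self, rng):
        genome = random_genome(rng, connection_prob=0.4)
        s1 = NetworkState(genome)
        s2 = NetworkState(genome)
        s1.reset_plastic_weights("randomize", np.random.default_rng(7))
        s2.reset_plastic_weights("randomize", np.random.default_rng(7))
        assert np.array_equal(s1.plastic_weights(), s2.plastic_weights())
        assert np.all(np.abs(s1.plastic_weights()) <= 1.0)

    def test_unknown_mode_rejected(self, rng):
        state = NetworkState(random_genome(rng))
        with pytest.raises(ValueError):
            state.reset_plastic_weights("bogus", rng)

    def test_randomize_distribution_is_centered_uniform(self):
        genome = genome_with([((0, 0), (1, 0), 0.0)])
        state = NetworkState(genome)
        rng = np.random.default_rng(11)
        draws = np.empty(10_000)
        for k in range(draws.size):
            state.reset_plastic_weights("randomize", rng)
            draws[k] = state.w_act[0, 0, 0]
        se = np.sqrt(1 / 3 / draws.size)  # U(-1,1) has variance 1/3
        assert abs(draws.mean()) < 3 * se
        assert np.all(np.abs(draws) <= 1.0)


class TestGenomeStructure:
    def test_max_connection_count(self):
        sizes = LAYER_SIZES
        assert sum(a * b for a, b in zip(sizes, sizes[1:])) == MAX_CONNECTIONS == 150

    def test_serialization_round_trip(self, rng, tmp_path):
        from modevo.network import Genome

        genome = random_genome(rng, connection_prob=0.3, modulatory_prob=0.2)
        path = tmp_path / "g.json"
        genome.to_json(path)
        back = Genome.from_json(path)
        assert back.to_dict() == genome.to_dict()

    def test_graph_exports(self, rng, tmp_path):
        import networkx as nx

        genome = random_genome(rng, connection_prob=0.3)
        from modevo.network import to_networkx, write_dot, write_graphml

        g = to_networkx(genome)
        assert g.number_of_edges() == genome.connection_count
        assert g.nodes["L0N8"]["role"] == "reward_input"
        assert g.nodes["L0N0"]["role"] == "food_input"
        write_graphml(genome, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_edges() == genome.connection_count
        write_dot(genome, tmp_path / "g.dot")
        text = (tmp_path / "g.dot").read_text()
        assert text.startswith("digraph") and "->" in text
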