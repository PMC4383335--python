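"""PNSGA engine: objectives, dominance, mutation, and the generational loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modevo.evolution import (EvolutionConfig, Individual, MutationRates,
                              behavioral_diversity, connection_cost,
                              dominance_matrix, mutate, non_dominated_sort,
                              pnsga_generation, run_evolution,
                              stochastic_dominates)
from modevo.network import (LAYER_SIZES, MAX_CONNECTIONS, N_LAYERS,
                            random_genome, zero_genome)


def make_individual(perf, div, cost):
    ind = Individual(zero_genome())
    ind.performance, ind.diversity, ind.connection_cost = perf, div, cost
    return ind


class TestConnectionCost:
    def test_empty_genome(self):
        assert connection_cost(zero_genome()) == 0

    def test_fully_connected(self, rng):
        g = random_genome(rng, connection_prob=1.0)
        assert connection_cost(g) == MAX_CONNECTIONS == 150

    @pytest.mark.parametrize("p", [0.1, 0.5])
    def test_counts_connection_list(self, p, rng):
        g = random_genome(rng, connection_prob=p)
        assert connection_cost(g) == len(g.connections)


class TestBehavioralDiversity:
    def test_identical_population_has_zero_diversity(self):
        sigs = np.ones((5, 12), dtype=np.uint8)
        assert np.all(behavioral_diversity(sigs) == 0.0)

    def test_complementary_pair(self):
        sigs = np.array([[0, 0, 1, 1], [1, 1, 0, 0]], dtype=np.uint8)
        assert np.all(behavioral_diversity(sigs) == 1.0)

    def test_matches_pairwise_average_oracle(self):
        # pairwise Hamming fractions: (a,b)=0.5, (a,c)=0.25, (b,c)=0.75
        a = np.array([0, 0, 0, 0], dtype=np.uint8)
        b = np.array([1, 1, 0, 0], dtype=np.uint8)
        c = np.array([0, 0, 1, 0], dtype=np.uint8)
        div = behavioral_diversity(np.stack([a, b, c]))
        assert div[0] == pytest.approx((0.5 + 0.25) / 2)
        assert div[1] == pytest.approx((0.5 + 0.75) / 2)
        assert div[2] == pytest.approx((0.25 + 0.75) / 2)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            behavioral_diversity([np.zeros(3), np.zeros(4)])


class TestStochasticDominance:
    def test_p_one_is_deterministic_three_objective_dominance(self, rng):
        cfg = EvolutionConfig(p_cc=1.0, treatment="PCC",
                              population_size=4, generations=1)
        a = make_individual(0.9, 0.5, 10)
        b = make_individual(0.8, 0.5, 20)
        c = make_individual(0.9, 0.5, 5)
        for _ in range(20):
            assert stochastic_dominates(a, b, cfg, rng)
            assert not stochastic_dominates(b, a, cfg, rng)
            assert stochastic_dominates(c, a, cfg, rng)

    def test_p_zero_ignores_cost(self, rng):
        cfg = EvolutionConfig(p_cc=0.0, treatment="PCC",
                              population_size=4, generations=1)
        a = make_individual(0.5, 0.5, 1)
        b = make_individual(0.5, 0.5, 100)
        for _ in range(20):
            assert not stochastic_dominates(a, b, cfg, rng)

    def test_pa_treatment_never_uses_cost(self, rng):
        cfg = EvolutionConfig(treatment="PA", population_size=4, generations=1)
        a = make_individual(0.5, 0.5, 1)
        b = make_individual(0.5, 0.5, 100)
        assert not any(stochastic_dominates(a, b, cfg, rng)
                       for _ in range(50))

    def test_inclusion_frequency_matches_p(self):
        """Cost-only advantage wins with empirical frequency ~ p = 0.75."""
        rng = np.random.default_rng(123)
        cfg = EvolutionConfig(p_cc=0.75, treatment="PCC",
                              population_size=4, generations=1)
        a = make_individual(0.5, 0.5, 3)
        b = make_individual(0.5, 0.5, 9)
        n = 50_000
        wins = sum(stochastic_dominates(a, b, cfg, rng) for _ in range(n))
        # binomial 99% CI half-width around p=0.75
        half = 2.576 * np.sqrt(0.75 * 0.25 / n)
        assert abs(wins / n - 0.75) < half


class TestMutation:
    def test_add_to_saturated_genome_is_noop(self, rng):
        g = random_genome(rng, connection_prob=1.0)
        rates = MutationRates(add_connection=1.0, remove_connection=0.0,
                              perturb_weight=0.0, move_connection=0.0,
                              toggle_neuron_type=0.0)
        assert mutate(g, rates, rng).connection_count == 150

    def test_remove_from_empty_genome_is_noop(self, rng):
        rates = MutationRates(add_connection=0.0, remove_connection=1.0,
                              perturb_weight=0.0, move_connection=0.0,
                              toggle_neuron_type=0.0)
        assert mutate(zero_genome(), rates, rng).connection_count == 0

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariants_preserved_under_mutation(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genome(rng, connection_prob=0.3, modulatory_prob=0.3)
        rates = MutationRates(add_connection=0.5, remove_connection=0.5,
                              perturb_weight=0.3, move_connection=0.5,
                              toggle_neuron_type=0.3)
        for _ in range(5):
            g = mutate(g, rates, rng)
        g.validate()  # bounds, adjacency, no duplicates, output non-modulatory

    def test_add_rate_monte_carlo(self):
        rng = np.random.default_rng(321)
        g = random_genome(rng, connection_prob=0.3)
        rates = MutationRates(add_connection=0.2, remove_connection=0.0,
                              perturb_weight=0.0, move_connection=0.0,
                              toggle_neuron_type=0.0)
        n = 10_000
        added = sum(mutate(g, rates, rng).connection_count
                    == g.connection_count + 1 for _ in range(n))
        half = 2.576 * np.sqrt(0.2 * 0.8 / n)
        assert abs(added / n - 0.2) < half

    def test_mutation_does_not_modify_parent(self, rng):
        g = random_genome(rng, connection_prob=0.3)
        snapshot = g.to_dict()
        rates = MutationRates(add_connection=1.0, remove_connection=1.0,
                              perturb_weight=1.0, move_connection=1.0,
                              toggle_neuron_type=1.0)
        mutate(g, rates, rng)
        assert g.to_dict() == snapshot


class TestSorting:
    def test_front_matches_brute_force_oracle(self):
        """Deterministic (p=1) non-dominated front vs an O(N^2) oracle."""
        rng = np.random.default_rng(5)
        cfg = EvolutionConfig(p_cc=1.0, treatment="PCC",
                              population_size=40, generations=1)
        pop = [make_individual(rng.random(), rng.random(),
                               int(rng.integers(0, 150))) for _ in range(40)]
        dom = dominance_matrix(pop, cfg, rng)
        fronts = non_dominated_sort(dom)

        def dominates(a, b):
            ga = (a.performance, a.diversity, -a.connection_cost)
            gb = (b.performance, b.diversity, -b.connection_cost)
            return (all(x >= y for x, y in zip(ga, gb))
                    and any(x > y for x, y in zip(ga, gb)))

        oracle_front = {i for i, a in enumerate(pop)
                        if not any(dominates(b, a) for b in pop)}
        assert set(fronts[0]) == oracle_front

    def test_fronts_partition_population(self):
        rng = np.random.default_rng(6)
        cfg = EvolutionConfig(p_cc=0.75, treatment="PCC",
                              population_size=30, generations=1)
        pop = [make_individual(rng.random(), rng.random(),
                               int(rng.integers(0, 150))) for _ in range(30)]
        fronts = non_dominated_sort(dominance_matrix(pop, cfg, rng))
        all_idx = np.concatenate(fronts)
        assert sorted(all_idx) == list(range(30))


def _smoke_config(**kw):
    base = dict(population_size=12, generations=3, master_seed=7,
                treatment="PCC")
    base.update(kw)
    return EvolutionConfig(**base)


class TestGenerationLoop:
    def test_population_size_preserved(self):
        res = run_evolution(_smoke_config())
        assert len(res.population) == 12
        assert len(res.log) == 3
        for ind in res.population:
            ind.genome.validate()

    def test_elitist_selection_keeps_best_performer(self):
        """Non-dominated truncation never drops the top performer."""
        from modevo.evolution import _select

        rng = np.random.default_rng(1)
        cfg = _smoke_config(p_cc=0.0)
        pool = [make_individual(rng.random(), rng.random(),
                                int(rng.integers(0, 150)))
                for _ in range(2 * cfg.population_size)]
        survivors, _, _ = _select(pool, cfg, rng)
        assert len(survivors) == cfg.population_size
        best = max(pool, key=lambda i: i.performance)
        assert best in survivors

    def test_generation_reevaluates_survivors_on_shared_environments(self):
        """After a step, every individual carries this generation's
        evaluation (no stale scores from earlier environment draws)."""
        cfg = _smoke_config()
        rng = np.random.default_rng(2)
        from modevo.evolution import (assign_diversity, evaluate_individual)
        from modevo.environment import generation_environments
        from modevo.network import random_genome as rg

        pop = [Individual(rg(rng)) for _ in range(cfg.population_size)]
        envs = generation_environments(rng, 4)
        for ind in pop:
            evaluate_individual(ind, envs, cfg, rng, generation=0)
        assign_diversity(pop)
        nxt = pnsga_generation(pop, cfg, rng, generation=5)
        assert all(ind.evaluated_generation == 5 for ind in nxt)

    def test_bit_identical_replay(self):
        r1 = run_evolution(_smoke_config())
        r2 = run_evolution(_smoke_config())
        g1 = [ind.genome.to_dict() for ind in r1.population]
        g2 = [ind.genome.to_dict() for ind in r2.population]
        assert g1 == g2
        assert r1.log == r2.log
        assert r1.best.final_performance == r2.best.final_performance

    def test_pcc_with_p_zero_equals_pa(self):
        ra = run_evolution(_smoke_config(treatment="PA"))
        rb = run_evolution(_smoke_config(treatment="PCC", p_cc=0.0))
        assert [i.genome.to_dict() for i in ra.population] == \
               [i.genome.to_dict() for i in rb.population]

    def test_population_checkpoint_round_trip(self, tmp_path):
        from modevo.evolution import load_population, save_population

        res = run_evolution(_smoke_config())
        path = tmp_path / "pop.json"
        save_population(res.population, path)
        back = load_population(path)
        assert [i.genome.to_dict() for i in back] == \
               [i.genome.to_dict() for i in res.population]
        assert [i.performance for i in back] == \
               [i.performance for i in res.population]

    def test_log_fields(self):
        res = run_evolution(_smoke_config(log_modularity_every=2))
        frame = res.log_frame()
        assert {"generation", "median_performance", "max_performance",
                "median_connections"} <= set(frame.columns)
        assert "median_q" in res.log[1]
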