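"""Multi-objective neuroevolution with a stochastic connection-cost objective.

The engine is an NSGA-II variant ("PNSGA"): performance and behavioral
diversity are always objectives; in the P&CC treatment the number of
connections is a third objective that enters each pairwise dominance
comparison only with probability ``p_cc`` (default 0.75).  Offspring are
produced by copying a tournament-selected parent and mutating it; there
is no crossover.  Every generation draws a fresh set of shared
environments, so selection favors learning over hard-coded responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .environment import generation_environments
from .network import (Genome, ConnectionGene, LAYER_SIZES, MAX_CONNECTIONS,
                      N_LAYERS, NetworkState, PUNISHMENT_INPUT, REWARD_INPUT,
                      random_genome, _SIZES)


@dataclass
class MutationRates:
    """Per-offspring operator probabilities (perturb_weight is applied
    independently per connection)."""

    add_connection: float = 0.20
    remove_connection: float = 0.20
    perturb_weight: float = 0.10
    move_connection: float = 0.10
    toggle_neuron_type: float = 0.05
    perturb_scale: float = 0.5     # weight perturbation is U(-scale, scale)


@dataclass
class EvolutionConfig:
    population_size: int = 400
    generations: int = 20_000
    p_cc: float = 0.75
    treatment: str = "PCC"             # "PA" (performance alone) or "PCC"
    forced_forgetting: bool = False
    no_neuromodulation: bool = False
    cost_draw: str = "per_comparison"  # or "per_individual"
    n_eval_environments: int = 4
    n_final_environments: int = 80
    mutation_rates: MutationRates = field(default_factory=MutationRates)
    eta: float = 0.04
    steepness: float = 5.0
    init_connection_prob: float = 0.5
    init_modulatory_prob: float = 0.2
    master_seed: int = 0
    log_modularity_every: int = 0      # 0 = only at the end
    environment: dict = field(default_factory=dict)  # spec kwargs overrides

    def __post_init__(self):
        if not 0.0 <= self.p_cc <= 1.0:
            raise ValueError("p_cc must be in [0, 1]")
        if self.treatment not in ("PA", "PCC"):
            raise ValueError("treatment must be PA or PCC")

    @property
    def uses_connection_cost(self) -> bool:
        return self.treatment == "PCC"


@dataclass
class Individual:
    genome: Genome
    performance: float = 0.0
    diversity: float = 0.0
    connection_cost: int = 0
    choice_signature: np.ndarray | None = None
    evaluated_generation: int = -1
    final_performance: float | None = None


def connection_cost(genome: Genome) -> int:
    """A network's connection cost is simply its number of connections."""
    return genome.connection_count


def behavioral_diversity(signatures) -> np.ndarray:
    """Mean normalized Hamming distance of each choice signature to all
    others (normalized bitwise XOR, averaged over the population)."""
    sigs = np.asarray(signatures, dtype=np.float32)
    if sigs.ndim != 2:
        raise ValueError("signatures must be a 2-D array of equal-length vectors")
    n, length = sigs.shape
    if n < 2:
        return np.zeros(n)
    ones = sigs @ (1.0 - sigs.T)          # i has 1 where j has 0
    hamming = ones + ones.T               # symmetric XOR counts
    return hamming.sum(axis=1) / ((n - 1) * length)


def _objective_arrays(population):
    perf = np.array([ind.performance for ind in population])
    div = np.array([ind.diversity for ind in population])
    cost = np.array([ind.connection_cost for ind in population], dtype=float)
    return perf, div, cost


def _cost_inclusion_matrix(n, config: EvolutionConfig, rng) -> np.ndarray:
    """Symmetric boolean matrix saying whether the cost objective is active
    for each pairwise comparison."""
    if not config.uses_connection_cost or config.p_cc == 0.0:
        return np.zeros((n, n), dtype=bool)
    if config.p_cc == 1.0:
        return np.ones((n, n), dtype=bool)
    if config.cost_draw == "per_individual":
        per = rng.random(n) < config.p_cc
        return per[:, None] | per[None, :]
    draws = rng.random((n, n)) < config.p_cc
    upper = np.triu(draws, 1)
    return upper | upper.T


def dominance_matrix(population, config: EvolutionConfig, rng) -> np.ndarray:
    """dom[i, j] True iff i Pareto-dominates j under the stochastically
    drawn active objective set (performance and diversity maximized,
    connection cost minimized when active)."""
    perf, div, cost = _objective_arrays(population)
    include = _cost_inclusion_matrix(len(population), config, rng)
    ge_p = perf[:, None] >= perf[None, :]
    gt_p = perf[:, None] > perf[None, :]
    ge_d = div[:, None] >= div[None, :]
    gt_d = div[:, None] > div[None, :]
    le_c = cost[:, None] <= cost[None, :]
    lt_c = cost[:, None] < cost[None, :]
    no_worse = ge_p & ge_d & (le_c | ~include)
    better = gt_p | gt_d | (lt_c & include)
    return no_worse & better


def stochastic_dominates(a: Individual, b: Individual,
                         config: EvolutionConfig, rng) -> bool:
    """Pairwise stochastic Pareto dominance: does ``a`` dominate ``b``?"""
    include = (config.uses_connection_cost and rng.random() < config.p_cc)
    objs_a = [a.performance, a.diversity]
    objs_b = [b.performance, b.diversity]
    if include:
        objs_a.append(-a.connection_cost)
        objs_b.append(-b.connection_cost)
    no_worse = all(x >= y for x, y in zip(objs_a, objs_b))
    better = any(x > y for x, y in zip(objs_a, objs_b))
    return no_worse and better


def non_dominated_sort(dom: np.ndarray) -> list[np.ndarray]:
    """Fronts (arrays of indices) from a dominance matrix."""
    n = dom.shape[0]
    dominated_by = dom.sum(axis=0).astype(int)   # how many dominate j
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        front = np.where(remaining & (dominated_by == 0))[0]
        if front.size == 0:   # defensive: cycles cannot occur with Pareto dominance
            front = np.where(remaining)[0]
        fronts.append(front)
        remaining[front] = False
        dominated_by -= dom[front].sum(axis=0).astype(int)
    return fronts


def crowding_distance(population, indices: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (all three objectives)."""
    perf, div, cost = _objective_arrays([population[i] for i in indices])
    k = len(indices)
    dist = np.zeros(k)
    if k <= 2:
        return np.full(k, np.inf)
    for vals in (perf, div, cost):
        order = np.argsort(vals, kind="stable")
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vals[order[-1]] - vals[order[0]]
        if span == 0:
            continue
        dist[order[1:-1]] += (vals[order[2:]] - vals[order[:-2]]) / span
    return dist


# -- mutation ----------------------------------------------------------

def _existing_pairs(genome: Genome):
    return {(c.source, c.target) for c in genome.connections}


def mutate(genome: Genome, rates: MutationRates, rng) -> Genome:
    """Copy-and-mutate: add / remove / perturb / move connections and
    toggle neuron types.  Inapplicable operators are silent no-ops."""
    g = genome.copy()
    if rng.random() < rates.add_connection:
        pairs = _existing_pairs(g)
        if len(pairs) < MAX_CONNECTIONS:
            while True:
                l = int(rng.integers(N_LAYERS - 1))
                si = int(rng.integers(LAYER_SIZES[l]))
                ti = int(rng.integers(LAYER_SIZES[l + 1]))
                if ((l, si), (l + 1, ti)) not in pairs:
                    g.connections.append(ConnectionGene(
                        (l, si), (l + 1, ti), float(rng.uniform(-1, 1))))
                    break
    if rng.random() < rates.remove_connection and g.connections:
        g.connections.pop(int(rng.integers(len(g.connections))))
    for c in g.connections:
        if rng.random() < rates.perturb_weight:
            c.weight = float(np.clip(
                c.weight + rng.uniform(-rates.perturb_scale, rates.perturb_scale),
                -1.0, 1.0))
    if rng.random() < rates.move_connection and g.connections:
        idx = int(rng.integers(len(g.connections)))
        c = g.connections[idx]
        pairs = _existing_pairs(g)
        if rng.random() < 0.5:
            new_src = (c.source[0], int(rng.integers(LAYER_SIZES[c.source[0]])))
            candidate = (new_src, c.target)
        else:
            new_tgt = (c.target[0], int(rng.integers(LAYER_SIZES[c.target[0]])))
            candidate = (c.source, new_tgt)
        if candidate not in pairs:
            c.source, c.target = candidate
    if rng.random() < rates.toggle_neuron_type:
        non_output = [n for n in g.neurons if n.layer < N_LAYERS - 1]
        n = non_output[int(rng.integers(len(non_output)))]
        n.is_modulatory = not n.is_modulatory
    return g


# -- evaluation --------------------------------------------------------

def evaluate_individual(ind: Individual, environments, config: EvolutionConfig,
                        rng, generation: int = -1) -> None:
    """Evaluate one individual on the shared environment set, filling
    performance, connection cost, and the concatenated choice signature."""
    state = NetworkState(ind.genome, eta=config.eta,
                         steepness=config.steepness,
                         neuromodulation_enabled=not config.no_neuromodulation,
                         validate=False)
    reset_mode = "genetic" if config.no_neuromodulation else "randomize"
    sigs = []
    perfs = []
    for spec in environments:
        state.reset_plastic_weights(reset_mode, rng)
        if config.forced_forgetting:
            boundaries = np.asarray(spec.season_boundaries(), dtype=np.int64)
            reset_values = rng.uniform(-1, 1,
                                       size=(len(boundaries),) + state.w_act.shape)
        else:
            boundaries = np.zeros(0, dtype=np.int64)
            reset_values = np.zeros((0,) + state.w_act.shape)
        choices = np.zeros(spec.encounters_per_lifetime, dtype=bool)
        day_scores = np.zeros(spec.total_days)
        _kernels.run_lifetime(
            state.w_act, state.w_mod, state.bias, state.plastic, _SIZES,
            state.steepness, state.eta, state.neuromodulation_enabled, True,
            state.activations, state.modulation,
            spec.day_orders, spec.day_seasons(), spec.edibility,
            spec.items_per_season, REWARD_INPUT, PUNISHMENT_INPUT,
            boundaries, reset_values, choices, day_scores)
        sigs.append(choices)
        perfs.append(day_scores.mean())
    ind.performance = float(np.mean(perfs))
    ind.connection_cost = connection_cost(ind.genome)
    ind.choice_signature = np.concatenate(sigs).astype(np.uint8)
    ind.evaluated_generation = generation


def assign_diversity(population) -> None:
    sigs = np.stack([ind.choice_signature for ind in population])
    for ind, d in zip(population, behavioral_diversity(sigs)):
        ind.diversity = float(d)


# -- the generational loop ---------------------------------------------

def _generation_rng(config: EvolutionConfig, generation: int):
    return np.random.default_rng(
        np.random.SeedSequence([config.master_seed, generation]))


def _tournament(population, ranks, crowd, rng):
    i, j = rng.integers(len(population), size=2)
    if ranks[i] < ranks[j] or (ranks[i] == ranks[j] and crowd[i] > crowd[j]):
        return population[i]
    return population[j]


def _select(population, config, rng):
    """Non-dominated sorting + crowding-distance truncation; returns the
    survivors and their (rank, crowding) arrays."""
    n_keep = config.population_size
    dom = dominance_matrix(population, config, rng)
    fronts = non_dominated_sort(dom)
    survivors, ranks, crowds = [], [], []
    for rank, front in enumerate(fronts):
        crowd = crowding_distance(population, front)
        if len(survivors) + len(front) <= n_keep:
            chosen = np.arange(len(front))
        else:
            chosen = np.argsort(-crowd, kind="stable")[: n_keep - len(survivors)]
        for c in chosen:
            survivors.append(population[front[c]])
            ranks.append(rank)
            crowds.append(crowd[c])
        if len(survivors) >= n_keep:
            break
    return survivors, np.asarray(ranks), np.asarray(crowds)


def pnsga_generation(population, config: EvolutionConfig, rng,
                     generation: int = 0):
    """One PNSGA step: tournament parents -> copy+mutate offspring ->
    evaluate parents and offspring on this generation's shared (freshly
    randomized) environments -> stochastic non-dominated truncation back
    to N.

    Survivors are re-evaluated alongside their offspring because every
    individual of a generation faces the same four environments; letting
    parents keep scores from earlier environment draws would immortalize
    lucky evaluations instead of selecting for robust learning.
    """
    environments = generation_environments(rng, config.n_eval_environments,
                                           **config.environment)
    # parent selection uses the previous generation's objective values
    dom = dominance_matrix(population, config, rng)
    fronts = non_dominated_sort(dom)
    ranks = np.empty(len(population), dtype=int)
    crowds = np.empty(len(population))
    for r, front in enumerate(fronts):
        ranks[front] = r
        crowds[front] = crowding_distance(population, front)
    offspring = []
    for _ in range(config.population_size):
        parent = _tournament(population, ranks, crowds, rng)
        offspring.append(Individual(mutate(parent.genome,
                                           config.mutation_rates, rng)))
    merged = list(population) + offspring
    for ind in merged:
        evaluate_individual(ind, environments, config, rng, generation)
    assign_diversity(merged)
    survivors, _, _ = _select(merged, config, rng)
    return survivors


def save_population(population, path) -> None:
    """Checkpoint a population (genomes + objective values) as JSON."""
    import json

    payload = [{"genome": ind.genome.to_dict(),
                "performance": ind.performance,
                "diversity": ind.diversity,
                "connection_cost": ind.connection_cost,
                "evaluated_generation": ind.evaluated_generation}
               for ind in population]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_population(path) -> list:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    population = []
    for d in payload:
        ind = Individual(Genome.from_dict(d["genome"]))
        ind.performance = d["performance"]
        ind.diversity = d["diversity"]
        ind.connection_cost = d["connection_cost"]
        ind.evaluated_generation = d["evaluated_generation"]
        population.append(ind)
    return population


@dataclass
class EvolutionResult:
    config: EvolutionConfig
    log: list
    population: list
    best: Individual

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log)


def _median_q(population, sample: int = 0):
    from .modularity import genome_graph, spectral_decompose

    qs = []
    for ind in population:
        g = genome_graph(ind.genome)
        if g.number_of_edges() == 0:
            continue
        qs.append(spectral_decompose(g).q)
    return float(np.median(qs)) if qs else float("nan")


def run_evolution(config: EvolutionConfig, progress: bool = False) -> EvolutionResult:
    """Run a full evolutionary experiment.

    Returns the per-generation log, the final population, and the
    highest-performing individual (selected on evolution-time performance,
    re-evaluated on ``n_final_environments`` fresh lifetimes).
    """
    rng0 = _generation_rng(config, 0)
    population = [Individual(random_genome(
        rng0, config.init_connection_prob,
        config.init_modulatory_prob,
        allow_modulatory=not config.no_neuromodulation))
        for _ in range(config.population_size)]
    env0 = generation_environments(rng0, config.n_eval_environments,
                                   **config.environment)
    for ind in population:
        evaluate_individual(ind, env0, config, rng0, 0)
    assign_diversity(population)

    log = []
    for gen in range(1, config.generations + 1):
        rng = _generation_rng(config, gen)
        population = pnsga_generation(population, config, rng, gen)
        perfs = np.array([ind.performance for ind in population])
        conns = np.array([ind.connection_cost for ind in population])
        row = {"generation": gen,
               "median_performance": float(np.median(perfs)),
               "max_performance": float(perfs.max()),
               "median_connections": float(np.median(conns))}
        if (config.log_modularity_every
                and gen % config.log_modularity_every == 0):
            row["median_q"] = _median_q(population)
        log.append(row)
    best = max(population, key=lambda ind: ind.performance)
    final_rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, config.generations + 1]))
    from .environment import evaluate_performance

    best.final_performance = evaluate_performance(
        best.genome, config.n_final_environments, final_rng,
        eta=config.eta, steepness=config.steepness,
        neuromodulation_enabled=not config.no_neuromodulation,
        forced_forgetting=config.forced_forgetting)
    return EvolutionResult(config, log, population, best)
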