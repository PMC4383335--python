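# Methods

## Network model

Agents are directly encoded, layered, feed-forward networks with fixed
layer sizes 10/10/4/2/1 (inputs / three hidden layers / one output).
Connections only link adjacent layers, so the architecture holds at most
10·10 + 10·4 + 4·2 + 2·1 = 150 connections. Weights and biases are
constrained to [−1, 1] at all times.

Each neuron is either *non-modulatory* (activity-carrying) or
*modulatory*. Input and hidden neurons may be modulatory; the output
neuron may not. A connection inherits its kind from its source neuron:
connections from non-modulatory neurons carry activity and are
*plastic*; connections from modulatory neurons feed only the modulation
sum of their target and never change weight.

One forward pass updates layers 1→4 in order, with the inputs held
constant:

    a_i = φ( Σ_{j∈Cn} w_ij a_j + b_i )        activation
    m_i = φ( Σ_{j∈Cm} w_ij a_j )              modulation

and plasticity (applied only when learning is enabled) updates every
plastic connection j→i by

    Δw_ij = η · m_i · a_i · a_j ,   η = 0.04,

followed by clamping to [−1, 1]. The clamp is needed because the update
rule itself is unbounded while the model's weight range is not; clamping
after every update is the simplest rule that preserves the range
exactly.

**Transfer function.** φ must be an odd sigmoid onto (−1, 1); its exact
shape is a free implementation choice. We use φ(x) = tanh(λx) with
steepness λ = 5 by default. λ is a configuration key (`steepness`) so
sensitivity can be examined; λ = 5 makes a single unit-weight input
drive a neuron to ±0.9999, i.e. near-saturating, which matches the
crisp eat/ignore behavior the task demands while staying smooth at 0.

**Decision rule.** The agent eats iff the output activation is strictly
positive; 0 or below means ignore.

**Ablation switch.** With neuromodulation disabled, every m_i is held at
1, reducing the update to pure Hebbian learning Δw = η·a_i·a_j, and
modulatory neurons are disallowed in genomes.

## Encounters and the reward channel

The model does not prescribe a unique sequencing of the outcome signal,
so an encounter is implemented as two full forward passes with
plasticity after each:

1. *Decision pass*: the item's input is 1, reward/punishment inputs are
   0; the output is read and the eat decision made.
2. *Outcome pass*: the item input stays 1; the reward input is set to 1
   if a nutritious item was eaten, the punishment input to 1 if a
   poisonous one was eaten, both stay 0 if the item was ignored.

Applying plasticity on both passes lets modulatory neurons gate
learning on the outcome while the stimulus is still present; applying it
on only one of the passes is a contained change (two lines in the
encounter kernel) but was not exposed as an option because the choice
interacts with every evolved solution.

Input layout: summer items map one-hot onto inputs 0–3, winter items
onto 4–7, the reward signal is input 8 and the punishment signal
input 9. Out-of-season item inputs are always 0.

## Environments

A lifetime is `years` × `seasons_per_year` × `days_per_season` days
(3 × 2 × 5 = 30 by default). Per season, exactly half of the
`items_per_season` (4) items are nutritious, drawn uniformly over the 6
possible 2-of-4 choices, independently for summer and winter. Each day
presents all in-season items once, in a uniformly random order. All
counts are configuration parameters (longer seasons, more items, etc.),
but the defaults above are the study conditions and the network's input
layout constrains `seasons_per_year · items_per_season ≤ 8`.

The bookkeeping helper `environment_space_accounting` reproduces the
conventional count of distinct environments for the default task:
24 orders/day × 30 days = 720 presentation patterns, 6 × 6 = 36
edibility assignments, 720 × 36 = 25,920. Note that this accounting
multiplies the per-day order count by the number of days rather than
exponentiating (24³⁰ would count full order sequences); we keep the
conventional figure as the reference quantity and note the discrepancy
here rather than redefining it.

Day score = 0.5 + (F − P) / (2·N_nutritious), where F and P are the
nutritious and poisonous items eaten. The formula is anchored by its
fixed points: eat-nothing and eat-everything both give 0.5, a perfect
forager gives 1.0, and each correct (incorrect) bite moves the score up
(down) by 0.25 at the defaults. Lifetime performance is the mean day
score; evolutionary fitness is the mean over the evaluation lifetimes.

Before each lifetime the plastic weights are randomized i.i.d. uniform
on [−1, 1] (the distribution is unspecified upstream; uniform over the
full legal range is the least-informative choice). In the
no-neuromodulation ablation they are instead reset to the genetic
weights, because with m ≡ 1 every lifetime would otherwise start from
noise it cannot gate away. Modulatory connection weights are never
reset — they never change in the first place.

## Evolution

The engine is NSGA-II with three modifications ("PNSGA"):

- **Objectives**: performance (maximize), behavioral diversity
  (maximize), and — in the P&CC treatment only — connection count
  (minimize). Behavioral diversity of an individual is the mean
  normalized Hamming distance between its concatenated eat/ignore
  choice vector and those of all other individuals of the generation.
- **Stochastic dominance**: the cost objective enters each pairwise
  dominance comparison independently with probability p = 0.75
  (configurable; drawing inclusion per individual per generation is
  exposed as `cost_draw="per_individual"`). The inclusion draw is made
  once per unordered pair so dominance stays antisymmetric.
- **Reproduction**: offspring are genome copies with mutation; no
  crossover. Parent selection is binary tournament on (front rank,
  crowding distance); survivor selection is standard non-dominated
  sorting with crowding-distance truncation.

Every generation draws a fresh shared set of 4 evaluation environments,
and the *merged* parent+offspring pool is evaluated on them. Survivors
are deliberately re-evaluated rather than carrying scores forward: with
per-generation environment randomization, a stale score is an estimate
of performance on environments nobody else in the generation saw, and a
pilot run showed it immortalizes lucky evaluations (an elite whose
stored score was 0.80 re-evaluated at 0.49 on 80 fresh lifetimes).
Re-evaluation makes all within-generation comparisons share the same
four environments.

Mutation operators and per-offspring probabilities (per-connection for
the weight perturbation): add a random absent connection 0.20, remove a
random connection 0.20, perturb each connection weight 0.10 (uniform
step in [−0.5, 0.5], clamped), move one endpoint of a connection 0.10,
toggle a random non-output neuron's kind 0.05. The exact upstream
probabilities are not recoverable from text, so these defaults are
declared choices in the range typical of direct-encoding neuroevolution;
all are configuration fields. Biases are drawn uniform on [−1, 1] at
genome creation and are not mutated thereafter (the operator list keeps
to the five documented kinds); bias diversity therefore comes from the
initial population. Inapplicable operators (add to a full genome,
remove/move/toggle on an empty one) are silent no-ops.

Initial genomes contain every possible connection with probability 0.5
(weights uniform) and make each non-output neuron modulatory with
probability 0.2 — dense enough that the cost objective has material
work to do, sparse enough that functional sub-circuits exist at
generation 0.

Study conditions are population 400 × 20,000 generations × 100 repeats
per treatment. Because a single such run is hours-to-days of CPU time,
the package ships three presets: `paper` (the above), `reduced`
(100 × 2,000 × 20, the scale used for statistically powered directional
comparisons; a few hours on one CPU), and `smoke` (50 × 250 × 8, minutes,
used by the test suite and quick demos). The per-run analysis unit is
always the highest-performing network of the run (selected on
evolution-time performance, reported on a re-evaluation over 80 fresh
lifetimes).

Determinism: a run is fully determined by its configuration and master
seed; each generation derives its own generator from (master seed,
generation index), so studies replay bit-identically and per-run
checkpoint files allow interrupted studies to resume.

## Modularity

Directed modularity follows the Leicht–Newman extension of Newman's Q:

    Q = (1/m) Σ_ij [ A_ij − k_i^in k_j^out / m ] δ(c_i, c_j)

with A the (unweighted) directed adjacency matrix. Weights are
deliberately ignored: the hypothesis concerns topology. An alternative
*layered feed-forward* null model replaces the global m in the
expectation with m_pq, the number of edges between the layer pair of the
two nodes, so that structure explained by the layering itself is
discounted; both nulls cancel exactly on the single-module partition.

Optimization is recursive spectral bisection: each module is split along
the sign pattern of the leading eigenvector of the symmetrized
generalized modularity matrix, refined by greedy single-node moves
(Kernighan–Lin style; toggleable, default on), and the split is accepted
only if Q strictly increases (tolerance 1e−12). A module whose leading
eigenvalue is ≤ 1e−10 is declared indivisible. Isolated neurons are
removed before decomposition: their Q terms vanish but they distort the
eigenvector step. On all ≤ 8-node fixtures the decomposition is verified
against exhaustive partition enumeration (≥ 0.95 of the optimum, the
standard guarantee expected of the spectral heuristic).

A network has a *separate learning module* when no module containing a
reward or punishment input also contains a food input. Reinforcement
inputs that are isolated (unwired) are excluded from the partition and
cannot violate the criterion.

## Learning and retention measurement

All probes run with learning disabled, so measurement cannot alter what
the network knows (verified bitwise on the plastic weights). A season's
association set is "known" when the agent responds correctly to all
four in-season items (single decision pass each).

- **Counters** (per lifetime, 6 season-ends, both sets probed at each):
  Known = sets known at season ends (≤ 960 over 80 lifetimes);
  Perfect = season ends with both sets known (≤ 480); Retained /
  Forgotten = sets known at one season end that are kept / lost at the
  next (≤ 800 combined). Percentages use Known as denominator and are
  defined as 0 when Known = 0, making the metric total instead of
  undefined for never-learners (analyses that mirror the original
  filtering instead drop the bottom half of runs by performance).
- **Retention curves**: train 50 winter days, record the winter score as
  baseline (learning off), then for 20 summer days alternate one summer
  training day with learning-off probes of the winter score (normalized
  by baseline), the summer score, and the *combined* score — the
  unweighted mean of the two raw scores (sum vs mean is not fixed
  upstream; the mean keeps the [0, 1] scale of every other score).
  A baseline at or below the chance score 0.5 flags the agent as a
  non-learner; cohort analyses exclude such runs by keeping the top 50 %
  of runs by final performance.

## Statistics

Mann-Whitney U (scipy; exact for small tie-free samples) is the default
two-sample test; medians carry 95 % percentile-bootstrap confidence
intervals from 5,000 resamples; a permutation test on the absolute
median difference (+1-smoothed, with a bootstrap-resampling variant) is
available for the forced-forgetting contrast; Pearson r is tested by the
exact t-test on n−2 degrees of freedom; evolutionary time series are
smoothed by a median filter of window 11 applied to every-10th-generation
samples (each value spans 110 generations). The permutation test sorts
the pooled sample and canonicalizes the argument order, making its
p-value exactly invariant under swapping the two samples.

## Scripted reference agents

Four hand-written policies anchor the metrics analytically: never-eat
and eat-all (day score exactly 0.5), an edibility oracle (exactly 1.0),
a perfect-memory learner (tastes unknown items, never forgets — attains
the counter values 880/400/720/0 over 80 lifetimes), and a total
forgetter (memory wiped at season change — retention 0.5/baseline from
day 1). These are oracles for the instrumentation, not models of the
networks.

## What the synthetic environments do and do not capture

The generator reproduces the study conditions exactly: item counts,
season structure, per-day randomized orders, per-generation re-drawn
edibility. It does not model spatial foraging, item depletion, partial
observability, sensory noise, or distributed input encodings, so
passing tests demonstrate properties of the learning-and-evolution
dynamics under clean one-hot stimuli, not robustness of those dynamics
to richer perception.

## Problem sizes used by the test suite

The deterministic, analytic checks (scores, counters, bounds, Q values,
dominance calibration) run at full fidelity in seconds. Treatment-level
directional comparisons in the suite use the `smoke` preset
(population 50, 250 generations, 8 repeats per arm), the size at which
the sparsity and modularity contrasts between P&CC and PA are already
measurable while a full comparison stays in the minutes range; the
`reduced` preset is the recommended scale for statistically powered
claims, and `paper` reproduces the original conditions. Performance
contrasts between treatments, the forced-forgetting equalization, and
the no-neuromodulation degradation need the larger presets: within a
few hundred generations neither treatment reliably evolves strong
learners, so those comparisons are exposed as library functions and the
`compare` workflows rather than asserted at smoke scale.

## Known limitations

- The exact transfer function, mutation probabilities, and encounter
  sequencing of the original implementation are not recoverable from
  text; the choices above are documented and configurable, so absolute
  performance values are not expected to match the original study —
  directional effects are.
- Modularity scores topology only; weighted variants are out of scope.
- The layered null model assumes adjacent-layer feed-forward graphs
  (true of every genome in this package).
- Checkpointing is at run granularity, not generation granularity.
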