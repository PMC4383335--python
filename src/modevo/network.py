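"""Directly-encoded layered networks with neuromodulated Hebbian plasticity.

The model is a five-layer feed-forward network (10 inputs, hidden layers
of 10/4/2 neurons, one output).  Neurons come in two kinds: ordinary
activity-carrying neurons and *modulatory* neurons.  A connection whose
source is non-modulatory carries activity (Eq-style activation sum) and
is *plastic*: its weight changes during the organism's lifetime by a
Hebbian rule gated by the modulatory input of its target,

    m_i  = phi( sum_{j in Cm} w_ij a_j )
    dw_ij = eta * m_i * a_i * a_j          (then clamped to [-1, 1])

A connection whose source is modulatory feeds only the modulation sum
``m_i`` of its target and never changes weight.  ``phi`` is an odd,
bounded sigmoid, here tanh(lambda * x) with configurable steepness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

#: Neurons per layer: inputs / hidden1 / hidden2 / hidden3 / output.
LAYER_SIZES = (10, 10, 4, 2, 1)
N_LAYERS = len(LAYER_SIZES)
MAX_WIDTH = max(LAYER_SIZES)
#: Maximum number of adjacent-layer connections (10*10 + 10*4 + 4*2 + 2*1).
MAX_CONNECTIONS = sum(a * b for a, b in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]))

#: Input-vector layout: summer items 0-3, winter items 4-7, then the
#: reinforcement signals.
REWARD_INPUT = 8
PUNISHMENT_INPUT = 9

DEFAULT_ETA = 0.04
DEFAULT_STEEPNESS = 5.0

_SIZES = np.asarray(LAYER_SIZES, dtype=np.int64)


def activation_function(x: float, steepness: float = DEFAULT_STEEPNESS) -> float:
    """Neuron transfer function phi: odd, monotone, bounded in (-1, 1)."""
    if not math.isfinite(x):
        raise ValueError(f"activation input must be finite, got {x!r}")
    return math.tanh(steepness * x)


@dataclass
class NeuronGene:
    """One neuron of the genotype.

    ``layer`` 0 is the input layer, ``layer`` 4 the single output neuron.
    ``bias`` is the activation threshold, constrained to [-1, 1].
    Modulatory neurons gate learning in their targets instead of carrying
    activity; the output neuron is never modulatory.
    """

    layer: int
    index: int
    bias: float = 0.0
    is_modulatory: bool = False

    def validate(self) -> None:
        if not 0 <= self.layer < N_LAYERS:
            raise ValueError(f"layer {self.layer} out of range")
        if not 0 <= self.index < LAYER_SIZES[self.layer]:
            raise ValueError(f"index {self.index} out of range for layer {self.layer}")
        if not -1.0 <= self.bias <= 1.0:
            raise ValueError(f"bias {self.bias} outside [-1, 1]")
        if self.is_modulatory and self.layer == N_LAYERS - 1:
            raise ValueError("the output neuron may not be modulatory")


@dataclass
class ConnectionGene:
    """A directed connection between adjacent layers.

    ``source``/``target`` are (layer, index) pairs; ``weight`` is the
    innate (genetic) strength in [-1, 1].
    """

    source: tuple[int, int]
    target: tuple[int, int]
    weight: float

    def validate(self) -> None:
        sl, si = self.source
        tl, ti = self.target
        if tl != sl + 1:
            raise ValueError(f"connection {self.source}->{self.target} not adjacent-layer")
        if not (0 <= sl < N_LAYERS - 1 and 0 <= si < LAYER_SIZES[sl]):
            raise ValueError(f"bad source {self.source}")
        if not 0 <= ti < LAYER_SIZES[tl]:
            raise ValueError(f"bad target {self.target}")
        if not -1.0 <= self.weight <= 1.0:
            raise ValueError(f"weight {self.weight} outside [-1, 1]")


@dataclass
class Genome:
    """Direct encoding: the full neuron complement plus a connection list."""

    neurons: list[NeuronGene] = field(default_factory=list)
    connections: list[ConnectionGene] = field(default_factory=list)

    def validate(self) -> None:
        expected = {(l, i) for l in range(N_LAYERS) for i in range(LAYER_SIZES[l])}
        seen = set()
        for n in self.neurons:
            n.validate()
            seen.add((n.layer, n.index))
        if seen != expected:
            raise ValueError("genome must contain exactly the full neuron complement")
        pairs = set()
        for c in self.connections:
            c.validate()
            key = (c.source, c.target)
            if key in pairs:
                raise ValueError(f"duplicate connection {key}")
            pairs.add(key)
        if len(self.connections) > MAX_CONNECTIONS:
            raise ValueError("too many connections")

    @property
    def connection_count(self) -> int:
        return len(self.connections)

    def neuron(self, layer: int, index: int) -> NeuronGene:
        for n in self.neurons:
            if n.layer == layer and n.index == index:
                return n
        raise KeyError((layer, index))

    def copy(self) -> "Genome":
        return Genome(
            [NeuronGene(n.layer, n.index, n.bias, n.is_modulatory) for n in self.neurons],
            [ConnectionGene(c.source, c.target, c.weight) for c in self.connections],
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(LAYER_SIZES),
            "neurons": [
                {"layer": n.layer, "index": n.index, "bias": n.bias,
                 "is_modulatory": n.is_modulatory}
                for n in self.neurons
            ],
            "connections": [
                {"source": list(c.source), "target": list(c.target), "weight": c.weight}
                for c in self.connections
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        g = cls(
            [NeuronGene(n["layer"], n["index"], n["bias"], n["is_modulatory"])
             for n in d["neurons"]],
            [ConnectionGene(tuple(c["source"]), tuple(c["target"]), c["weight"])
             for c in d["connections"]],
        )
        g.validate()
        return g

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "Genome":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))


def full_neuron_complement(rng=None, modulatory_prob: float = 0.0) -> list[NeuronGene]:
    """All neurons of the fixed architecture, biases 0 (or random if rng given)."""
    neurons = []
    for layer, size in enumerate(LAYER_SIZES):
        for i in range(size):
            bias = 0.0 if rng is None else float(rng.uniform(-1, 1))
            mod = (
                layer < N_LAYERS - 1
                and rng is not None
                and rng.random() < modulatory_prob
            )
            neurons.append(NeuronGene(layer, i, bias, mod))
    return neurons


def random_genome(rng, connection_prob: float = 0.5,
                  modulatory_prob: float = 0.2,
                  allow_modulatory: bool = True) -> Genome:
    """A random genome: each potential adjacent-layer connection present
    independently with ``connection_prob``; weights and biases uniform on
    [-1, 1]; non-output neurons modulatory with ``modulatory_prob``."""
    neurons = full_neuron_complement(
        rng, modulatory_prob if allow_modulatory else 0.0)
    connections = []
    for l in range(N_LAYERS - 1):
        for si in range(LAYER_SIZES[l]):
            for ti in range(LAYER_SIZES[l + 1]):
                if rng.random() < connection_prob:
                    connections.append(ConnectionGene(
                        (l, si), (l + 1, ti), float(rng.uniform(-1, 1))))
    g = Genome(neurons, connections)
    g.validate()
    return g


def zero_genome() -> Genome:
    """A genome with the full neuron complement and no connections."""
    return Genome(full_neuron_complement(), [])


class NetworkState:
    """Runtime phenotype: dense weight arrays plus activation state.

    Plastic weights live in ``w_act`` (entries where ``plastic`` is True);
    ``w_genetic`` preserves the innate values for genetic resets.
    """

    def __init__(self, genome: Genome, eta: float = DEFAULT_ETA,
                 steepness: float = DEFAULT_STEEPNESS,
                 learning_enabled: bool = True,
                 neuromodulation_enabled: bool = True,
                 validate: bool = True):
        if validate:
            genome.validate()
        self.genome = genome
        self.eta = float(eta)
        self.steepness = float(steepness)
        self.learning_enabled = bool(learning_enabled)
        self.neuromodulation_enabled = bool(neuromodulation_enabled)

        ng = N_LAYERS - 1
        self.w_act = np.zeros((ng, MAX_WIDTH, MAX_WIDTH))
        self.w_mod = np.zeros((ng, MAX_WIDTH, MAX_WIDTH))
        self.plastic = np.zeros((ng, MAX_WIDTH, MAX_WIDTH), dtype=bool)
        self.bias = np.zeros((N_LAYERS, MAX_WIDTH))
        self.modulatory = np.zeros((N_LAYERS, MAX_WIDTH), dtype=bool)
        for n in genome.neurons:
            self.bias[n.layer, n.index] = n.bias
            self.modulatory[n.layer, n.index] = n.is_modulatory
        for c in genome.connections:
            (sl, si), (_, ti) = c.source, c.target
            if self.modulatory[sl, si]:
                self.w_mod[sl, ti, si] = c.weight
            else:
                self.w_act[sl, ti, si] = c.weight
                self.plastic[sl, ti, si] = True
        self.w_genetic = np.where(self.plastic, self.w_act, 0.0)

        self.activations = np.zeros((N_LAYERS, MAX_WIDTH))
        self.modulation = np.zeros((N_LAYERS, MAX_WIDTH))

    # -- core dynamics -------------------------------------------------
    def forward_pass(self, inputs) -> float:
        """Propagate ``inputs`` (length 10, values in [-1, 1]) through all
        layers, refreshing activations and modulation; returns the output
        neuron's activation."""
        inputs = np.asarray(inputs, dtype=float)
        if inputs.shape != (LAYER_SIZES[0],):
            raise ValueError(
                f"expected {LAYER_SIZES[0]} inputs, got shape {inputs.shape}")
        if not np.all(np.isfinite(inputs)):
            raise ValueError("inputs must be finite")
        self.activations[0, :LAYER_SIZES[0]] = inputs
        return _kernels.forward(
            self.w_act, self.w_mod, self.bias, _SIZES, self.steepness,
            self.neuromodulation_enabled, self.activations, self.modulation)

    def compute_modulation(self, layer: int, index: int) -> float:
        """Modulatory input m_i of one neuron from current upstream
        activations (1.0 when neuromodulation is disabled)."""
        if not self.neuromodulation_enabled:
            return 1.0
        if layer == 0:
            return activation_function(0.0, self.steepness)
        s = float(self.w_mod[layer - 1, index, :LAYER_SIZES[layer - 1]]
                  @ self.activations[layer - 1, :LAYER_SIZES[layer - 1]])
        return activation_function(s, self.steepness)

    def apply_plasticity(self) -> None:
        """One modulated-Hebbian update of every plastic weight (no-op when
        learning is disabled)."""
        if not self.learning_enabled:
            return
        _kernels.hebbian_update(self.w_act, self.plastic, _SIZES,
                                self.activations, self.modulation, self.eta)

    # -- weight management ---------------------------------------------
    def plastic_weights(self) -> np.ndarray:
        """Current values of all plastic weights (copy, fixed order)."""
        return self.w_act[self.plastic].copy()

    def reset_plastic_weights(self, mode: str, rng=None) -> None:
        """Reset plastic weights: ``randomize`` -> i.i.d. U(-1, 1) draws
        (needs ``rng``); ``genetic`` -> the innate genome weights."""
        if mode == "randomize":
            if rng is None:
                raise ValueError("randomize mode requires an rng")
            n = int(self.plastic.sum())
            self.w_act[self.plastic] = rng.uniform(-1, 1, size=n)
        elif mode == "genetic":
            self.w_act[self.plastic] = self.w_genetic[self.plastic]
        else:
            raise ValueError(f"unknown reset mode {mode!r}")

    def decide_eat(self, output_activation: float | None = None) -> bool:
        if output_activation is None:
            output_activation = self.activations[N_LAYERS - 1, 0]
        return decide_eat(output_activation)


def decide_eat(output_activation: float) -> bool:
    """Eat when the output is strictly positive; ignore otherwise."""
    return output_activation > 0.0


def reset_plastic_weights(state: NetworkState, mode: str, rng=None) -> NetworkState:
    state.reset_plastic_weights(mode, rng)
    return state


# -- graph views and exports ------------------------------------------

def input_role(index: int, items_per_season: int = 4,
               seasons_per_year: int = 2) -> str:
    """Role of an input neuron under the standard input layout."""
    if index < items_per_season * seasons_per_year:
        return "food_input"
    return "reward_input"


def to_networkx(genome: Genome, items_per_season: int = 4,
                seasons_per_year: int = 2):
    """Directed graph of the genome with node roles and layers.

    Node names are ``"L{layer}N{index}"``; roles are food_input /
    reward_input / hidden / modulatory / output.
    """
    import networkx as nx

    g = nx.DiGraph()
    for n in genome.neurons:
        if n.layer == 0:
            # inputs keep their sensory identity even when modulatory;
            # the flag is carried separately
            role = input_role(n.index, items_per_season, seasons_per_year)
        elif n.layer == N_LAYERS - 1:
            role = "output"
        else:
            role = "modulatory" if n.is_modulatory else "hidden"
        g.add_node(f"L{n.layer}N{n.index}", layer=n.layer, role=role,
                   is_modulatory=bool(n.is_modulatory), bias=float(n.bias))
    for c in genome.connections:
        g.add_edge(f"L{c.source[0]}N{c.source[1]}",
                   f"L{c.target[0]}N{c.target[1]}", weight=float(c.weight))
    return g


def write_graphml(genome: Genome, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(genome), path)


def write_dot(genome: Genome, path) -> None:
    """Minimal DOT export (node layer/role attributes, edge weights)."""
    g = to_networkx(genome)
    lines = ["digraph network {"]
    for node, d in g.nodes(data=True):
        lines.append(
            f'  "{node}" [layer={d["layer"]}, role="{d["role"]}", '
            f'modulatory={str(d["is_modulatory"]).lower()}];')
    for u, v, d in g.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [weight={d["weight"]:.6f}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
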