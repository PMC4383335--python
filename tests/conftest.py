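import numpy as np
import pytest

from modevo.network import (ConnectionGene, Genome, LAYER_SIZES, NeuronGene,
                            full_neuron_complement, random_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sparse_genome(rng):
    """A random genome with roughly 20 connections."""
    return random_genome(rng, connection_prob=20 / 150, modulatory_prob=0.3)


def chain_genome(weight: float = 1.0):
    """Input 0 -> one neuron per layer -> output, all pass-through."""
    connections = [
        ConnectionGene((l, 0), (l + 1, 0), weight)
        for l in range(len(LAYER_SIZES) - 1)
    ]
    return Genome(full_neuron_complement(), connections)


def genome_with(connections, modulatory=()):
    """Full neuron complement, given connections, given modulatory neurons."""
    neurons = full_neuron_complement()
    mod = set(modulatory)
    for n in neurons:
        if (n.layer, n.index) in mod:
            n.is_modulatory = True
    return Genome(neurons, [ConnectionGene(s, t, w) for s, t, w in connections])
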