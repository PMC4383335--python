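"""Directed modularity of network topologies.

Q compares within-module connection counts against a random-network
expectation; the decomposition also reports whether the reinforcement
(reward/punishment) inputs occupy a module with no food inputs -- the
"separate learning module" signature.
"""

import networkx as nx
import numpy as np

from modevo.modularity import genome_modularity, spectral_decompose
from modevo.network import random_genome

# a textbook fixture: two disjoint directed 3-cycles
g = nx.DiGraph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
res = spectral_decompose(g)
print(f"two 3-cycles: Q = {res.q:.3f}, modules = {res.modules()}")

# evolved-style genomes: dense vs sparse random networks
rng = np.random.default_rng(3)
for density in (0.9, 0.2):
    genome = random_genome(rng, connection_prob=density, modulatory_prob=0.2)
    for null in ("directed_configuration", "layered_feedforward"):
        r = genome_modularity(genome, null_model=null)
        print(f"density {density}: null={null:<24} Q = {r.q:.3f} "
              f"modules = {r.n_modules} separate = {r.separate_learning_module}")
print("Sparser networks decompose more cleanly (higher Q); the layered "
      "null discounts structure explained by the feed-forward layering.")
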