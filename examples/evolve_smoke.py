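"""A small evolutionary run with the connection-cost objective.

Population and generation counts here are kept tiny so the script runs
in under a minute; see `modevo.experiments.PRESETS` for the study-scale
settings.
"""

import numpy as np

from modevo.evolution import EvolutionConfig, run_evolution

cfg = EvolutionConfig(population_size=40, generations=100, treatment="PCC",
                      master_seed=1, log_modularity_every=50)
res = run_evolution(cfg)

log = res.log_frame()
print(log.tail(5).to_string(index=False))
best = res.best
print(f"\nbest individual: evolution-time performance {best.performance:.3f}, "
      f"re-evaluated on 80 fresh lifetimes: {best.final_performance:.3f}, "
      f"{best.connection_cost} connections")
print("0.5 is chance (eat nothing / everything). At this tiny scale the "
      "re-evaluated performance barely exceeds chance -- evolving reliable "
      "within-lifetime learners takes thousands of generations (see the "
      "'reduced' and 'paper' presets); what does emerge quickly under the "
      "connection cost is sparsity, visible in median_connections.")
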