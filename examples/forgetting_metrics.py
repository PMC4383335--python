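"""Learning/retention counters and retention curves for reference agents.

Counters over 80 lifetimes (6 season-ends each): Known counts every
association set known at a season end (cap 960), Perfect counts season
ends where both sets are known (cap 480), Retained/Forgotten count sets
carried over or lost across the 5 season transitions (cap 800 combined).
"""

import numpy as np

from modevo.agents import PerfectMemoryLearner, TotalForgetter
from modevo.forgetting import association_metrics, retention_experiment

for name, agent in [("perfect memory", PerfectMemoryLearner()),
                    ("total forgetter", TotalForgetter())]:
    m = association_metrics(agent, n_environments=80,
                            rng=np.random.default_rng(0))
    print(f"{name:>15}: known={m.known} perfect={m.perfect} "
          f"retained={m.retained} forgotten={m.forgotten} "
          f"(%forgotten={m.pct_forgotten:.2f})")

print("\nretention after 50 winter days, probed over 20 summer days:")
for name, agent in [("perfect memory", PerfectMemoryLearner()),
                    ("total forgetter", TotalForgetter())]:
    c = retention_experiment(agent, np.random.default_rng(1))
    print(f"{name:>15}: baseline={c.baseline:.2f} "
          f"normalized retention day 1/10/20 = "
          f"{c.retention_normalized[0]:.2f}/"
          f"{c.retention_normalized[9]:.2f}/"
          f"{c.retention_normalized[19]:.2f}")
print("A normalized retention of 1.0 means the old (winter) skill is "
      "intact; 0.5/baseline is what erasing all learned weights yields.")
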