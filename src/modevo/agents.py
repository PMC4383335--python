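"""Scripted reference agents.

These bypass the neural network and implement hand-written policies.
They serve as analytic bounds and oracles: the environment scoring, the
knowledge probes, and the retention/forgetting counters all have exact
expected values under these policies.

The agent interface used by :func:`modevo.environment.run_day`:

- ``begin_lifetime(rng)``: reset per-lifetime state,
- ``choose(season, item) -> bool``: the eat decision,
- ``observe(season, item, ate, outcome)``: outcome feedback (only called
  when learning is enabled),
- ``forget()``: erase learned state (forced-forgetting ablation).
"""

from __future__ import annotations

import numpy as np


class ScriptedAgent:
    def begin_lifetime(self, rng=None) -> None:
        pass

    def choose(self, season: int, item: int) -> bool:
        raise NotImplementedError

    def observe(self, season: int, item: int, ate: bool, outcome: str) -> None:
        pass

    def forget(self) -> None:
        pass


class NeverEat(ScriptedAgent):
    """Ignores every item: scores exactly 0.5 every day."""

    def choose(self, season, item):
        return False


class EatAll(ScriptedAgent):
    """Eats every item: also scores exactly 0.5 every day."""

    def choose(self, season, item):
        return True


class Oracle(ScriptedAgent):
    """Knows the edibility map; eats an item iff it is nutritious (the
    1.0-per-day upper bound)."""

    def __init__(self, spec):
        self.edibility = np.asarray(spec.edibility, dtype=bool)

    def choose(self, season, item):
        return bool(self.edibility[season, item])


class PerfectMemoryLearner(ScriptedAgent):
    """Learns by tasting and never forgets.

    Eats unfamiliar items (to discover their edibility), remembers every
    outcome, and thereafter eats an item iff it proved nutritious.  After
    one day of a season it knows that season's associations perfectly.
    """

    def __init__(self):
        self.memory: dict[tuple[int, int], bool] = {}

    def begin_lifetime(self, rng=None):
        self.memory = {}

    def choose(self, season, item):
        known = self.memory.get((season, item))
        return True if known is None else known

    def observe(self, season, item, ate, outcome):
        if ate:
            self.memory[(season, item)] = outcome == "reward"

    def forget(self):
        self.memory = {}

    def knows_season(self, season: int, items_per_season: int = 4) -> bool:
        return all((season, i) in self.memory for i in range(items_per_season))


class TotalForgetter(PerfectMemoryLearner):
    """Learns like :class:`PerfectMemoryLearner` but wipes its memory
    whenever the season changes (models complete catastrophic forgetting)."""

    def __init__(self):
        super().__init__()
        self._last_season: int | None = None

    def begin_lifetime(self, rng=None):
        super().begin_lifetime(rng)
        self._last_season = None

    def choose(self, season, item):
        if self._last_season is not None and season != self._last_season:
            self.memory = {}
        self._last_season = season
        return super().choose(season, item)
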