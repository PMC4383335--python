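"""Learning- and retention-measurement instrumentation.

Knowledge is always probed with learning disabled, so measuring what an
agent knows cannot change what it knows.  An agent "knows" a season's
association set when it responds correctly to every one of the season's
four items (eat the nutritious, ignore the poisonous).

Two analyses are provided:

- :func:`association_metrics`: the Perfect / Known / Forgotten /
  Retained counters accumulated over many lifetimes, probing both
  association sets at the end of every season.
- :func:`retention_experiment`: long-exposure training on one task
  (winter) followed by training on a new task (summer), tracking how the
  old skill decays and the new one is acquired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .environment import (EnvironmentSpec, SEASON_NAMES, generate_environment,
                          run_day)
from .network import (NetworkState, PUNISHMENT_INPUT, REWARD_INPUT, _SIZES)

SUMMER, WINTER = 0, 1


@dataclass
class KnowledgeProbe:
    season: str
    knows: bool
    responses: list = field(default_factory=list)  # (item, ate, correct)


@dataclass
class AssociationMetrics:
    perfect: int = 0
    known: int = 0
    forgotten: int = 0
    retained: int = 0
    n_environments: int = 0
    seasons_per_lifetime: int = 0

    @property
    def pct_forgotten(self) -> float:
        return self.forgotten / self.known if self.known else 0.0

    @property
    def pct_retained(self) -> float:
        return self.retained / self.known if self.known else 0.0

    def to_dict(self) -> dict:
        return {"perfect": self.perfect, "known": self.known,
                "forgotten": self.forgotten, "retained": self.retained,
                "pct_forgotten": self.pct_forgotten,
                "pct_retained": self.pct_retained,
                "n_environments": self.n_environments}


@dataclass
class RetentionCurves:
    baseline: float                    # old-task score before the switch
    retention_normalized: np.ndarray   # old-task score / baseline, per day
    old_task: np.ndarray               # raw old-task scores
    new_task: np.ndarray               # raw new-task scores
    combined: np.ndarray               # mean of the two raw scores
    non_learner: bool = False          # baseline at or below chance

    def frame(self, agent_id=0):
        import pandas as pd

        rows = []
        for d in range(len(self.new_task)):
            for metric, series in (("retention_normalized", self.retention_normalized),
                                   ("old_task", self.old_task),
                                   ("new_task", self.new_task),
                                   ("combined", self.combined)):
                rows.append({"agent": agent_id, "day": d + 1,
                             "metric": metric, "value": float(series[d])})
        return pd.DataFrame(rows)


def _present_items(state, edibility, season, items, items_per_season,
                   learn: bool):
    """Run a sequence of encounters; returns (ate flags, day score)."""
    edibility = np.asarray(edibility, dtype=bool)
    items = np.asarray(items, dtype=np.int64)
    if isinstance(state, NetworkState):
        ate = np.zeros(len(items), dtype=bool)
        score = _kernels.run_day(
            state.w_act, state.w_mod, state.bias, state.plastic, _SIZES,
            state.steepness, state.eta, state.neuromodulation_enabled,
            learn, state.activations, state.modulation, items, season,
            edibility, items_per_season, REWARD_INPUT, PUNISHMENT_INPUT, ate)
        return ate, float(score)
    ate = np.zeros(len(items), dtype=bool)
    eaten_food = eaten_poison = 0
    for k, item in enumerate(items):
        item = int(item)
        ate[k] = state.choose(season, item)
        nutritious = bool(edibility[season, item])
        if ate[k]:
            if nutritious:
                eaten_food += 1
            else:
                eaten_poison += 1
        if learn:
            outcome = ("reward" if ate[k] and nutritious
                       else "punishment" if ate[k] else "none")
            state.observe(season, item, bool(ate[k]), outcome)
    n_nutritious = int(edibility[season].sum())
    return ate, 0.5 + (eaten_food - eaten_poison) / (2.0 * n_nutritious)


def _probe_decision(state, season, item, items_per_season):
    """Learning-disabled single decision pass for one item."""
    if isinstance(state, NetworkState):
        from .environment import encode_item_input

        out = state.forward_pass(
            encode_item_input(season, item, items_per_season))
        return out > 0.0
    return bool(state.choose(season, item))


def knowledge_probe(state, spec: EnvironmentSpec, season: int) -> KnowledgeProbe:
    """Does the agent currently know the season's associations?

    Presents each in-season item (decision pass only, learning off);
    never touches plastic weights.
    """
    responses = []
    knows = True
    for item in range(spec.items_per_season):
        ate = _probe_decision(state, season, item, spec.items_per_season)
        correct = ate == bool(spec.edibility[season, item])
        knows = knows and correct
        responses.append((item, ate, correct))
    return KnowledgeProbe(SEASON_NAMES[season], knows, responses)


def association_metrics(state, n_environments: int = 80, rng=None,
                        reset_mode: str | None = "randomize") -> AssociationMetrics:
    """Perfect / Known / Forgotten / Retained counters over many lifetimes.

    At the end of each season both association sets are probed (learning
    off).  Known counts every known set at every season end; Perfect
    counts season ends at which both sets are known; Forgotten/Retained
    count sets known at one season end that are lost/kept at the next.
    """
    if rng is None:
        rng = np.random.default_rng()
    metrics = AssociationMetrics(n_environments=n_environments)
    for _ in range(n_environments):
        spec = generate_environment(rng)
        if isinstance(state, NetworkState):
            if reset_mode is not None:
                mode = reset_mode if state.neuromodulation_enabled else "genetic"
                state.reset_plastic_weights(mode, rng)
        else:
            state.begin_lifetime(rng)
        n_seasons = spec.seasons_per_year * spec.years
        metrics.seasons_per_lifetime = n_seasons
        prev_known = None
        for s in range(n_seasons):
            for d in range(s * spec.days_per_season,
                           (s + 1) * spec.days_per_season):
                run_day(state, spec, d, learning=True)
            known_now = [knowledge_probe(state, spec, season).knows
                         for season in range(spec.seasons_per_year)]
            metrics.known += sum(known_now)
            metrics.perfect += int(all(known_now))
            if prev_known is not None:
                for was, is_now in zip(prev_known, known_now):
                    if was:
                        if is_now:
                            metrics.retained += 1
                        else:
                            metrics.forgotten += 1
            prev_known = known_now
    return metrics


def retention_experiment(state, rng, old_days: int = 50, new_days: int = 20,
                         old_season: int = WINTER, new_season: int = SUMMER,
                         items_per_season: int = 4) -> RetentionCurves:
    """Train long on one season, then track forgetting while training on
    the other.

    The agent learns ``old_days`` days of the old season (winter by
    default), its old-task score is recorded as the baseline (learning
    off), and then for each of ``new_days`` days it trains one day on the
    new season followed by learning-disabled probes of the old-task
    score (normalized by baseline), the new-task score, and their mean.
    A baseline at or below the chance score 0.5 flags a non-learner.
    """
    spec = generate_environment(rng)
    edibility = spec.edibility
    if isinstance(state, NetworkState):
        mode = "randomize" if state.neuromodulation_enabled else "genetic"
        state.reset_plastic_weights(mode, rng)
    else:
        state.begin_lifetime(rng)
    for _ in range(old_days):
        order = rng.permutation(items_per_season)
        _present_items(state, edibility, old_season, order,
                       items_per_season, learn=True)
    probe_order = np.arange(items_per_season)
    _, baseline = _present_items(state, edibility, old_season, probe_order,
                                 items_per_season, learn=False)
    old_raw = np.zeros(new_days)
    new_raw = np.zeros(new_days)
    for d in range(new_days):
        order = rng.permutation(items_per_season)
        _present_items(state, edibility, new_season, order,
                       items_per_season, learn=True)
        _, old_raw[d] = _present_items(state, edibility, old_season,
                                       probe_order, items_per_season,
                                       learn=False)
        _, new_raw[d] = _present_items(state, edibility, new_season,
                                       probe_order, items_per_season,
                                       learn=False)
    non_learner = baseline <= 0.5
    normalized = old_raw / baseline if baseline > 0 else np.full(new_days, np.nan)
    return RetentionCurves(float(baseline), normalized, old_raw, new_raw,
                           (old_raw + new_raw) / 2.0, non_learner)
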