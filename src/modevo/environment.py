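"""Seasonal association-learning environments.

A *lifetime* alternates between a summer and a winter season over three
years.  Each season has four food items, exactly two of which are
nutritious; each day the agent encounters all four in-season items in a
random order, decides whether to eat each, and receives a reward or
punishment signal when it eats a nutritious or poisonous item.  Which
items are edible is re-randomized for every environment, so good
performance requires within-lifetime learning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import (LAYER_SIZES, NetworkState, PUNISHMENT_INPUT,
                      REWARD_INPUT, _SIZES)

SEASON_NAMES = ("summer", "winter")


@dataclass
class EnvironmentSpec:
    """One randomized lifetime: edibility assignments plus daily orders."""

    edibility: np.ndarray          # (seasons_per_year, items) bool, True = nutritious
    day_orders: np.ndarray         # (total_days, items) int
    seasons_per_year: int = 2
    days_per_season: int = 5
    years: int = 3
    items_per_season: int = 4
    seed: int | None = None

    @property
    def total_days(self) -> int:
        return self.days_per_season * self.seasons_per_year * self.years

    @property
    def encounters_per_lifetime(self) -> int:
        return self.total_days * self.items_per_season

    def season_of_day(self, day: int) -> int:
        return (day // self.days_per_season) % self.seasons_per_year

    def season_name(self, day: int) -> str:
        return SEASON_NAMES[self.season_of_day(day)]

    def season_boundaries(self) -> list[int]:
        """Day indices (>0) on which a new season starts."""
        return [d for d in range(1, self.total_days)
                if d % self.days_per_season == 0]

    def day_seasons(self) -> np.ndarray:
        cached = getattr(self, "_day_seasons", None)
        if cached is None:
            cached = np.array([self.season_of_day(d)
                               for d in range(self.total_days)], dtype=np.int64)
            self._day_seasons = cached
        return cached

    def validate(self) -> None:
        if self.edibility.shape != (self.seasons_per_year, self.items_per_season):
            raise ValueError("edibility shape mismatch")
        want = self.items_per_season // 2
        if not np.all(self.edibility.sum(axis=1) == want):
            raise ValueError("each season must have exactly half nutritious items")
        if self.day_orders.shape != (self.total_days, self.items_per_season):
            raise ValueError("day_orders shape mismatch")
        ref = np.arange(self.items_per_season)
        for d in range(self.total_days):
            if not np.array_equal(np.sort(self.day_orders[d]), ref):
                raise ValueError(f"day {d} order is not a permutation")

    def to_dict(self) -> dict:
        return {
            "seasons_per_year": self.seasons_per_year,
            "days_per_season": self.days_per_season,
            "years": self.years,
            "items_per_season": self.items_per_season,
            "seed": self.seed,
            "edibility": self.edibility.astype(int).tolist(),
            "day_orders": self.day_orders.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentSpec":
        spec = cls(
            edibility=np.asarray(d["edibility"], dtype=bool),
            day_orders=np.asarray(d["day_orders"], dtype=np.int64),
            seasons_per_year=d["seasons_per_year"],
            days_per_season=d["days_per_season"],
            years=d["years"],
            items_per_season=d["items_per_season"],
            seed=d.get("seed"),
        )
        spec.validate()
        return spec


@dataclass
class Encounter:
    day: int
    season: str
    item: int
    ate: bool
    outcome: str  # reward | punishment | none


@dataclass
class TrialRecord:
    """Everything recorded over one lifetime."""

    encounters: list[Encounter]
    choice_vector: np.ndarray      # bool, one entry per encounter
    day_scores: np.ndarray         # float in [0, 1], one per day
    season_end_probes: list = field(default_factory=list)

    @property
    def lifetime_performance(self) -> float:
        return float(self.day_scores.mean())

    def to_dict(self) -> dict:
        return {
            "choice_vector": self.choice_vector.astype(int).tolist(),
            "day_scores": self.day_scores.tolist(),
            "encounters": [
                {"day": e.day, "season": e.season, "item": int(e.item),
                 "ate": bool(e.ate), "outcome": e.outcome}
                for e in self.encounters
            ],
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def generate_environment(rng, seasons_per_year: int = 2,
                         days_per_season: int = 5, years: int = 3,
                         items_per_season: int = 4,
                         seed: int | None = None) -> EnvironmentSpec:
    """Draw a random environment: independent uniform 2-of-4 edibility per
    season and a uniform item permutation per day."""
    edibility = np.zeros((seasons_per_year, items_per_season), dtype=bool)
    half = items_per_season // 2
    for s in range(seasons_per_year):
        nutritious = rng.choice(items_per_season, size=half, replace=False)
        edibility[s, nutritious] = True
    total_days = days_per_season * seasons_per_year * years
    day_orders = np.stack([rng.permutation(items_per_season)
                           for _ in range(total_days)]).astype(np.int64)
    spec = EnvironmentSpec(edibility, day_orders,
                           seasons_per_year, days_per_season, years,
                           items_per_season, seed)
    spec.validate()
    return spec


def environment_space_accounting(seasons_per_year: int = 2,
                                 days_per_season: int = 5, years: int = 3,
                                 items_per_season: int = 4):
    """The environment-count bookkeeping for the default task.

    Counts presentation orders as (permutations per day) x (days per
    lifetime) and multiplies by the squared number of 2-of-4 edibility
    choices: 24 x 30 = 720 orders, 6 x 6 = 36 assignments, 25,920 total.
    """
    total_days = days_per_season * seasons_per_year * years
    orders_per_lifetime = math.factorial(items_per_season) * total_days
    association_assignments = math.comb(items_per_season,
                                        items_per_season // 2) ** seasons_per_year
    return (orders_per_lifetime, association_assignments,
            orders_per_lifetime * association_assignments)


def encode_item_input(season: int, item: int, items_per_season: int = 4,
                      reward: float = 0.0, punishment: float = 0.0) -> np.ndarray:
    """Input vector for one encounter: one-hot item (summer items map to
    inputs 0-3, winter to 4-7) plus reward/punishment signal inputs."""
    x = np.zeros(LAYER_SIZES[0])
    x[season * items_per_season + item] = 1.0
    x[REWARD_INPUT] = reward
    x[PUNISHMENT_INPUT] = punishment
    return x


def _check_input_capacity(spec: EnvironmentSpec) -> None:
    if spec.seasons_per_year * spec.items_per_season > REWARD_INPUT:
        raise ValueError("item inputs would collide with the reinforcement inputs")


# -- running networks through days and lifetimes -----------------------

def run_day(state, spec: EnvironmentSpec, day: int,
            learning: bool | None = None):
    """Present one day's items (in the spec's order) to a network or a
    scripted agent; returns (encounters, day score)."""
    if day >= spec.total_days:
        raise ValueError(f"day {day} beyond lifetime of {spec.total_days}")
    season = spec.season_of_day(day)
    items = spec.day_orders[day]
    if isinstance(state, NetworkState):
        _check_input_capacity(spec)
        learn = state.learning_enabled if learning is None else learning
        ate = np.zeros(len(items), dtype=bool)
        score = _kernels.run_day(
            state.w_act, state.w_mod, state.bias, state.plastic, _SIZES,
            state.steepness, state.eta, state.neuromodulation_enabled,
            learn, state.activations, state.modulation,
            items, season, spec.edibility, spec.items_per_season,
            REWARD_INPUT, PUNISHMENT_INPUT, ate)
    else:  # scripted agent
        learn = True if learning is None else learning
        ate = np.zeros(len(items), dtype=bool)
        eaten_food = eaten_poison = 0
        for k, item in enumerate(items):
            item = int(item)
            ate[k] = state.choose(season, item)
            nutritious = bool(spec.edibility[season, item])
            if ate[k]:
                if nutritious:
                    eaten_food += 1
                else:
                    eaten_poison += 1
            if learn:
                outcome = ("reward" if ate[k] and nutritious
                           else "punishment" if ate[k] else "none")
                state.observe(season, item, bool(ate[k]), outcome)
        n_nutritious = int(spec.edibility[season].sum())
        score = 0.5 + (eaten_food - eaten_poison) / (2.0 * n_nutritious)
    encounters = []
    for k, item in enumerate(items):
        nutritious = bool(spec.edibility[season, int(item)])
        outcome = ("reward" if ate[k] and nutritious
                   else "punishment" if ate[k] else "none")
        encounters.append(Encounter(day, SEASON_NAMES[season], int(item),
                                    bool(ate[k]), outcome))
    return encounters, float(score)


def run_lifetime(state, spec: EnvironmentSpec, learning: bool = True,
                 forced_forgetting: bool = False,
                 reset_mode: str | None = "randomize",
                 rng=None) -> TrialRecord:
    """Run a full lifetime, optionally randomizing plastic weights at
    every season boundary (the forced-forgetting ablation).

    ``reset_mode`` resets plastic weights before day 1 (None skips the
    reset, e.g. to continue from a trained state).
    """
    if isinstance(state, NetworkState):
        _check_input_capacity(spec)
        if reset_mode is not None:
            state.reset_plastic_weights(reset_mode, rng)
        boundaries = np.asarray(spec.season_boundaries() if forced_forgetting
                                else [], dtype=np.int64)
        if forced_forgetting:
            if rng is None:
                raise ValueError("forced forgetting requires an rng")
            reset_values = rng.uniform(
                -1, 1, size=(len(boundaries),) + state.w_act.shape)
        else:
            reset_values = np.zeros((0,) + state.w_act.shape)
        choices = np.zeros(spec.encounters_per_lifetime, dtype=bool)
        day_scores = np.zeros(spec.total_days)
        _kernels.run_lifetime(
            state.w_act, state.w_mod, state.bias, state.plastic, _SIZES,
            state.steepness, state.eta, state.neuromodulation_enabled,
            learning, state.activations, state.modulation,
            spec.day_orders, spec.day_seasons(), spec.edibility,
            spec.items_per_season, REWARD_INPUT, PUNISHMENT_INPUT,
            boundaries, reset_values, choices, day_scores)
        encounters = []
        for d in range(spec.total_days):
            season = spec.season_of_day(d)
            for k, item in enumerate(spec.day_orders[d]):
                ate = bool(choices[d * spec.items_per_season + k])
                nutritious = bool(spec.edibility[season, int(item)])
                outcome = ("reward" if ate and nutritious
                           else "punishment" if ate else "none")
                encounters.append(Encounter(d, SEASON_NAMES[season],
                                            int(item), ate, outcome))
        return TrialRecord(encounters, choices, day_scores)
    # scripted agent
    state.begin_lifetime(rng)
    encounters, choices, day_scores = [], [], []
    for d in range(spec.total_days):
        if forced_forgetting and d in spec.season_boundaries():
            state.forget()
        enc, score = run_day(state, spec, d, learning=learning)
        encounters.extend(enc)
        choices.extend(e.ate for e in enc)
        day_scores.append(score)
    return TrialRecord(encounters, np.asarray(choices, dtype=bool),
                       np.asarray(day_scores))


def generation_environments(rng, n_environments: int,
                            **spec_kwargs) -> list[EnvironmentSpec]:
    """The shared environment set for one generation (or evaluation)."""
    return [generate_environment(rng, **spec_kwargs)
            for _ in range(n_environments)]


def evaluate_performance(genome_or_state, n_environments: int, rng,
                         eta: float = 0.04, steepness: float = 5.0,
                         neuromodulation_enabled: bool = True,
                         forced_forgetting: bool = False,
                         environments: list[EnvironmentSpec] | None = None,
                         return_records: bool = False):
    """Mean lifetime performance over ``n_environments`` random lifetimes.

    Plastic weights are re-randomized before each lifetime (reset to the
    genetic weights when neuromodulation is disabled).  Pass
    ``environments`` to evaluate on a pre-drawn shared set.
    """
    if n_environments < 1:
        raise ValueError("need at least one environment")
    from .network import Genome  # local import to avoid cycle confusion

    if isinstance(genome_or_state, Genome):
        state = NetworkState(genome_or_state, eta=eta, steepness=steepness,
                             neuromodulation_enabled=neuromodulation_enabled)
    else:
        state = genome_or_state
    if environments is None:
        environments = generation_environments(rng, n_environments)
    reset = ("randomize"
             if (isinstance(state, NetworkState) and state.neuromodulation_enabled)
             else "genetic" if isinstance(state, NetworkState) else None)
    records = []
    for spec in environments:
        rec = run_lifetime(state, spec, learning=True,
                           forced_forgetting=forced_forgetting,
                           reset_mode=reset, rng=rng)
        records.append(rec)
    mean_perf = float(np.mean([r.lifetime_performance for r in records]))
    if return_records:
        return mean_perf, records
    return mean_perf


def day_scores_frame(records: list[TrialRecord], run: int = 0):
    """Tidy per-day scores (run, lifetime, day, season, score)."""
    import pandas as pd

    rows = []
    for k, rec in enumerate(records):
        seen_days = sorted({e.day for e in rec.encounters})
        season_of = {e.day: e.season for e in rec.encounters}
        for d, s in zip(seen_days, rec.day_scores):
            rows.append({"run": run, "lifetime": k, "day": d,
                         "season": season_of[d], "score": float(s)})
    return pd.DataFrame(rows)
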