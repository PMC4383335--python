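"""Treatment orchestration: replicated evolution runs and comparisons.

A *treatment* is an evolutionary condition: PA (selection on performance
and diversity alone) or PCC (adds the stochastic connection-cost
objective), each optionally combined with the forced-forgetting or
no-neuromodulation ablation.  Analyses operate on the highest-performing
network of each run, re-evaluated on 80 fresh lifetimes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .environment import evaluate_performance
from .evolution import EvolutionConfig, MutationRates, run_evolution
from .forgetting import association_metrics
from .modularity import genome_modularity
from .network import Genome, NetworkState
from . import stats

TREATMENTS = ("PA", "PCC", "PA_forced", "PCC_forced", "PA_nomod", "PCC_nomod")

#: Problem-size presets.  ``paper`` matches the original study conditions;
#: ``reduced`` is the scale used for directional treatment comparisons on
#: a single CPU; ``smoke`` is for quick checks and CI-sized runs.
PRESETS = {
    "paper": {"population_size": 400, "generations": 20_000, "repeats": 100},
    "reduced": {"population_size": 100, "generations": 2_000, "repeats": 20},
    "smoke": {"population_size": 50, "generations": 250, "repeats": 8},
}


@dataclass
class TreatmentConfig:
    treatment: str = "PCC"
    repeats: int = 20
    population_size: int = 100
    generations: int = 2000
    p_cc: float = 0.75
    master_seed: int = 0
    n_final_environments: int = 80
    mutation_rates: MutationRates = field(default_factory=MutationRates)
    eta: float = 0.04
    steepness: float = 5.0
    compute_forgetting_metrics: bool = False
    forgetting_environments: int = 80

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")

    @property
    def base_treatment(self) -> str:
        return "PCC" if self.treatment.startswith("PCC") else "PA"

    @property
    def forced_forgetting(self) -> bool:
        return self.treatment.endswith("_forced")

    @property
    def no_neuromodulation(self) -> bool:
        return self.treatment.endswith("_nomod")

    def evolution_config(self, run: int) -> EvolutionConfig:
        return EvolutionConfig(
            population_size=self.population_size,
            generations=self.generations,
            p_cc=self.p_cc,
            treatment=self.base_treatment,
            forced_forgetting=self.forced_forgetting,
            no_neuromodulation=self.no_neuromodulation,
            n_final_environments=self.n_final_environments,
            mutation_rates=self.mutation_rates,
            eta=self.eta,
            steepness=self.steepness,
            master_seed=int(np.random.SeedSequence(
                [self.master_seed, run]).generate_state(1)[0] % (2**31)),
        )

    @classmethod
    def from_preset(cls, treatment: str, preset: str = "reduced",
                    **overrides) -> "TreatmentConfig":
        kwargs = dict(PRESETS[preset])
        kwargs.update(overrides)
        return cls(treatment=treatment, **kwargs)


@dataclass
class StudyResult:
    """One record per repeat: the best network of each run plus its
    re-evaluated performance, structure, and modularity."""

    config: TreatmentConfig
    records: list[dict]
    genomes: list[Genome]

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def values(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records], dtype=float)

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "records.json"), "w") as fh:
            json.dump({"treatment": self.config.treatment,
                       "records": self.records}, fh, indent=1)
        for r, g in zip(self.records, self.genomes):
            g.to_json(os.path.join(directory, f"best_run{r['run']}.json"))


def analyze_best(genome: Genome, config: TreatmentConfig, rng) -> dict:
    """Final analysis of one run's best network."""
    record = {
        "connections": genome.connection_count,
    }
    perf = evaluate_performance(
        genome, config.n_final_environments, rng,
        eta=config.eta, steepness=config.steepness,
        neuromodulation_enabled=not config.no_neuromodulation,
        forced_forgetting=config.forced_forgetting)
    record["performance"] = perf
    for null, key in (("directed_configuration", "q"),
                      ("layered_feedforward", "q_layered")):
        res = genome_modularity(genome, null_model=null)
        record[key] = res.q
        if null == "directed_configuration":
            record["n_modules"] = res.n_modules
            record["separate_module"] = bool(res.separate_learning_module) \
                if res.separate_learning_module is not None else False
    if config.compute_forgetting_metrics:
        state = NetworkState(
            genome, eta=config.eta, steepness=config.steepness,
            neuromodulation_enabled=not config.no_neuromodulation)
        m = association_metrics(state, config.forgetting_environments, rng)
        record.update({f"assoc_{k}": v for k, v in m.to_dict().items()})
    return record


def run_treatment(config: TreatmentConfig, save_dir=None,
                  progress: bool = False) -> StudyResult:
    """Execute ``repeats`` independent evolution runs of one treatment.

    When ``save_dir`` is given, each completed run is written to disk
    immediately and already-saved runs are skipped on restart, making
    interrupted studies resumable at run granularity.
    """
    records: list[dict] = []
    genomes: list[Genome] = []
    for run in range(config.repeats):
        run_path = (os.path.join(save_dir, f"run{run}.json")
                    if save_dir else None)
        if run_path and os.path.exists(run_path):
            with open(run_path) as fh:
                saved = json.load(fh)
            records.append(saved["record"])
            genomes.append(Genome.from_dict(saved["genome"]))
            continue
        evo_cfg = config.evolution_config(run)
        result = run_evolution(evo_cfg)
        rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, run, 999]))
        record = analyze_best(result.best.genome, config, rng)
        record.update({
            "run": run,
            "treatment": config.treatment,
            "seed": evo_cfg.master_seed,
            "evolution_performance": result.best.performance,
            "final_median_connections": result.log[-1]["median_connections"]
            if result.log else float("nan"),
        })
        records.append(record)
        genomes.append(result.best.genome)
        if run_path:
            os.makedirs(save_dir, exist_ok=True)
            with open(run_path, "w") as fh:
                json.dump({"record": record,
                           "genome": result.best.genome.to_dict()}, fh)
        if progress:
            print(f"[{config.treatment}] run {run}: "
                  f"perf={record['performance']:.3f} "
                  f"conn={record['connections']} q={record['q']:.3f}")
    result = StudyResult(config, records, genomes)
    if save_dir:
        result.save(save_dir)
    return result


def compare_treatments(a: StudyResult, b: StudyResult,
                       metrics=("performance", "q", "q_layered",
                                "connections"),
                       rng=None) -> list[dict]:
    """Per-metric medians, bootstrap CIs, and Mann-Whitney p-values for
    two treatments (two-sided test)."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for metric in metrics:
        xa, xb = a.values(metric), b.values(metric)
        u, p = stats.mann_whitney_u(xa, xb)
        rows.append({
            "metric": metric,
            "treatment_a": a.config.treatment,
            "treatment_b": b.config.treatment,
            "median_a": float(np.median(xa)),
            "ci_a": stats.bootstrap_median_ci(xa, rng=rng),
            "median_b": float(np.median(xb)),
            "ci_b": stats.bootstrap_median_ci(xb, rng=rng),
            "u": u, "p": p,
        })
    return rows


def directional_suite(preset: str = "reduced", master_seed: int = 0,
                      treatments=("PA", "PCC"), save_dir=None,
                      progress: bool = False) -> dict:
    """Run the cross-treatment comparison suite at a chosen problem size.

    Returns the per-treatment study results plus one-sided Mann-Whitney
    tests of the directional claims: PCC more modular, sparser, and at
    least as high-performing as PA; a separate-learning-module fraction
    at least as large.
    """
    studies = {}
    for i, t in enumerate(treatments):
        cfg = TreatmentConfig.from_preset(t, preset,
                                          master_seed=master_seed + 1000 * i)
        sub = os.path.join(save_dir, t) if save_dir else None
        studies[t] = run_treatment(cfg, save_dir=sub, progress=progress)
    out = {"studies": studies, "tests": {}}
    if "PA" in studies and "PCC" in studies:
        pa, pcc = studies["PA"], studies["PCC"]
        tests = out["tests"]
        for metric, alternative in (("q", "greater"),
                                    ("q_layered", "greater"),
                                    ("connections", "less"),
                                    ("performance", "greater")):
            u, p = stats.mann_whitney_u(pcc.values(metric), pa.values(metric),
                                        alternative=alternative)
            tests[f"{metric}_{alternative}"] = {
                "median_pcc": float(np.median(pcc.values(metric))),
                "median_pa": float(np.median(pa.values(metric))),
                "u": u, "p": p}
        tests["separate_module_fraction"] = {
            "pcc": float(np.mean(pcc.values("separate_module"))),
            "pa": float(np.mean(pa.values("separate_module")))}
    return out
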