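"""Generational evolution of developmental genomes, with germline penetration.

Each generation every genome is developed and scored against the target;
elites are carried unchanged, and the rest of the next population is produced
by tournament selection, one-point crossover, per-field mutation and — when
enabled — germline penetration, which appends inactive genetic units built
from the dormant driver states of the offspring's fitter parent.  Penetration
runs AFTER mutation, so a unit inserted this generation cannot be activated
in the same offspring: activation is strictly a later, ordinary mutation.

All randomness flows from a single master seed through per-generation,
per-offspring derived streams (numpy ``SeedSequence`` spawning), so a run is
a pure function of (engine config, evolution config, target).

The ablation harness runs paired replicates with penetration on and off.
With exact MOS/MOC matching over the default 10^8 code space, the off arm
cannot acquire a first match by mutation (MOS symbols are immutable by
default and a random match is essentially impossible), so its fitness stays
flat while the on arm bootstraps development from the founder's dormant code
and keeps climbing — the stochastic-ordering claim the harness tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binomtest

from ._io import atomic_write_text
from .config import EngineConfig, _load_yaml_mapping
from .engine import develop, dormant_mocs
from .errors import ConfigError, FormatError
from .genome import Genome, MutationRates, mutate, random_genome, recombine
from .penetration import penetrate
from .targets import FitnessWeights, TargetShape, fitness

GENERATION_LOG_COLUMNS = [
    "generation",
    "best_fitness",
    "mean_fitness",
    "best_genome_length",
    "n_penetrated_this_gen",
    "seed",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the evolutionary loop."""

    pop_size: int = 40
    n_generations: int = 200
    tournament_size: int = 3
    p_crossover: float = 0.5
    rates: MutationRates = field(default_factory=MutationRates)
    elitism_count: int = 2
    penetration_enabled: bool = True
    k_max: int = 2
    master_seed: int = 0
    initial_genome_length: int = 8
    bootstrap_match: bool = False
    weights: FitnessWeights = field(default_factory=FitnessWeights)

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigError(f"pop_size must be >= 2, got {self.pop_size}")
        if self.n_generations < 0:
            raise ConfigError(f"n_generations must be >= 0, got {self.n_generations}")
        if not 0 <= self.elitism_count < self.pop_size:
            raise ConfigError(
                f"elitism_count must be in [0, pop_size), got {self.elitism_count}"
            )
        if self.tournament_size < 1:
            raise ConfigError(f"tournament_size must be >= 1, got {self.tournament_size}")
        if not 0.0 <= self.p_crossover <= 1.0:
            raise ConfigError(f"p_crossover must be in [0, 1], got {self.p_crossover}")
        if self.k_max < 0:
            raise ConfigError(f"k_max must be >= 0, got {self.k_max}")
        if self.initial_genome_length < 1:
            raise ConfigError(
                f"initial_genome_length must be >= 1, got {self.initial_genome_length}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class EvolveResult:
    champion: Genome
    champion_fitness: float
    log: pd.DataFrame  # one row per generation (GENERATION_LOG_COLUMNS)
    penetration_events: pd.DataFrame  # generation, individual_id, moc, unit_index


def _evaluate(genome: Genome, engine: EngineConfig, target, weights):
    embryo, record = develop(genome, engine)
    return fitness(embryo, target, weights).fitness, record


def _tournament(fitnesses: list[float], size: int, rng: np.random.Generator) -> int:
    idx = rng.integers(0, len(fitnesses), size=size)
    best = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if fitnesses[i] > fitnesses[best] or (
            fitnesses[i] == fitnesses[best] and i < best
        ):
            best = i
    return best


def evolve(
    engine_config: EngineConfig,
    evo_config: EvolutionConfig,
    target: TargetShape,
) -> EvolveResult:
    """Run the full evolutionary loop; returns the best genome ever seen.

    With ``elitism_count >= 1`` the per-generation best fitness is checked to
    be non-decreasing while the run executes; a violation raises, because it
    can only mean the loop itself is broken.
    """
    engine = engine_config
    evo = evo_config
    root = np.random.SeedSequence(evo.master_seed)
    init_ss, *gen_ss = root.spawn(evo.n_generations + 1)
    init_rng = np.random.default_rng(init_ss)
    population = [
        random_genome(engine, evo.initial_genome_length, init_rng, evo.bootstrap_match)
        for _ in range(evo.pop_size)
    ]

    champion: Genome = population[0]
    champion_fitness = -np.inf
    prev_best = -np.inf
    log_rows = []
    pen_rows: list[tuple] = []

    for gen in range(evo.n_generations):
        evals = [_evaluate(g, engine, target, evo.weights) for g in population]
        fitnesses = [e[0] for e in evals]
        best_i = int(np.argmax(fitnesses))
        best_f = fitnesses[best_i]
        if best_f > champion_fitness:
            champion, champion_fitness = population[best_i], best_f
        if evo.elitism_count >= 1:
            if best_f < prev_best:
                raise AssertionError(
                    f"elite fitness decreased: {prev_best} -> {best_f} at gen {gen}"
                )
            prev_best = best_f
        n_pen_this_gen = 0

        if gen < evo.n_generations - 1:
            order = sorted(range(evo.pop_size), key=lambda i: (-fitnesses[i], i))
            elites = [population[i] for i in order[: evo.elitism_count]]
            n_offspring = evo.pop_size - len(elites)
            child_ss = gen_ss[gen].spawn(n_offspring)
            offspring = []
            for j in range(n_offspring):
                rng = np.random.default_rng(child_ss[j])
                i1 = _tournament(fitnesses, evo.tournament_size, rng)
                i2 = _tournament(fitnesses, evo.tournament_size, rng)
                if rng.random() < evo.p_crossover:
                    child = recombine(population[i1], population[i2], engine, rng)
                else:
                    child = population[i1]
                child = mutate(child, evo.rates, engine, rng)
                if evo.penetration_enabled and evo.k_max > 0:
                    fitter = i1 if fitnesses[i1] >= fitnesses[i2] else i2
                    pool = dormant_mocs(evals[fitter][1], population[fitter])
                    before = len(child)
                    child = penetrate(child, pool, evo.k_max, engine, rng)
                    for u_idx in range(before, len(child)):
                        moc_str = "-".join(str(s) for s in child.units[u_idx].mos)
                        pen_rows.append((gen, len(elites) + j, moc_str, u_idx))
                        n_pen_this_gen += 1
                offspring.append(child)
            next_population = elites + offspring
        else:
            next_population = population

        log_rows.append(
            (
                gen,
                best_f,
                float(np.mean(fitnesses)),
                len(population[best_i]),
                n_pen_this_gen,
                evo.master_seed,
            )
        )
        population = next_population

    if evo.n_generations == 0:
        # no generations to log, but still report the best of the initial pool
        fitnesses = [
            _evaluate(g, engine, target, evo.weights)[0] for g in population
        ]
        best_i = int(np.argmax(fitnesses))
        champion, champion_fitness = population[best_i], fitnesses[best_i]

    log = pd.DataFrame(log_rows, columns=GENERATION_LOG_COLUMNS)
    pen = pd.DataFrame(
        pen_rows, columns=["generation", "individual_id", "moc", "unit_index"]
    )
    return EvolveResult(champion, float(champion_fitness), log, pen)


# ---------------------------------------------------------------------------
# Ablation experiment
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    table: pd.DataFrame  # replicate, seed, fitness_on, fitness_off
    median_on: float
    median_off: float
    n_on_greater: int
    n_informative: int
    sign_test_p: float


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Paired per-replicate seeds derived from the master seed (below 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n_replicates)
    return [int(s) % 2**31 for s in state]


def ablation_experiment(
    engine_config: EngineConfig,
    evo_config: EvolutionConfig,
    target: TargetShape,
    n_replicates: int = 5,
) -> AblationResult:
    """Paired comparison of evolution with and without germline penetration.

    Each replicate runs both arms from the same derived seed, differing only
    in ``penetration_enabled``; the summary reports per-arm medians of the
    final champion fitness and a paired sign test (binomial, one-sided:
    on > off) over the informative (non-tied) pairs.
    """
    if n_replicates < 3:
        raise ConfigError(f"n_replicates must be >= 3, got {n_replicates}")
    seeds = replicate_seeds(evo_config.master_seed, n_replicates)
    rows = []
    for rep, seed in enumerate(seeds):
        per_arm = {}
        for arm in (True, False):
            cfg = dataclasses.replace(
                evo_config, master_seed=seed, penetration_enabled=arm
            )
            per_arm[arm] = evolve(engine_config, cfg, target).champion_fitness
        rows.append((rep, seed, per_arm[True], per_arm[False]))
    table = pd.DataFrame(rows, columns=["replicate", "seed", "fitness_on", "fitness_off"])
    diffs = table["fitness_on"] - table["fitness_off"]
    n_informative = int((diffs != 0).sum())
    n_on_greater = int((diffs > 0).sum())
    if n_informative > 0:
        p = float(binomtest(n_on_greater, n_informative, alternative="greater").pvalue)
    else:
        p = 1.0
    return AblationResult(
        table=table,
        median_on=float(table["fitness_on"].median()),
        median_off=float(table["fitness_off"].median()),
        n_on_greater=n_on_greater,
        n_informative=n_informative,
        sign_test_p=p,
    )


# ---------------------------------------------------------------------------
# Run configuration files ({engine: ..., evolution: ...} YAML)
# ---------------------------------------------------------------------------

def _evolution_config_from_dict(data: dict) -> EvolutionConfig:
    known = {f.name for f in dataclasses.fields(EvolutionConfig)}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown evolution config keys: {sorted(unknown)}")
    data = dict(data)
    if "rates" in data:
        data["rates"] = MutationRates(**data["rates"])
    if "weights" in data:
        data["weights"] = FitnessWeights(**data["weights"])
    return EvolutionConfig(**data)


def load_run_config(path: str | Path) -> tuple[EngineConfig, EvolutionConfig]:
    """Read a run config: YAML with ``engine:`` and ``evolution:`` sections
    (the evolution section is optional and defaults apply)."""
    data = _load_yaml_mapping(path)
    if "engine" not in data:
        raise FormatError(f"{path}: run config needs an 'engine' section")
    engine = EngineConfig.from_dict(data["engine"])
    try:
        evo = _evolution_config_from_dict(data.get("evolution", {}))
    except TypeError as exc:
        raise FormatError(f"{path}: bad evolution config: {exc}") from exc
    extra = set(data) - {"engine", "evolution"}
    if extra:
        raise FormatError(f"{path}: unknown top-level sections {sorted(extra)}")
    return engine, evo


def save_run_config(
    engine: EngineConfig, evo: EvolutionConfig, path: str | Path
) -> None:
    doc = {"engine": engine.to_dict(), "evolution": evo.to_dict()}
    atomic_write_text(path, yaml.safe_dump(doc, sort_keys=True))
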