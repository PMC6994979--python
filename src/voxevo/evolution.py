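"""Evolutionary search over voxel-organism designs.

Search maintains a population of genomes under an age-fitness Pareto
scheme with per-clade truncation: survivors are the Pareto-best
individuals on (locomotion fitness, youth of lineage), with at most a
fixed number of survivors per clade, which keeps young lineages
competing against established ones. Every generation, one brand-new
random genome (a new clade) is injected, and deleted slots are refilled
with mutants of survivors. Fitness is the net displacement achieved in a
10-s evaluation (after 1 s of settling) under randomized phase-modulated
contraction cycling at 2 Hz.

Two operating modes mirror the pipeline's two passes: ``first_pass``
runs on land and lets evolution fine-tune the phase offsets;
``second_pass`` runs in the aquatic environment with each clade's random
phase offsets hardcoded at founding.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional

import numpy as np

from .errors import (ConfigurationError, MutationFailureError,
                     SimulationUnstableError)
from . import genome as G
from .physics import (ActuationConfig, EnvironmentConfig, SimulationConfig,
                      simulate)

#: Sentinel fitness for empty phenotypes and unstable simulations.
WORST_FITNESS = float("-inf")


@dataclasses.dataclass
class EvolutionConfig:
    population_size: int = 50
    generations: int = 100
    n_trials: int = 100
    mode: str = "second_pass"   # first_pass (land) | second_pass (aquatic)
    seed: int = 0
    fitness: str = "net_displacement"
    resolution: tuple = G.DEFAULT_WORKSPACE
    clade_quota: int = 3        # max survivors per clade
    survivor_fraction: float = 0.5
    phase_noise_sd: float = 0.4 * math.pi  # per-evaluation modulation
    genome: G.GenomeConfig = dataclasses.field(default_factory=G.GenomeConfig)
    env: Optional[EnvironmentConfig] = None  # default chosen by mode
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    act: ActuationConfig = dataclasses.field(default_factory=ActuationConfig)

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.generations < 0 or self.n_trials < 1:
            raise ConfigurationError("need generations >= 0 and n_trials >= 1")
        if self.mode not in ("first_pass", "second_pass"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.fitness != "net_displacement":
            raise ConfigurationError(f"unknown fitness {self.fitness!r}")
        self.genome.validate()

    def environment(self) -> EnvironmentConfig:
        if self.env is not None:
            return self.env
        return (EnvironmentConfig.terrestrial() if self.mode == "first_pass"
                else EnvironmentConfig.aquatic())


@dataclasses.dataclass(eq=False)
class Individual:
    genome: G.Genome
    design: G.VoxelDesign
    fitness: Optional[float] = None

    @property
    def clade_id(self) -> int:
        return self.genome.clade_id

    @property
    def age(self) -> int:
        return self.genome.age


@dataclasses.dataclass(eq=False)
class RunResult:
    champion: Individual
    log: list                     # per generation: {clade_id: best fitness}
    population: List[Individual]  # final population
    trial_seed: int = 0

    def log_dataframe(self):
        import pandas as pd

        rows = [{"generation": g, "clade_id": cid, "best_fitness": fit}
                for g, gen in enumerate(self.log)
                for cid, fit in sorted(gen.items())]
        return pd.DataFrame(rows,
                            columns=["generation", "clade_id", "best_fitness"])


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def evaluate_fitness(ind: Individual, env: EnvironmentConfig,
                     sim: SimulationConfig, act: ActuationConfig,
                     seed: int, phase_noise_sd: float = 0.4 * math.pi,
                     events: Optional[list] = None) -> float:
    """Score one individual: net displacement under phase modulation.

    Empty phenotypes and numerically unstable simulations receive the
    worst-fitness sentinel (and are logged) so selection discards them.
    """
    if ind.design.is_empty:
        ind.fitness = WORST_FITNESS
        if events is not None:
            events.append(f"empty phenotype: clade={ind.clade_id} seed={seed}")
        return ind.fitness
    try:
        result = simulate(ind.design, env, sim, act, seed=seed,
                          phase_noise_sd=phase_noise_sd)
        ind.fitness = result.net_displacement
    except SimulationUnstableError:
        ind.fitness = WORST_FITNESS
        if events is not None:
            events.append(f"unstable: clade={ind.clade_id} seed={seed}")
    return ind.fitness


# ---------------------------------------------------------------------------
# Selection and generational step
# ---------------------------------------------------------------------------


def _pareto_order(population: List[Individual]) -> List[int]:
    """Indices sorted by Pareto rank on (fitness max, age min), then fitness."""
    n = len(population)
    fit = [ind.fitness for ind in population]
    age = [ind.age for ind in population]
    rank = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (fit[j] >= fit[i] and age[j] <= age[i]
                    and (fit[j] > fit[i] or age[j] < age[i])):
                rank[i] += 1  # i is dominated by j
    return sorted(range(n), key=lambda i: (rank[i], -fit[i], age[i], i))


def step_generation(population: List[Individual], config: EvolutionConfig,
                    rng: np.random.Generator,
                    events: Optional[list] = None) -> List[Individual]:
    """Advance the population one generation.

    Survivors are chosen in Pareto order with at most ``clade_quota``
    members per clade; freed slots are refilled with mutants of
    survivors; exactly one fresh random genome (new clade, age 0) is
    injected; every pre-existing clade's age is incremented; population
    size is conserved. New individuals are evaluated here so the
    invariant "everyone has a fitness" holds at every boundary.
    """
    pop_size = config.population_size
    if any(ind.fitness is None for ind in population):
        raise ConfigurationError("all individuals must be evaluated")
    n_survivors_target = max(1, int(pop_size * config.survivor_fraction))
    survivors: List[Individual] = []
    clade_counts: dict = {}
    for i in _pareto_order(population):
        ind = population[i]
        if clade_counts.get(ind.clade_id, 0) >= config.clade_quota:
            continue
        clade_counts[ind.clade_id] = clade_counts.get(ind.clade_id, 0) + 1
        survivors.append(ind)
        if len(survivors) >= n_survivors_target:
            break

    env = config.environment()
    children: List[Individual] = []
    n_children = pop_size - len(survivors) - 1
    for _ in range(n_children):
        child = None
        for _attempt in range(10):  # draw a new parent on mutation failure
            parent = survivors[int(rng.integers(len(survivors)))]
            try:
                g = G.mutate(parent.genome, rng, mode=config.mode,
                             config=config.genome,
                             resolution=config.resolution)
                child = Individual(g, G.develop(g, config.resolution,
                                                config.genome))
                break
            except MutationFailureError:
                if events is not None:
                    events.append(f"mutation failure: clade={parent.clade_id}")
        if child is None:
            # Fall back to an extra random injection; keeps size conserved.
            g = G.random_genome(int(rng.integers(2**31 - 1)), config.genome)
            child = Individual(g, G.develop(g, config.resolution, config.genome))
        children.append(child)

    # Age every pre-existing clade member, then inject a fresh clade at age 0.
    for ind in survivors + children:
        ind.genome.age += 1
    g_new = G.random_genome(int(rng.integers(2**31 - 1)), config.genome)
    injected = Individual(g_new, G.develop(g_new, config.resolution,
                                           config.genome))

    new_pop = survivors + children + [injected]
    if len(new_pop) != pop_size:
        raise ConfigurationError(
            f"population size {len(new_pop)} != {pop_size} after refill")
    for ind in children + [injected]:
        evaluate_fitness(ind, env, config.sim, config.act,
                         seed=int(rng.integers(2**31 - 1)),
                         phase_noise_sd=config.phase_noise_sd, events=events)
    return new_pop


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------


def run_trial(config: EvolutionConfig, trial_seed: int,
              events: Optional[list] = None) -> RunResult:
    """Run one independent evolutionary trial; all randomness from the seed."""
    config.validate()
    rng = np.random.default_rng(int(trial_seed))
    env = config.environment()
    population = []
    for _ in range(config.population_size):
        g = G.random_genome(int(rng.integers(2**31 - 1)), config.genome)
        ind = Individual(g, G.develop(g, config.resolution, config.genome))
        evaluate_fitness(ind, env, config.sim, config.act,
                         seed=int(rng.integers(2**31 - 1)),
                         phase_noise_sd=config.phase_noise_sd, events=events)
        population.append(ind)

    def best_of(pop):
        return max(pop, key=lambda ind: ind.fitness)

    def snapshot(ind):
        return Individual(ind.genome.copy(), ind.design.copy(), ind.fitness)

    champion = snapshot(best_of(population))
    log = []
    for _gen in range(config.generations):
        population = step_generation(population, config, rng, events=events)
        gen_best = best_of(population)
        if gen_best.fitness > champion.fitness:
            champion = snapshot(gen_best)
        per_clade: dict = {}
        for ind in population:
            cur = per_clade.get(ind.clade_id, WORST_FITNESS)
            if ind.fitness > cur:
                per_clade[ind.clade_id] = ind.fitness
        log.append(per_clade)
    return RunResult(champion=champion, log=log, population=population,
                     trial_seed=int(trial_seed))


def run_trials(config: EvolutionConfig,
               events: Optional[list] = None) -> List[RunResult]:
    """Run all independent trials; champions sorted by fitness descending."""
    config.validate()
    trial_seeds = np.random.default_rng(int(config.seed)).integers(
        0, 2**31 - 1, size=config.n_trials)
    results = [run_trial(config, int(s), events=events) for s in trial_seeds]
    results.sort(key=lambda r: -r.champion.fitness)
    return results


def champion_contact_statistics(config: EvolutionConfig,
                                events: Optional[list] = None) -> dict:
    """Run all trials, then measure ground contact of each trial champion.

    Every champion is re-simulated once over the full evaluation window
    (10 s after 1 s settling by default) under a fresh phase-modulation
    draw, and the fraction of output steps with at least one voxel
    touching the ground plane is recorded, along with the airborne
    fraction over whole gait cycles. Returns the per-champion values and
    their means (as percentages of the evaluation period).
    """
    from .analysis import airborne_fraction
    from .physics import contact_fraction, simulate as _simulate

    results = run_trials(config, events=events)
    env = config.environment()
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(
        0, 2**31 - 1) + 1)
    contacts, airbornes, fitnesses = [], [], []
    for res in results:
        sim_res = _simulate(res.champion.design, env, config.sim, config.act,
                            seed=int(rng.integers(2**31 - 1)),
                            phase_noise_sd=config.phase_noise_sd)
        contacts.append(100.0 * contact_fraction(sim_res))
        airbornes.append(100.0 * airborne_fraction(sim_res, config.act))
        fitnesses.append(res.champion.fitness)
    return {
        "contact_percent": contacts,
        "airborne_percent": airbornes,
        "champion_fitness": fitnesses,
        "mean_contact_percent": float(np.mean(contacts)),
        "mean_airborne_percent": float(np.mean(airbornes)),
        "n_champions": len(contacts),
    }
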