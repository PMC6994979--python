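"""Evolutionary search: fitness, selection, injection, reproducibility.

All runs here use micro budgets and short evaluation windows; they test
the machinery's contracts, not locomotion statistics.
"""

import numpy as np
import pytest

import voxevo as V
from voxevo.evolution import (EvolutionConfig, Individual, evaluate_fitness,
                              run_trial, run_trials, step_generation,
                              WORST_FITNESS)


def micro_config(mode="second_pass", **kw):
    kw.setdefault("population_size", 8)
    kw.setdefault("generations", 3)
    kw.setdefault("n_trials", 2)
    kw.setdefault("resolution", (6, 6, 5))
    cfg = EvolutionConfig(mode=mode, seed=11, **kw)
    cfg.sim = V.SimulationConfig(settle_time=0.2, eval_time=1.0)
    return cfg


def evaluated_population(cfg, seed=0):
    rng = np.random.default_rng(seed)
    env = cfg.environment()
    pop = []
    for _ in range(cfg.population_size):
        g = V.random_genome(int(rng.integers(2**31 - 1)), cfg.genome)
        ind = Individual(g, V.develop(g, cfg.resolution, cfg.genome))
        evaluate_fitness(ind, env, cfg.sim, cfg.act,
                         seed=int(rng.integers(2**31 - 1)),
                         phase_noise_sd=cfg.phase_noise_sd)
        pop.append(ind)
    return pop


class TestEvaluateFitness:
    def test_passive_fixture_cannot_locomote(self, solid_block):
        ind = Individual(V.random_genome(0), solid_block)
        fit = evaluate_fitness(ind, V.EnvironmentConfig.terrestrial(),
                               V.SimulationConfig(), V.ActuationConfig(),
                               seed=1, phase_noise_sd=0.0)
        assert fit <= 1e-3

    def test_walker_outperforms_passive_block(self, walker, solid_block):
        env = V.EnvironmentConfig.terrestrial()
        sim, act = V.SimulationConfig(), V.ActuationConfig()
        f_walk = evaluate_fitness(Individual(V.random_genome(0), walker),
                                  env, sim, act, seed=1, phase_noise_sd=0.0)
        f_block = evaluate_fitness(Individual(V.random_genome(0), solid_block),
                                   env, sim, act, seed=1, phase_noise_sd=0.0)
        assert f_walk > f_block

    def test_same_seed_same_fitness(self, walker, fast_sim):
        env = V.EnvironmentConfig.aquatic()
        act = V.ActuationConfig()
        vals = [evaluate_fitness(Individual(V.random_genome(0), walker.copy()),
                                 env, fast_sim, act, seed=42,
                                 phase_noise_sd=0.5)
                for _ in range(2)]
        assert vals[0] == vals[1]

    def test_empty_phenotype_gets_worst_fitness(self):
        g = V.random_genome(3)
        g.presence_bias, g.presence_nodes = -1.0, []
        ind = Individual(g, V.develop(g))
        events = []
        fit = evaluate_fitness(ind, V.EnvironmentConfig.terrestrial(),
                               V.SimulationConfig(), V.ActuationConfig(),
                               seed=0, events=events)
        assert fit == WORST_FITNESS
        assert events


class TestStepGeneration:
    def test_injects_exactly_one_new_clade(self):
        cfg = micro_config()
        pop = evaluated_population(cfg)
        out = step_generation(pop, cfg, np.random.default_rng(2))
        old_clades = {ind.clade_id for ind in pop}
        newcomers = [ind for ind in out
                     if ind.age == 0 and ind.clade_id not in old_clades]
        assert len(newcomers) == 1

    def test_population_size_conserved(self):
        cfg = micro_config()
        pop = evaluated_population(cfg)
        out = step_generation(pop, cfg, np.random.default_rng(2))
        assert len(out) == cfg.population_size
        assert all(ind.fitness is not None for ind in out)

    def test_ages_increment_for_surviving_clades(self):
        cfg = micro_config()
        pop = evaluated_population(cfg)
        out = step_generation(pop, cfg, np.random.default_rng(2))
        survivors = [ind for ind in out if ind.clade_id in
                     {p.clade_id for p in pop}]
        assert survivors and all(ind.age >= 1 for ind in survivors)

    def test_unevaluated_population_rejected(self):
        cfg = micro_config()
        pop = evaluated_population(cfg)
        pop[0].fitness = None
        with pytest.raises(V.ConfigurationError):
            step_generation(pop, cfg, np.random.default_rng(2))


class TestRunTrial:
    def test_champion_is_best_ever_and_log_length(self):
        cfg = micro_config()
        res = run_trial(cfg, trial_seed=5)
        assert len(res.log) == cfg.generations
        gen_bests = [max(g.values()) for g in res.log]
        assert res.champion.fitness == pytest.approx(
            max(gen_bests + [res.champion.fitness]))
        # best-ever must weakly dominate every per-generation best
        assert all(res.champion.fitness >= b for b in gen_bests)

    def test_second_pass_phases_match_clade_founders(self):
        """No individual's phase field ever drifts from its clade founder's."""
        cfg = micro_config(mode="second_pass", generations=4)
        res = run_trial(cfg, trial_seed=9)
        founders = {}
        for ind in res.population:
            key = ind.clade_id
            if key not in founders:
                founders[key] = ind.genome.phase_grid
            assert np.array_equal(ind.genome.phase_grid, founders[key])

    def test_zero_generations_returns_best_initial(self):
        cfg = micro_config(generations=0)
        res = run_trial(cfg, trial_seed=3)
        assert len(res.log) == 0
        assert res.champion.fitness == max(i.fitness for i in res.population)


class TestRunTrials:
    def test_master_seed_reproducibility(self):
        cfg = micro_config()
        a = run_trials(cfg)
        b = run_trials(cfg)
        assert [r.champion.fitness for r in a] == [r.champion.fitness for r in b]
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.champion.design.grid,
                                  rb.champion.design.grid)

    def test_champions_sorted_descending(self):
        res = run_trials(micro_config(n_trials=3))
        fits = [r.champion.fitness for r in res]
        assert fits == sorted(fits, reverse=True)

    def test_diversity_multiple_clades_present(self):
        """Per-generation injection keeps >= 2 clades in the population."""
        cfg = micro_config(generations=6)
        res = run_trial(cfg, trial_seed=21)
        assert len({ind.clade_id for ind in res.population}) >= 2

    def test_search_improves_over_initial_population(self):
        """Evolved champions beat best-of-initial-random-population.

        Paired comparison: a zero-generation run with the same master
        seed reproduces each trial's initial population exactly, so its
        champion is the initial best; evolving must not do worse and
        must strictly improve the mean.
        """
        evolved = run_trials(micro_config(population_size=10, generations=8,
                                          n_trials=3))
        initial = run_trials(micro_config(population_size=10, generations=0,
                                          n_trials=3))
        f_evo = sorted(r.champion.fitness for r in evolved)
        f_init = sorted(r.champion.fitness for r in initial)
        assert all(e >= i for e, i in zip(f_evo, f_init))
        assert np.mean(f_evo) > np.mean(f_init)
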