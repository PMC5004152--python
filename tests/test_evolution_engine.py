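import numpy as np
import pytest

from modevo.evolution_engine import (
    ConnectiveMutationRegime,
    Population,
    ScenarioConfig,
    WeightMutationRegime,
    forward_population,
    get_preset,
    list_presets,
    mutate_connections,
    mutate_weights,
    population_fitness,
    run_scenario,
    run_temporal_separation,
    select_reproduce,
    selection_indices,
)
from modevo.fitness_tasks import evaluate_population
from modevo.network_model import ArchitectureSpec, init_genome
from modevo.pattern_inputs import assemble_input_set


def small_genome(seed=0):
    return init_genome(16, 8, ArchitectureSpec("fcnmn", 16, 8), seed=seed)


class TestMutateWeights:
    def test_zero_sd_leaves_genome_unchanged(self):
        g = small_genome()
        regime = WeightMutationRegime("every_weight", 1.0, 0.0)
        g2 = mutate_weights(g, regime, np.random.default_rng(0))
        assert np.array_equal(g2.w_ih, g.w_ih) and g2.b_o == g.b_o

    def test_every_weight_perturbs_every_parameter(self):
        g = small_genome()
        regime = WeightMutationRegime("every_weight", 1.0, 0.25)
        g2 = mutate_weights(g, regime, np.random.default_rng(0))
        assert (g2.w_ih != g.w_ih).all()
        assert (g2.b_h != g.b_h).all()
        assert (g2.w_ho != g.w_ho).all()
        assert g2.b_o != g.b_o
        assert np.array_equal(g2.m_ih, g.m_ih)  # mask untouched

    def test_inactive_weights_keep_mutating(self):
        g = small_genome()
        g.m_ih[:] = False
        regime = WeightMutationRegime("every_weight", 1.0, 0.25)
        g2 = mutate_weights(g, regime, np.random.default_rng(0))
        assert (g2.w_ih != g.w_ih).all()

    def test_per_weight_probability_matches_binomial_expectation(self):
        g = init_genome(96, 48, ArchitectureSpec("fcnmn", 96, 48), seed=0)
        regime = WeightMutationRegime("per_weight_prob", 1 / 1000, 1.0)
        rng = np.random.default_rng(123)
        trials = 2000
        hits = [
            int((mutate_weights(g, regime, rng).w_ih != g.w_ih).sum())
            for _ in range(trials)
        ]
        expected = 4608 / 1000  # 4.608 input-hidden weights per call
        se = np.sqrt(expected * (1 - 1 / 1000) / trials)
        assert abs(np.mean(hits) - expected) < 3 * se


class TestMutateConnections:
    def test_zero_probability_is_identity(self):
        g = small_genome()
        regime = ConnectiveMutationRegime("symmetric", 0.0)
        assert np.array_equal(
            mutate_connections(g, regime, np.random.default_rng(0)).m_ih, g.m_ih
        )

    def test_symmetric_flip_count_matches_binomial_expectation(self):
        g = init_genome(96, 48, ArchitectureSpec("fcnmn", 96, 48), seed=0)
        regime = ConnectiveMutationRegime("symmetric", 0.001)
        rng = np.random.default_rng(5)
        trials = 2000
        flips = [
            int((mutate_connections(g, regime, rng).m_ih != g.m_ih).sum())
            for _ in range(trials)
        ]
        expected = 4.608
        se = np.sqrt(expected * (1 - 0.001) / trials)
        assert abs(np.mean(flips) - expected) < 3 * se

    def test_irreversible_loss_is_monotone(self):
        g = small_genome()
        regime = ConnectiveMutationRegime("irreversible_loss", 0.2)
        rng = np.random.default_rng(1)
        counts = [int(g.m_ih.sum())]
        for _ in range(20):
            g = mutate_connections(g, regime, rng)
            counts.append(int(g.m_ih.sum()))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_weights_untouched(self):
        g = small_genome()
        g2 = mutate_connections(
            g, ConnectiveMutationRegime("symmetric", 0.5), np.random.default_rng(0)
        )
        assert np.array_equal(g2.w_ih, g.w_ih)


class TestSelection:
    def config(self):
        return get_preset("small_scaled")

    def test_flat_fitness_keeps_first_ten_in_order(self):
        pop = [small_genome(s) for s in range(50)]
        out = select_reproduce(pop, np.zeros(50), self.config())
        for i in range(10):
            for c in range(5):
                assert np.array_equal(out[i * 5 + c].w_ih, pop[i].w_ih)

    def test_distinct_fitness_clones_top_ten_five_times(self):
        pop = [small_genome(s) for s in range(50)]
        fits = np.random.default_rng(0).permutation(50) / 50
        out = select_reproduce(pop, fits, self.config())
        assert len(out) == 50
        top = np.argsort(-fits, kind="stable")[:10]
        expected = np.repeat(top, 5)
        for got, idx in zip(out, expected):
            assert np.array_equal(got.w_ih, pop[idx].w_ih)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            select_reproduce([small_genome()], np.zeros(1), self.config())

    def test_selection_indices_stable_ties(self):
        idx = selection_indices(np.array([1.0, 1.0, 0.5, 1.0]), 2, 2)
        assert np.array_equal(idx, [0, 0, 1, 1])


class TestRunScenario:
    def test_zero_generations_returns_initial_population(self):
        cfg = get_preset("small_scaled", generations=0, n_replicates=1, log_every=0)
        (rec,) = run_scenario(cfg)
        assert rec.generation.size == 0
        assert rec.best_genome is None
        assert rec.final_population.size == 50
        assert rec.final_population.M.all()  # untouched full start

    def test_fixed_architecture_mask_never_changes(self):
        cfg = get_preset(
            "small_scaled",
            generations=25,
            n_replicates=1,
            connective_regime=ConnectiveMutationRegime("none", 0.0),
            fixed_architecture="pmn",
            log_every=0,
        )
        (rec,) = run_scenario(cfg)
        from modevo.network_model import make_architecture_mask

        pmn = make_architecture_mask(ArchitectureSpec("pmn", 16, 8))
        assert np.array_equal(rec.best_genome.m_ih, pmn)
        assert (rec.final_population.M == pmn).all()

    def test_best_fitness_at_least_population_mean(self):
        cfg = get_preset("small_scaled", generations=40, n_replicates=1, log_every=0)
        (rec,) = run_scenario(cfg)
        assert (rec.best_fitness >= rec.mean_fitness - 1e-12).all()

    def test_deterministic_given_master_seed(self):
        cfg = get_preset("small_scaled", generations=15, n_replicates=2, log_every=0)
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.best_fitness, rb.best_fitness)
            assert np.array_equal(ra.best_genome.w_ih, rb.best_genome.w_ih)

    def test_replicates_use_distinct_inputs(self):
        cfg = get_preset("small_scaled", generations=1, n_replicates=2, log_every=0)
        a, b = run_scenario(cfg)
        assert not np.array_equal(a.input_set.patterns, b.input_set.patterns)

    def test_neutral_drift_toward_half_connectivity(self):
        # flat fitness + symmetric flips: f(t) = 0.5 + (f0-0.5)(1-2p)^t
        p = 0.01
        cfg = get_preset(
            "small_scaled",
            generations=120,
            n_replicates=1,
            connective_regime=ConnectiveMutationRegime("symmetric", p, "full"),
            flat_fitness=True,
            log_every=0,
        )
        (rec,) = run_scenario(cfg)
        for t in (30, 119):
            f = 0.5 + 0.5 * (1 - 2 * p) ** t
            se = np.sqrt(f * (1 - f) / 128)  # conservative: one lineage of 128 entries
            assert abs(rec.mean_active_fraction[t] - f) < 3 * se

    def test_vectorized_engine_matches_genome_level_evaluation(self):
        inputs = assemble_input_set(2, 100, seed=3)
        genomes = [small_genome(s) for s in range(8)]
        pop = Population.from_genomes(genomes)
        fits_vec = population_fitness(
            forward_population(pop, inputs.patterns), inputs.positive_mask
        )
        fits_ref = evaluate_population(genomes, inputs)
        assert np.allclose(fits_vec, fits_ref)


class TestTemporalSeparation:
    def test_single_round_without_inner_loop_applies_one_connective_pass(self):
        p = 1 / 400
        cfg = get_preset(
            "temporal_separation",
            n_replicates=1,
            rounds=1,
            inner_generations=0,
            generations=0,
            log_every=0,
        )
        (rec,) = run_temporal_separation(cfg)
        assert rec.generation.size == 1
        # starting from the full mask, every inactive entry is one flip
        flips = (~rec.final_population.M).sum()
        expected = 50 * 4608 * p
        se = np.sqrt(expected * (1 - p))
        assert abs(flips - expected) < 3 * se

    def test_zero_flip_probability_reduces_to_weight_only_evolution(self):
        cfg = get_preset(
            "temporal_separation",
            n_replicates=1,
            rounds=3,
            inner_generations=2,
            generations=6,
            connective_regime=ConnectiveMutationRegime("symmetric", 0.0),
            log_every=0,
        )
        (rec,) = run_temporal_separation(cfg)
        assert rec.final_population.M.all()
        assert rec.generation.size == 3

    def test_requires_round_structure(self):
        cfg = get_preset("starting_state_scaled", n_replicates=1)
        with pytest.raises(ValueError, match="rounds"):
            run_temporal_separation(cfg)


class TestPresets:
    def test_all_presets_build(self):
        for name in list_presets():
            cfg = get_preset(name)
            assert isinstance(cfg, ScenarioConfig)
            assert cfg.pop_size == cfg.n_parents * cfg.n_clones

    def test_unknown_preset_lists_alternatives(self):
        with pytest.raises(ValueError, match="starting_state"):
            get_preset("nonsense")

    def test_starting_state_regimes_match_study_conditions(self):
        cfg = get_preset("starting_state")
        assert (cfg.n_inputs, cfg.n_hidden) == (96, 48)
        assert cfg.weight_regime.mode == "every_weight"
        assert cfg.weight_regime.sd == 0.25
        assert cfg.connective_regime.flip_prob == 0.001
        assert (cfg.pop_size, cfg.n_parents, cfg.n_clones) == (50, 10, 5)
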