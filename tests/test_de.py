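"""Binary differential evolution: operators, fitness, full runs."""

import itertools

import numpy as np
import pytest

from beatselect import de
from beatselect.pipeline import SplitSpec, split


@pytest.fixture
def cfg():
    return de.DEConfig(np_=10, max_gen=20, cr=0.8, mr=0.2, seed=3)


class TestInitPopulation:
    def test_last_individual_is_all_features(self, cfg, rng):
        pop = de.init_population(cfg, nf=30, rng=rng)
        assert pop.shape == (10, 30)
        assert np.all(pop[-1] == 1)

    def test_init_p1_one_gives_all_ones(self, rng):
        cfg = de.DEConfig(np_=5, init_p1=1.0)
        assert np.all(de.init_population(cfg, 12, rng) == 1)

    def test_no_all_zero_rows_even_at_tiny_p1(self):
        cfg = de.DEConfig(np_=20, init_p1=0.01)
        pop = de.init_population(cfg, 5, np.random.default_rng(0))
        assert np.all(pop.sum(axis=1) >= 1)

    def test_deterministic_under_seed(self, cfg):
        a = de.init_population(cfg, 40, np.random.default_rng(9))
        b = de.init_population(cfg, 40, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_bit_fraction_tracks_init_p1(self):
        cfg = de.DEConfig(np_=50, init_p1=0.8)
        pop = de.init_population(cfg, 200, np.random.default_rng(1))
        assert pop[:-1].mean() == pytest.approx(0.8, abs=0.02)


class TestCrossover:
    def test_prefix_suffix_construction(self):
        """Force a crossover and check the cut splices prefix and suffix."""
        pop = np.array([[1, 1, 1, 1, 1, 1],
                        [0, 0, 0, 0, 0, 0],
                        [1, 0, 1, 0, 1, 0]], dtype=np.int8)
        cfg = de.DEConfig(np_=3, cr=1.0)
        rng = np.random.default_rng(0)
        trials = de.crossover(pop, cfg, rng)
        for t in trials:
            # every trial must be a prefix of one parent + suffix of another
            ok = False
            for i1, i2 in itertools.permutations(range(3), 2):
                for ri in range(1, 6):
                    if (np.array_equal(t[:ri], pop[i1, :ri])
                            and np.array_equal(t[ri:], pop[i2, ri:])):
                        ok = True
            assert ok

    def test_cr_zero_copies_population(self, rng):
        pop = (rng.random((6, 10)) < 0.5).astype(np.int8)
        out = de.crossover(pop, de.DEConfig(np_=6, cr=0.0), rng)
        assert np.array_equal(out, pop)

    def test_nf_two_boundary(self, rng):
        pop = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        trials = de.crossover(pop, de.DEConfig(np_=3, cr=1.0), rng)
        # cut is always 1: first bit from one parent, second from another
        for t in trials:
            assert t[0] in pop[:, 0] and t[1] in pop[:, 1]

    def test_tiny_population_raises(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            de.crossover(np.ones((2, 4), dtype=np.int8),
                         de.DEConfig(np_=2, cr=1.0), rng)


class TestMutate:
    def test_mr_zero_is_identity(self, rng):
        pop = (rng.random((5, 20)) < 0.5).astype(np.int8)
        pop[:, 0] = 1
        assert np.array_equal(de.mutate(pop, de.DEConfig(mr=0.0), rng), pop)

    def test_mr_one_is_complement(self, rng):
        pop = np.array([[1, 0, 1, 0]], dtype=np.int8)
        out = de.mutate(pop, de.DEConfig(mr=1.0), rng)
        assert np.array_equal(out, [[0, 1, 0, 1]])

    def test_all_zero_repaired(self, rng):
        pop = np.array([[1, 1, 1]], dtype=np.int8)
        out = de.mutate(pop, de.DEConfig(mr=1.0), rng)
        assert out.sum() == 1  # complement is all-zero; one bit flipped back on

    def test_flip_fraction_concentrates_at_mr(self):
        rng = np.random.default_rng(5)
        pop = np.zeros((100, 100), dtype=np.int8)
        pop[:, 0] = 1
        out = de.mutate(pop, de.DEConfig(mr=0.2), rng)
        flipped = np.mean(out[:, 1:] != pop[:, 1:])
        assert flipped == pytest.approx(0.2, abs=0.01)


class TestSelect:
    def test_all_trials_worse_keeps_population(self, rng):
        pop = (rng.random((4, 6)) < 0.5).astype(np.int8)
        trials = 1 - pop
        new, fit = de.select(pop, np.ones(4), trials, np.zeros(4))
        assert np.array_equal(new, pop) and np.all(fit == 1)

    def test_all_trials_better_takes_trials(self, rng):
        pop = (rng.random((4, 6)) < 0.5).astype(np.int8)
        trials = 1 - pop
        new, fit = de.select(pop, np.zeros(4), trials, np.ones(4))
        assert np.array_equal(new, trials)

    def test_ties_keep_parent(self, rng):
        pop = (rng.random((4, 6)) < 0.5).astype(np.int8)
        new, _ = de.select(pop, np.ones(4), 1 - pop, np.ones(4))
        assert np.array_equal(new, pop)


class TestEvaluateFitness:
    def test_memorization_gives_perfect_fit(self, planted_feature_dataset):
        ds = planted_feature_dataset
        mask = np.ones(ds.nf, dtype=np.int8)
        fit = de.evaluate_fitness(mask, ds, ds, sigma=0.01)
        assert fit == 1.0

    def test_shuffled_labels_give_chance_fitness(self):
        from beatselect.synthetic import SyntheticSpec, make_beats

        rng = np.random.default_rng(0)
        ds = make_beats(SyntheticSpec(
            n_beats=800, class_proportions=(0.5, 0.5, 0, 0, 0, 0, 0, 0),
            informative_features=(1, 2), informative_sep=2.5, n_features=8,
            seed=13))
        train, test = split(ds, SplitSpec(seed=1))
        shuffled = train.subset(np.arange(train.n_beats))
        shuffled.labels = rng.permutation(shuffled.labels)
        fit = de.evaluate_fitness(np.ones(ds.nf, dtype=np.int8),
                                  shuffled, test, sigma=1.0)
        assert abs(fit) < 0.1

    def test_identical_masks_identical_fit(self, planted_feature_dataset):
        ds = planted_feature_dataset
        train, test = split(ds, SplitSpec(seed=2))
        mask = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=np.int8)
        a = de.evaluate_fitness(mask, train, test, sigma=1.0)
        b = de.evaluate_fitness(mask.copy(), train, test, sigma=1.0)
        assert a == b

    def test_empty_mask_raises(self, planted_feature_dataset):
        ds = planted_feature_dataset
        with pytest.raises(ValueError, match="empty feature mask"):
            de.evaluate_fitness(np.zeros(ds.nf), ds, ds, 1.0)


class TestRun:
    def test_constant_fitness_stops_at_stagnation_window(self,
                                                         planted_feature_dataset):
        ds = planted_feature_dataset
        cfg = de.DEConfig(np_=6, max_gen=100, stagnation_window=7, seed=0)
        # cache-aware stub: constant fitness regardless of mask
        result = de.run(ds, ds, cfg, fitness_fn=lambda m: 0.5)
        assert result.generations == 7
        assert len(result.history) == 1 + 7  # init + one entry per generation

    def test_max_gen_one_runs_single_cycle(self, planted_feature_dataset):
        ds = planted_feature_dataset
        cfg = de.DEConfig(np_=6, max_gen=1, seed=0)
        result = de.run(ds, ds, cfg, fitness_fn=lambda m: float(m.sum()))
        assert result.generations == 1
        assert len(result.history) == 2

    def test_history_non_decreasing_and_reproducible(self, planted_feature_dataset):
        ds = planted_feature_dataset
        train, test = split(ds, SplitSpec(seed=5))
        cfg = de.DEConfig(np_=8, max_gen=10, stagnation_window=5, seed=42)
        a = de.run(train, test, cfg, sigma=1.0)
        b = de.run(train, test, cfg, sigma=1.0)
        assert np.all(np.diff(a.history) >= 0)
        assert np.array_equal(a.best_mask, b.best_mask)
        assert a.history == b.history
        assert a.best_fit == de.evaluate_fitness(a.best_mask, train, test, 1.0)

    def test_final_best_at_least_all_features_seed(self, planted_feature_dataset):
        ds = planted_feature_dataset
        train, test = split(ds, SplitSpec(seed=5))
        cfg = de.DEConfig(np_=8, max_gen=10, stagnation_window=5, seed=1)
        result = de.run(train, test, cfg, sigma=1.0)
        all_fit = de.evaluate_fitness(np.ones(train.nf), train, test, 1.0)
        assert result.best_fit >= all_fit

    def test_finds_planted_informative_features(self, planted_feature_dataset):
        """Near-exhaustive-optimal on an nf=8 problem with signal in {1, 2}."""
        train, test = split(planted_feature_dataset, SplitSpec(seed=5))
        best_exhaustive, best_mask_ex = -2.0, None
        for bits in itertools.product([0, 1], repeat=8):
            if not any(bits):
                continue
            f = de.evaluate_fitness(np.array(bits), train, test, sigma=1.0)
            if f > best_exhaustive:
                best_exhaustive, best_mask_ex = f, bits
        cfg = de.DEConfig(np_=10, max_gen=30, stagnation_window=10, seed=7)
        result = de.run(train, test, cfg, sigma=1.0)
        assert set(np.nonzero(result.best_mask)[0]) >= {1, 2}
        assert result.best_fit >= best_exhaustive - 0.02

    def test_run_log_written(self, tmp_path, planted_feature_dataset):
        import json

        ds = planted_feature_dataset
        cfg = de.DEConfig(np_=6, max_gen=3, stagnation_window=2, seed=0)
        log = tmp_path / "de.jsonl"
        de.run(ds, ds, cfg, fitness_fn=lambda m: float(m.sum()), log_path=log)
        lines = [json.loads(l) for l in log.read_text().splitlines()]
        assert lines[0]["generation"] == 0
        assert all("best_fit" in l and "best_mask_hex" in l for l in lines)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"cr": 1.5}, {"mr": -0.1}, {"np_": 1}, {"max_gen": 0}, {"init_p1": 2.0},
    ])
    def test_bad_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            de.DEConfig(**kwargs)

    def test_mask_csv_round_trip(self, tmp_path, rng):
        mask = (rng.random(50) < 0.5).astype(np.int8)
        de.save_mask_csv(mask, tmp_path / "mask.csv")
        assert np.array_equal(de.load_mask_csv(tmp_path / "mask.csv"), mask)
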