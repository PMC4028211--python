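import itertools

import numpy as np
import pytest

from gcselect import SwarmConfig, ValidationError
from gcselect import mbpso
from gcselect.gene_pools import GeneClustering

from tests.conftest import make_dataset


def trivial_clustering(n_genes, assignment=None):
    assignment = np.zeros(n_genes, int) if assignment is None else np.asarray(assignment)
    nc = assignment.max() + 1
    return GeneClustering(
        assignment=assignment,
        centers=np.zeros((nc, 1)),
        n_clusters=nc,
        cost=0.0,
        cluster_kept=np.ones(nc, dtype=bool),
        gene_kept=np.ones(n_genes, dtype=bool),
    )


def planted_two_gene_problem(seed=0, n_genes=10):
    """Two informative genes with huge margins, the rest pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], 15)
    X = rng.normal(size=(30, n_genes))
    X[:, 0] += 6.0 * (y == 1)
    X[:, 1] -= 6.0 * (y == 1)
    return X, y


class TestConfig:
    def test_published_defaults(self):
        cfg = SwarmConfig()
        assert cfg.c1 == cfg.c2 == 1.6
        assert (cfg.w_start, cfg.w_end) == (1.2, 0.4)
        assert cfg.a == 0.5
        assert cfg.ns == 50 and cfg.max_iter == 40

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SwarmConfig(ns=1)
        with pytest.raises(ValidationError):
            SwarmConfig(a=1.5)
        with pytest.raises(ValidationError):
            SwarmConfig(w_start=0.2, w_end=0.8)


class TestFitness:
    def test_smaller_subset_wins_at_equal_accuracy(self):
        """The size penalty is strictly decreasing in subset size."""
        cfg = SwarmConfig()
        # identical accuracy term by construction: compare penalty directly
        acc = 0.9
        f3 = cfg.w_acc * acc - cfg.w_size * 3 / 20
        f6 = cfg.w_acc * acc - cfg.w_size * 6 / 20
        assert f3 > f6

    def test_accuracy_dominates_at_fixed_size(self):
        X, y = planted_two_gene_problem()
        cfg = SwarmConfig(n_hidden=8, cv_seed=0)
        good = np.zeros(10, bool)
        good[[0, 1]] = True
        bad = np.zeros(10, bool)
        bad[[5, 6]] = True
        assert mbpso.fitness(good, X, y, cfg) > mbpso.fitness(bad, X, y, cfg)

    def test_empty_selection_rejected(self):
        X, y = planted_two_gene_problem()
        with pytest.raises(ValidationError):
            mbpso.fitness(np.zeros(10, bool), X, y, SwarmConfig())

    def test_exhaustive_best_subset_on_small_pool(self):
        """The highest-fitness subset among all 63 subsets of a 6-gene pool is
        found by direct evaluation and contains the informative genes."""
        X, y = planted_two_gene_problem(seed=1, n_genes=6)
        cfg = SwarmConfig(n_hidden=8, cv_seed=1)
        best_x, best_f = None, -np.inf
        for bits in itertools.product([0, 1], repeat=6):
            x = np.array(bits, bool)
            if not x.any():
                continue
            f = mbpso.fitness(x, X, y, cfg)
            if f > best_f:
                best_x, best_f = x, f
        assert best_x[0] or best_x[1]


class TestInitialization:
    def test_single_gene_cluster_always_selected(self):
        cl = trivial_clustering(1)
        for p in mbpso.initialize_swarm(cl, np.ones(1), SwarmConfig(ns=10)):
            assert p.x[0]

    def test_every_kept_cluster_covered(self):
        for seed in range(10):
            cl = trivial_clustering(12, assignment=np.repeat([0, 1, 2], 4))
            cfg = SwarmConfig(ns=100, seed=seed)
            for p in mbpso.initialize_swarm(cl, np.ones(12), cfg):
                for c in range(3):
                    assert p.x[cl.assignment == c].any()

    def test_same_seed_same_swarm(self):
        cl = trivial_clustering(8)
        a = mbpso.initialize_swarm(cl, np.ones(8), SwarmConfig(ns=5, seed=3))
        b = mbpso.initialize_swarm(cl, np.ones(8), SwarmConfig(ns=5, seed=3))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.x, pb.x)
            np.testing.assert_array_equal(pa.v, pb.v)

    def test_velocities_within_clamp(self):
        cl = trivial_clustering(20)
        cfg = SwarmConfig(ns=20, v_max=4.0)
        for p in mbpso.initialize_swarm(cl, np.ones(20), cfg):
            assert np.all(np.abs(p.v) <= cfg.v_max)


class TestVelocityUpdate:
    def test_fixed_point_at_consensus(self):
        """x = pbest = gbest with zero velocity stays at zero velocity."""
        cfg = SwarmConfig()
        x = np.array([True, False, True])
        p = mbpso.Particle(x=x, v=np.zeros(3), pbest_x=x.copy(), pbest_fit=0.0)
        v = mbpso.velocity_update(p, x.copy(), 0, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(v, 0.0)

    def test_inertia_schedule_endpoints(self):
        cfg = SwarmConfig(w_start=1.2, w_end=0.4, max_iter=40)
        assert mbpso.inertia(0, cfg) == 1.2
        assert mbpso.inertia(40, cfg) == 0.4

    def test_degenerate_constants_leave_velocity_unchanged(self):
        cfg = SwarmConfig(c1=1e-12, c2=1e-12, w_start=1.0, w_end=1.0, v_max=10.0)
        rng = np.random.default_rng(1)
        x = np.array([True, False])
        p = mbpso.Particle(x=x, v=np.array([0.5, -2.0]), pbest_x=~x, pbest_fit=0.0)
        v = mbpso.velocity_update(p, x.copy(), 5, cfg, rng)
        np.testing.assert_allclose(v, [0.5, -2.0], atol=1e-10)

    def test_clamped_to_v_max(self):
        cfg = SwarmConfig(v_max=4.0)
        x = np.zeros(4, bool)
        p = mbpso.Particle(x=x, v=np.full(4, 10.0), pbest_x=np.ones(4, bool), pbest_fit=0.0)
        v = mbpso.velocity_update(p, np.ones(4, bool), 0, cfg, np.random.default_rng(2))
        assert np.all(np.abs(v) <= 4.0)


class TestPositionUpdate:
    def run_updates(self, gcs, n=10_000, v=0.0, seed=0):
        """Empirical bit frequencies under repeated position updates."""
        cfg = SwarmConfig()
        D = gcs.size
        x = np.zeros(D, bool)
        p = mbpso.Particle(x=x, v=np.zeros(D), pbest_x=np.zeros(D, bool), pbest_fit=0.0)
        rng = np.random.default_rng(seed)
        counts = np.zeros(D)
        for _ in range(n):
            counts += mbpso.position_update(p, np.zeros(D, bool), gcs, cfg, rng,
                                            np.full(D, float(v)))
        return counts / n

    def test_sigmoid_at_zero_is_fair_coin_in_resample_branch(self):
        """With v' = 0 and all-zero histories, P(bit=1) = a * S(0) = a/2."""
        freq = self.run_updates(np.ones(50), v=0.0)
        assert abs(freq.mean() - 0.25) < 0.02

    def test_selection_frequency_monotone_in_gcs(self):
        """Two genes, identical dynamics, GCS (2, 0.5): the high-GCS gene is
        selected at least as often."""
        for v in (-1.0, 1.0):
            freq = self.run_updates(np.array([2.0, 0.5]), v=v)
            assert freq[0] >= freq[1]

    def test_uniform_gcs_reduces_to_unmodulated_rule(self):
        """All-equal GCS: empirical bit distribution matches the plain a-rule
        within 2% at 10k draws."""
        from scipy.special import expit

        cfg = SwarmConfig()
        v = 1.3
        D = 50  # many genes so the empty-selection repair is negligible
        freq = self.run_updates(np.ones(D), v=v)
        expected = cfg.a * expit(v)  # copy branch draws from all-zero histories
        assert abs(freq.mean() - expected) < 0.02


class TestRun:
    def test_single_gene_pool(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 15)
        X = (rng.normal(size=30) + 6.0 * (y == 1)).reshape(-1, 1)
        cl = trivial_clustering(1)
        cfg = SwarmConfig(ns=5, max_iter=3, n_hidden=5)
        res = mbpso.run(X, y, cl, np.ones(1), cfg)
        assert res.selected.tolist() == [0]
        assert len(set(res.trace)) == 1

    def test_gbest_trace_non_decreasing(self):
        X, y = planted_two_gene_problem(seed=2)
        cl = trivial_clustering(10)
        cfg = SwarmConfig(ns=10, max_iter=10, n_hidden=8, seed=2)
        res = mbpso.run(X, y, cl, np.ones(10), cfg)
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert res.selected.size >= 1

    def test_deterministic_given_seed(self):
        X, y = planted_two_gene_problem(seed=3)
        cl = trivial_clustering(10)
        cfg = SwarmConfig(ns=8, max_iter=5, n_hidden=8, seed=7)
        a = mbpso.run(X, y, cl, np.ones(10), cfg)
        b = mbpso.run(X, y, cl, np.ones(10), cfg)
        np.testing.assert_array_equal(a.gbest_x, b.gbest_x)
        assert a.trace == b.trace

    def test_finds_exhaustive_optimum_on_small_pool(self):
        """10-gene pool: the swarm reaches the best of all 1023 subsets."""
        X, y = planted_two_gene_problem(seed=4)
        cl = trivial_clustering(10)
        cfg = SwarmConfig(ns=30, max_iter=40, n_hidden=10, cv_seed=4, seed=4)
        res = mbpso.run(X, y, cl, np.ones(10), cfg)
        best = max(
            mbpso.fitness(np.array(bits, bool), X, y, cfg)
            for bits in itertools.product([0, 1], repeat=10)
            if any(bits)
        )
        assert res.gbest_fit == pytest.approx(best, abs=1e-12)

    def test_early_stop_on_fitness_threshold(self):
        X, y = planted_two_gene_problem(seed=5)
        cl = trivial_clustering(10)
        cfg = SwarmConfig(ns=10, max_iter=40, n_hidden=8, fitness_threshold=-10.0, seed=5)
        res = mbpso.run(X, y, cl, np.ones(10), cfg)
        assert len(res.trace) == 2  # stops after the first iteration
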