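"""Modularity Q, simulated annealing vs exhaustive oracle, node roles."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from megnet import (
    AnnealingConfig,
    Partition,
    PlantedGraphSpec,
    anneal_partition,
    brute_force_partition,
    generate_planted_graph,
    modularity_q,
    node_roles,
    per_epoch_metrics,
)
from megnet.connectivity import ConnectivityMatrix
from conftest import random_symmetric


def modularity_direct(w: np.ndarray, labels: np.ndarray) -> float:
    """Independent re-implementation of Q as an explicit double loop."""
    n = w.shape[0]
    strengths = w.sum(axis=1)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += w[i, j]
    q = 0.0
    for s in set(labels.tolist()):
        l_s = 0.0
        d_s = 0.0
        for i in range(n):
            if labels[i] != s:
                continue
            d_s += strengths[i]
            for j in range(i + 1, n):
                if labels[j] == s:
                    l_s += w[i, j]
        q += l_s / total - (d_s / (2 * total)) ** 2
    return q


class TestModularityQ:
    def test_single_module_is_zero(self):
        w = random_symmetric(6, 0)
        assert modularity_q(w, np.zeros(6, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_equal_isolated_modules(self, m):
        """m equal modules with no inter-module weight give Q = 1 - 1/m."""
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(3,) * m, w_in=1.0, w_out=0.0)
        )
        assert planted.q == pytest.approx(1 - 1 / m, abs=1e-12)

    def test_agrees_with_direct_double_loop(self):
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(3, 3), w_in=1.0, w_out=0.1)
        )
        expected = modularity_direct(matrix.weights, planted.labels)
        assert planted.q == pytest.approx(expected, abs=1e-12)
        # also on random graphs with random labelings
        for seed in range(5):
            w = random_symmetric(8, seed)
            labels = np.random.default_rng(seed).integers(0, 3, 8)
            assert modularity_q(w, labels) == pytest.approx(
                modularity_direct(w, labels), abs=1e-12
            )

    def test_label_permutation_and_node_reorder_invariance(self):
        w = random_symmetric(9, 3)
        labels = np.random.default_rng(3).integers(0, 3, 9)
        q = modularity_q(w, labels)
        assert modularity_q(w, labels + 10) == pytest.approx(q, abs=1e-12)
        perm = np.random.default_rng(4).permutation(9)
        assert modularity_q(w[np.ix_(perm, perm)], labels[perm]) == pytest.approx(q, abs=1e-12)

    def test_bounds_on_random_labelings(self):
        for seed in range(10):
            w = random_symmetric(7, seed)
            labels = np.random.default_rng(seed).integers(0, 4, 7)
            assert -1.0 < modularity_q(w, labels) < 1.0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            modularity_q(np.zeros((4, 4)), np.zeros(4, dtype=int))


class TestAnnealing:
    def test_planted_partition_recovery(self):
        """sizes=[5,5], w_in=1, w_out=0.05: annealing recovers the planted split."""
        hits = 0
        for seed in range(5):
            matrix, planted = generate_planted_graph(
                PlantedGraphSpec(module_sizes=(5, 5), w_in=1.0, w_out=0.05, seed=seed)
            )
            part = anneal_partition(matrix, AnnealingConfig(total_steps=100_000, seed=seed))
            hits += adjusted_rand_score(planted.labels, part.labels) == 1.0
        assert hits >= 4

    def test_matches_exhaustive_oracle_on_small_graphs(self):
        for seed in range(5):
            w = random_symmetric(7, 100 + seed)
            exact = brute_force_partition(w)
            annealed = anneal_partition(w, AnnealingConfig(total_steps=100_000, seed=seed))
            assert annealed.q == pytest.approx(exact.q, abs=1e-9)

    def test_deterministic_given_seed(self):
        w = random_symmetric(10, 5)
        cfg = AnnealingConfig(total_steps=20_000, seed=99)
        p1 = anneal_partition(w, cfg)
        p2 = anneal_partition(w, cfg)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    def test_random_graph_less_modular_than_planted(self):
        """Uniform-weight (random) networks anneal to lower Q than a planted
        modular network of the same size with no inter-module weight."""
        rng = np.random.default_rng(8)
        w = np.triu(rng.uniform(0.3, 0.7, (30, 30)), 1)
        w = w + w.T
        q_random = anneal_partition(w, AnnealingConfig(total_steps=50_000, seed=0)).q
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(10, 10, 10), w_in=0.5, w_out=0.0)
        )
        assert q_random < planted.q

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealingConfig(cooling_factor=1.5)
        with pytest.raises(ValueError):
            AnnealingConfig(total_steps=10, cooling_interval=100)


class TestBruteForce:
    def test_two_nodes_stay_together(self):
        """Splitting a single positive dyad yields Q = -0.5, so the optimum
        is the single module with Q = 0."""
        w = np.array([[0.0, 0.8], [0.8, 0.0]])
        part = brute_force_partition(w)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)
        split_q = modularity_q(w, np.array([0, 1]))
        assert split_q == pytest.approx(-0.5, abs=1e-12)

    def test_two_cliques_forced_split(self):
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(3, 3), w_in=1.0, w_out=0.0)
        )
        part = brute_force_partition(matrix)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert adjusted_rand_score(planted.labels, part.labels) == 1.0

    def test_beats_random_labelings(self):
        w = random_symmetric(6, 17)
        best = brute_force_partition(w).q
        rng = np.random.default_rng(17)
        for _ in range(100):
            labels = rng.integers(0, 6, 6)
            assert best >= modularity_q(w, labels) - 1e-12

    def test_size_guard(self):
        with pytest.raises(ValueError, match="N <= 10"):
            brute_force_partition(np.zeros((11, 11)))


class TestNodeRoles:
    def test_fully_internal_node_has_zero_pc(self):
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(4, 4), w_in=1.0, w_out=0.0)
        )
        roles = node_roles(matrix, planted)
        np.testing.assert_allclose(roles.pc, 0.0, atol=1e-12)

    def test_equal_four_way_spread(self):
        """A hub with equal strength into 4 modules has pc = 1 - 4 (1/4)^2."""
        n = 9  # hub + 4 modules of 2
        w = np.zeros((n, n))
        labels = np.array([0, 1, 1, 2, 2, 3, 3, 4, 4])
        w[0, 1] = w[0, 3] = w[0, 5] = w[0, 7] = 1.0
        for pair in ((1, 2), (3, 4), (5, 6), (7, 8)):
            w[pair] = 1.0
        w = w + w.T
        roles = node_roles(ConnectivityMatrix(np.clip(w, 0, 1)), Partition(labels, 0.0, 0))
        assert roles.pc[0] == pytest.approx(0.75, abs=1e-12)

    def test_within_strength_z_scores(self):
        """Within-strengths {1,2,3} standardise to +-sqrt(3/2) and 0 with the
        population SD convention."""
        w = np.zeros((4, 4))
        labels = np.array([0, 0, 0, 1])
        # within-module strengths 1, 2, 3 for the first three nodes
        w[0, 2] = 1.0
        w[1, 2] = 2.0
        w = w + w.T
        roles = node_roles(w, Partition(labels, 0.0, 0))
        expected = np.array([-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        np.testing.assert_allclose(roles.z[:3], expected, atol=1e-9)

    def test_z_standardisation_per_module(self, rng):
        w = random_symmetric(12, 21)
        labels = np.repeat([0, 1, 2], 4)
        roles = node_roles(ConnectivityMatrix(w), Partition(labels, 0.0, 0))
        for lab in (0, 1, 2):
            zs = roles.z[labels == lab]
            assert zs.mean() == pytest.approx(0.0, abs=1e-9)
            assert zs.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert abs(roles.z.mean()) < 1e-9

    def test_pc_upper_bound(self):
        w = random_symmetric(10, 33)
        labels = np.random.default_rng(33).integers(0, 3, 10)
        part = Partition(labels, 0.0, 0)
        roles = node_roles(ConnectivityMatrix(np.clip(w, 0, 1)), part)
        m = part.n_modules
        assert np.all(roles.pc <= 1 - 1 / m + 1e-12)
        assert np.all(roles.pc >= 0)

    def test_degenerate_cases(self):
        # singleton module and isolated node
        w = np.zeros((3, 3))
        w[0, 1] = 1.0
        w = w + w.T
        roles = node_roles(ConnectivityMatrix(w), Partition(np.array([0, 0, 1]), 0.0, 0))
        assert roles.z[2] == 0.0  # singleton module
        assert roles.pc[2] == 0.0  # isolated node (k=0)

    def test_sample_sd_option_scales_z(self):
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(4, 4), w_in=1.0, w_out=0.2, weight_noise_sd=0.05, seed=2)
        )
        pop = node_roles(matrix, planted, sd_mode="population")
        samp = node_roles(matrix, planted, sd_mode="sample")
        # sample SD is larger by sqrt(n/(n-1)), so z shrinks by that factor
        factor = np.sqrt(4 / 3)
        np.testing.assert_allclose(samp.z, pop.z / factor, atol=1e-9)

    def test_between_conn_mean_vs_sum(self):
        matrix, planted = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(3, 5), w_in=1.0, w_out=0.4)
        )
        mean_mode = node_roles(matrix, planted, between_mode="mean")
        sum_mode = node_roles(matrix, planted, between_mode="sum")
        # node 0 lives in the size-3 module: 5 outside nodes
        assert sum_mode.between_conn[0] == pytest.approx(5 * 0.4, abs=1e-12)
        assert mean_mode.between_conn[0] == pytest.approx(0.4, abs=1e-12)


class TestPerEpochMetrics:
    def _planted(self, seed):
        matrix, _ = generate_planted_graph(
            PlantedGraphSpec(module_sizes=(4, 4), w_in=0.8, w_out=0.1, seed=seed)
        )
        return matrix

    def test_single_epoch_passthrough(self):
        m = self._planted(0)
        cfg = AnnealingConfig(total_steps=20_000, seed=5)
        single = per_epoch_metrics([m], cfg)
        assert single["q"] == single["per_epoch_q"][0]

    def test_identical_epochs_average_to_single_value(self):
        m = self._planted(1)
        cfg = AnnealingConfig(total_steps=20_000, seed=6)
        five = per_epoch_metrics([m] * 5, cfg)
        # every epoch recovers the same (optimal) split of this easy graph
        assert np.ptp(five["per_epoch_q"]) == pytest.approx(0.0, abs=1e-12)
        assert five["q"] == pytest.approx(five["per_epoch_q"][0], abs=1e-12)

    def test_stronger_intermodule_coupling_lowers_q(self):
        """Groups differing in inter-module weight separate in mean Q."""
        q_low, q_high = [], []
        for seed in range(10):
            weak, _ = generate_planted_graph(
                PlantedGraphSpec((5, 5), w_in=0.8, w_out=0.1, weight_noise_sd=0.05, seed=seed)
            )
            strong, _ = generate_planted_graph(
                PlantedGraphSpec((5, 5), w_in=0.8, w_out=0.5, weight_noise_sd=0.05, seed=100 + seed)
            )
            cfg = AnnealingConfig(total_steps=20_000, seed=seed)
            q_low.append(per_epoch_metrics([strong], cfg)["q"])
            q_high.append(per_epoch_metrics([weak], cfg)["q"])
        assert np.mean(q_low) < np.mean(q_high)
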