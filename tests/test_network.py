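"""Delayed-network model, connectivity disruptions, synthetic connectome."""

import numpy as np
import pytest
from dataclasses import replace

from phasecrit.critical_models import KuramotoSpec, kuramoto_simulate, order_parameter
from phasecrit.errors import ParameterError, RandomizationError
from phasecrit.network import (
    NetworkSpec,
    cluster_summary,
    delays_from_distances,
    disconnect_hemispheres,
    network_simulate,
    randomize_connectivity,
    row_normalize,
    synthetic_connectome,
)


@pytest.fixture(scope="module")
def connectome():
    return synthetic_connectome(seed=42)


class TestDelays:
    def test_equal_distances_give_equal_delays(self):
        L = np.ones((5, 5)) - np.eye(5)
        D = delays_from_distances(L, 11.0)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(D.values[off], 11.0)

    def test_scale_free_in_distances(self, connectome):
        d1 = delays_from_distances(connectome.L, 11.0)
        d2 = delays_from_distances(2.0 * connectome.L, 11.0)
        assert np.allclose(d1.values, d2.values)

    def test_zero_mean_delay_disables_delays(self, connectome):
        D = delays_from_distances(connectome.L, 0.0)
        assert np.all(D.step_counts == 0)

    def test_mean_over_connected_pairs_is_mean_delay(self, connectome):
        D = delays_from_distances(connectome.L, 11.0, connectivity=connectome.C)
        mask = (connectome.L > 0) & (connectome.C > 0)
        assert D.values[mask].mean() == pytest.approx(11.0)
        assert np.abs(D.step_counts[mask].mean() - 11.0) < 0.5

    def test_all_zero_distances_rejected(self):
        with pytest.raises(ParameterError):
            delays_from_distances(np.zeros((4, 4)), 11.0)


class TestDisconnect:
    def test_block_diagonal_unchanged(self):
        C = np.kron(np.eye(2), np.ones((3, 3))) - np.eye(6)
        C = row_normalize(C)
        hemi = np.array(["L"] * 3 + ["R"] * 3)
        assert np.array_equal(disconnect_hemispheres(C, hemi), C)

    def test_all_cross_becomes_zero(self):
        C = row_normalize(np.kron(np.array([[0, 1], [1, 0]]), np.ones((3, 3))))
        hemi = np.array(["L"] * 3 + ["R"] * 3)
        assert np.all(disconnect_hemispheres(C, hemi) == 0)

    def test_within_weights_untouched_and_counts_match(self, connectome):
        out = disconnect_hemispheres(connectome.C, connectome.hemisphere)
        same = connectome.hemisphere[:, None] == connectome.hemisphere[None, :]
        assert np.array_equal(out[same], connectome.C[same])
        assert np.all(out[~same] == 0)
        assert np.count_nonzero(out) == np.count_nonzero(connectome.C[same])


class TestRandomize:
    def test_outgoing_weight_multisets_exact(self, connectome):
        for seed in range(3):
            out = randomize_connectivity(connectome.C, seed=seed)
            for i in range(out.shape[0]):
                assert np.allclose(
                    np.sort(out[i][out[i] > 0]),
                    np.sort(connectome.C[i][connectome.C[i] > 0]),
                )
            assert np.array_equal(
                (out > 0).sum(axis=1), (connectome.C > 0).sum(axis=1)
            )
            assert np.all(np.diag(out) == 0)

    def test_impossible_graph_fails_loudly(self):
        # a single hub with 5 out-edges cannot be rewired without self loops
        C = np.zeros((6, 6))
        C[0, 1:] = 0.2
        with pytest.raises(RandomizationError):
            randomize_connectivity(C, seed=0, max_restarts=3)

    def test_planted_block_structure_destroyed(self, connectome):
        """Within-cluster-4 weight share falls to the density-expected
        share after randomization."""
        mask = connectome.clusters == "cluster4"
        block = np.ix_(mask, mask)
        orig_share = connectome.C[block].sum() / connectome.C.sum()
        shares = [
            randomize_connectivity(connectome.C, seed=s)[block].sum()
            / connectome.C.sum()
            for s in range(20)
        ]
        density_share = mask.sum() ** 2 / connectome.C.shape[0] ** 2
        assert orig_share > 3 * density_share  # the structure was planted
        assert np.mean(shares) < orig_share / 2
        assert abs(np.mean(shares) - density_share) < 0.10


class TestClusterSummary:
    def test_uniform_single_cluster(self):
        C = row_normalize(np.ones((4, 4)) - np.eye(4))
        table = cluster_summary(C, ["all"] * 4).set_index("cluster")
        assert table.loc["all", "mean_weight_per_node"] == pytest.approx(1.0)
        assert table.loc["all", "mean_degree"] == pytest.approx(3.0)

    def test_isolated_cluster_zero(self):
        C = np.zeros((4, 4))
        C[0, 1] = C[1, 0] = 1.0
        labels = ["a", "a", "iso", "iso"]
        table = cluster_summary(row_normalize(C), labels).set_index("cluster")
        assert table.loc["iso", "mean_weight_per_node"] == 0.0
        assert table.loc["iso", "mean_degree"] == 0.0

    def test_label_coverage_enforced(self, connectome):
        with pytest.raises(ParameterError):
            cluster_summary(connectome.C, ["x"] * 10)


class TestSyntheticConnectome:
    def test_shapes_and_normalization(self, connectome):
        assert connectome.n_nodes == 66
        assert np.allclose(connectome.C.sum(axis=1), 1.0)
        assert np.allclose(connectome.L, connectome.L.T)
        assert np.all(np.diag(connectome.C) == 0)
        assert (connectome.hemisphere == "L").sum() == 33

    def test_cluster_sizes_match_layout(self, connectome):
        import collections

        counts = collections.Counter(connectome.clusters)
        assert counts["individual"] == 12
        assert sorted(
            v for k, v in counts.items() if k != "individual"
        ) == sorted((11, 5, 8, 14, 5, 11))

    def test_central_cluster_has_largest_raw_weight(self):
        for seed in (0, 1, 2):
            spec = synthetic_connectome(seed)
            table = cluster_summary(spec.raw_weights, spec.clusters)
            table = table.set_index("cluster")["mean_weight_per_node"]
            assert table.idxmax() == "cluster4"

    def test_disconnection_removes_homologous_links(self, connectome):
        out = disconnect_hemispheres(connectome.C, connectome.hemisphere)
        for i in range(26, 40):  # cluster 4, left members
            assert out[i, 65 - i] == 0.0

    def test_deterministic_per_seed(self):
        a = synthetic_connectome(7)
        b = synthetic_connectome(7)
        assert np.array_equal(a.C, b.C) and np.array_equal(a.L, b.L)


class TestNetworkSimulate:
    def test_zero_connectivity_is_free_noisy_rotators(self, connectome):
        zero_C = np.zeros_like(connectome.C)
        spec = replace(connectome, C=zero_C, coupling=50.0, n_steps=2000)
        phases = network_simulate(spec)
        rng = np.random.default_rng(spec.seed)
        omega = rng.normal(2 * np.pi * 60, 5, 66)
        drift = (phases[:, -1] - phases[:, 0]) / (1999 * spec.dt)
        # noise random walk over 2 s leaves ~1 rad/s of drift scatter
        assert np.allclose(drift, omega, atol=3.0)

    def test_two_node_full_sync(self):
        C = row_normalize(np.array([[0.0, 1.0], [1.0, 0.0]]))
        L = np.zeros((2, 2))
        spec = NetworkSpec(
            C=C, L=L, hemisphere=["L", "R"], clusters=["a", "a"],
            coupling=50.0, mean_delay=0.0, freq_sd=0.0, noise_sd=0.0,
            n_steps=4000, seed=1,
        )
        phases = network_simulate(spec)
        d = np.angle(np.exp(1j * (phases[0] - phases[1])))
        assert abs(d[-1]) < 1e-3

    def test_matches_global_kuramoto_without_delays(self):
        """With zero delays and uniform full connectivity the network
        reduces to the classical mean-field model (matched statistics)."""
        n = 60
        C = row_normalize(np.ones((n, n)) - np.eye(n))
        L = np.zeros((n, n))
        r_net, r_glob = [], []
        k_classical = 30.0  # above Kc for sigma = 15: discriminative r
        for s in range(5):
            spec = NetworkSpec(
                C=C, L=L, hemisphere=["L"] * 30 + ["R"] * 30,
                clusters=["a"] * n,
                # network drift is K * (1/(n-1)) * sum_j sin; the classical
                # (K/n) * sum_j sin form corresponds to K_net = K*(n-1)/n
                coupling=k_classical * (n - 1) / n, mean_delay=0.0,
                mean_freq_hz=22.0, freq_sd=15.0, noise_sd=0.32,
                n_steps=4000, seed=100 + s,
            )
            _, rm = order_parameter(network_simulate(spec)[:, 400:])
            r_net.append(rm)
            kspec = KuramotoSpec(
                coupling=k_classical, n_osc=n, mean_freq_hz=22.0,
                freq_sd=15.0, noise_sd=0.32, n_steps=4000, seed=200 + s,
            )
            _, rm2 = order_parameter(kuramoto_simulate(kspec)[:, 400:])
            r_glob.append(rm2)
        m1, s1 = np.mean(r_net), np.std(r_net)
        m2, s2 = np.mean(r_glob), np.std(r_glob)
        assert abs(m1 - m2) < 2 * np.hypot(s1, s2) + 0.05

    def test_excessive_delay_rejected(self, connectome):
        spec = replace(connectome, mean_delay=1e6, n_steps=2000)
        with pytest.raises(ParameterError):
            network_simulate(spec)
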