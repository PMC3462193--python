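"""The coupling energy H, its randomization statistics, and network stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import territory_coupling as tc
from conftest import random_metric_matrix


def _phi(values, chroms=None, counts=None):
    values = np.asarray(values, dtype=float)
    chroms = chroms or tuple(f"chr{i + 1}" for i in range(values.shape[0]))
    nets = tuple(f"net{j + 1}" for j in range(values.shape[1]))
    if counts is None:
        counts = (values != 0).astype(int)
    return tc.NetworkMatrix(
        chromosomes=tuple(chroms), networks=nets, phi=values, counts=counts
    )


def _adj(values, chroms=None):
    chroms = chroms or tuple(f"chr{i + 1}" for i in range(values.shape[0]))
    return tc.DistanceMatrix(
        labels=tuple(chroms), values=np.asarray(values, float), role="adjacency"
    )


class TestAdjacency:
    def test_zero_distance_gives_one(self):
        ipd = random_metric_matrix(4, np.random.default_rng(0))
        adj = tc.build_adjacency(ipd, 0.07)
        assert np.all(np.diag(adj.values) == 1.0)

    def test_distance_lambda_gives_inverse_e(self):
        vals = 0.07 * (1 - np.eye(2))
        ipd = tc.DistanceMatrix(labels=("chr1", "chr2"), values=vals)
        adj = tc.build_adjacency(ipd, 0.07)
        assert adj.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_monotone_decreasing_in_distance(self):
        ipd = random_metric_matrix(10, np.random.default_rng(1))
        adj = tc.build_adjacency(ipd, 0.1)
        iu = np.triu_indices(10, 1)
        d, a = ipd.values[iu], adj.values[iu]
        order = np.argsort(d)
        assert np.all(np.diff(a[order]) <= 1e-15)

    def test_rejects_bad_lambda(self):
        ipd = random_metric_matrix(3, np.random.default_rng(2))
        with pytest.raises(ValueError):
            tc.build_adjacency(ipd, 0.0)


class TestNetworkMatrix:
    def test_single_gene_log_activity(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chromosome": ["chr1"], "activity": [np.e**2]}
        )
        catalog = tc.NetworkCatalog(networks={"f": ("g1",)})
        phi = tc.build_network_matrix(genes, catalog, chromosomes=("chr1", "chr2"))
        assert phi.phi[0, 0] == pytest.approx(2.0)
        assert phi.phi[1, 0] == 0.0

    def test_integrates_then_logs(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chromosome": ["chr1", "chr1"],
                "activity": [np.e, np.e],
            }
        )
        catalog = tc.NetworkCatalog(networks={"f": ("g1", "g2")})
        phi = tc.build_network_matrix(genes, catalog)
        assert phi.phi[0, 0] == pytest.approx(1 + np.log(2))

    def test_matches_group_and_sum_oracle(self, coupled_dataset):
        genes = coupled_dataset["genes_raw"]
        catalog = coupled_dataset["catalog"]
        phi = coupled_dataset["phi"]
        by_gene = genes.set_index("gene_id")
        for j, name in enumerate(phi.networks):
            members = [g for g in catalog.networks[name] if g in by_gene.index]
            sub = by_gene.loc[members]
            for i, chrom in enumerate(phi.chromosomes):
                sel = sub[sub["chromosome"] == chrom]["activity"]
                expected = np.log(sel.sum()) if len(sel) else 0.0
                assert phi.phi[i, j] == pytest.approx(expected, abs=1e-12)


class TestComputeH:
    def test_constant_columns_zero(self):
        adj = _adj(np.full((3, 3), 0.5) + 0.5 * np.eye(3))
        phi = _phi(np.full((3, 2), 4.0), counts=np.ones((3, 2), int))
        assert tc.compute_H(adj, phi) == 0.0

    def test_forced_two_chromosome_value(self):
        adj = _adj(np.array([[1.0, 0.5], [0.5, 1.0]]))
        phi = _phi(np.array([[1.0], [3.0]]))
        assert tc.compute_H(adj, phi) == pytest.approx(0.5 * 4.0)

    def test_equals_triple_loop_and_permutation_invariance(self):
        """Vectorized H equals the brute-force triple loop; H is invariant
        under simultaneous permutation but changes when only the
        adjacency is permuted."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            A = rng.uniform(0.01, 1.0, size=(8, 8))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            phi_vals = rng.normal(size=(8, 5))
            adj = _adj(A)
            phi = _phi(phi_vals, counts=np.ones((8, 5), int))
            h = tc.compute_H(adj, phi)
            brute = sum(
                A[i, j] * (phi_vals[i, f] - phi_vals[j, f]) ** 2
                for f in range(5)
                for i in range(8)
                for j in range(i + 1, 8)
            )
            assert h == pytest.approx(brute, abs=1e-12 * max(1.0, brute))

        A = rng.uniform(0.01, 1.0, size=(8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        phi_vals = rng.normal(size=(8, 5))
        adj = _adj(A)
        phi = _phi(phi_vals, counts=np.ones((8, 5), int))
        h0 = tc.compute_H(adj, phi)
        changed = 0
        for _ in range(200):
            perm = rng.permutation(8)
            both = tc.compute_H(
                _adj(A[np.ix_(perm, perm)]), _phi(phi_vals[perm], counts=np.ones((8, 5), int))
            )
            assert both == pytest.approx(h0, rel=1e-12)
            only_adj = tc.compute_H(_adj(A[np.ix_(perm, perm)]), phi)
            if abs(only_adj - h0) > 1e-9:
                changed += 1
        assert changed > 190  # generic permutations move H

    def test_additive_column_shift_invariance(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0.1, 1.0, size=(6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        phi_vals = rng.normal(size=(6, 3))
        shifted = phi_vals + np.array([10.0, -3.0, 0.5])
        ones = np.ones((6, 3), int)
        h1 = tc.compute_H(_adj(A), _phi(phi_vals, counts=ones))
        h2 = tc.compute_H(_adj(A), _phi(shifted, counts=ones))
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_monotone_in_adjacency(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0.1, 0.9, size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        phi_vals = rng.normal(size=(5, 2))
        ones = np.ones((5, 2), int)
        h0 = tc.compute_H(_adj(A), _phi(phi_vals, counts=ones))
        A2 = A.copy()
        A2[0, 1] = A2[1, 0] = A[0, 1] + 0.05
        h1 = tc.compute_H(_adj(A2), _phi(phi_vals, counts=ones))
        assert h1 > h0


class TestRandomizeH:
    def test_degenerate_sigma(self):
        adj = _adj(np.full((3, 3), 0.5) + 0.5 * np.eye(3))
        phi = _phi(np.full((3, 2), 4.0), counts=np.ones((3, 2), int))
        summary = tc.randomize_H(adj, phi, tc.EnergyConfig(n_iterations=50, seed=0))
        assert summary.sigma == 0.0
        assert summary.degenerate

    def test_coupled_data_is_near_optimal(self):
        """beta=1 data: randomization raises H (delta_H > 0, small
        empirical p); beta=0 data: delta_H centered near 0."""
        deltas = {0.0: [], 1.0: []}
        small_p = 0
        n_seeds = 20
        for s in range(n_seeds):
            for beta in (0.0, 1.0):
                cfg = tc.SimulationConfig(coupling_beta=beta, seed=s)
                nuclei, truth = tc.generate_nuclei(cfg)
                expr, _ = tc.generate_expression(cfg, truth["log_activity"].to_numpy())
                genes = tc.aggregate_probes(tc.normalize_to_array_mean(expr))
                order = list(truth["log_activity"].sort_values().index)
                catalog = tc.generate_networks(
                    cfg, genes[["gene_id", "chromosome", "activity"]], chromosome_order=order
                )
                phi = tc.build_network_matrix(
                    genes, catalog, chromosomes=cfg.chromosome_labels()
                )
                ipd = tc.compute_ipd(nuclei)
                adj = tc.build_adjacency(ipd, 0.07)
                summary = tc.randomize_H(
                    adj, phi, tc.EnergyConfig(n_iterations=1000, seed=s + 100)
                )
                deltas[beta].append(summary.delta_h)
                if beta == 1.0 and summary.p_empirical < 0.1:
                    small_p += 1
        assert small_p >= 0.9 * n_seeds
        mean0 = np.mean(deltas[0.0])
        se0 = np.std(deltas[0.0], ddof=1) / np.sqrt(n_seeds)
        assert abs(mean0) <= 3 * se0 + 0.5
        assert np.mean(deltas[1.0]) > 1.0

    def test_trajectory_rises_early(self, coupled_dataset):
        """Most of the H increase happens in the first couple hundred swaps."""
        adj = tc.build_adjacency(coupled_dataset["ipd"], 0.07)
        summary = tc.randomize_H(
            adj, coupled_dataset["phi"], tc.EnergyConfig(n_iterations=10_000, seed=1)
        )
        early = summary.trajectory[:200].mean()
        late = summary.trajectory[1000:].mean()
        assert early < late

    def test_independent_mode_agrees_with_cumulative(self, coupled_dataset):
        adj = tc.build_adjacency(coupled_dataset["ipd"], 0.07)
        phi = coupled_dataset["phi"]
        cum = tc.randomize_H(adj, phi, tc.EnergyConfig(n_iterations=3000, seed=2))
        ind = tc.randomize_H(
            adj, phi, tc.EnergyConfig(n_iterations=600, mode="independent", seed=3)
        )
        # both modes estimate the same randomized ensemble
        assert ind.h_av == pytest.approx(cum.h_av, rel=0.1)
        assert np.sign(ind.delta_h) == np.sign(cum.delta_h)

    def test_exclude_homologues_matches_diagonal_zeroing(self, coupled_dataset):
        """The diagonal never contributes to H, so the variant only
        changes bookkeeping, not the statistics."""
        adj = tc.build_adjacency(coupled_dataset["ipd"], 0.07)
        phi = coupled_dataset["phi"]
        a = tc.randomize_H(adj, phi, tc.EnergyConfig(n_iterations=500, seed=4))
        b = tc.randomize_H(
            adj, phi, tc.EnergyConfig(n_iterations=500, seed=4, exclude_homologues=True)
        )
        assert a.h0 == pytest.approx(b.h0)
        np.testing.assert_allclose(a.trajectory, b.trajectory)


class TestDeviationToP:
    def test_zero_gives_one(self):
        assert tc.deviation_to_p(0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "delta,expected",
        [(1.97, 0.05), (1.02, 0.31), (0.71, 0.48), (0.92, 0.36)],
    )
    def test_printed_two_decimal_pairs(self, delta, expected):
        assert round(tc.deviation_to_p(delta), 2) == pytest.approx(expected)

    def test_matches_series_evaluation(self):
        """Closed form vs an independent erfc series at high precision."""
        import math

        for delta in (0.1, 0.5, 1.0, 1.97, 3.0):
            # p = erfc(delta / sqrt(2)); evaluate erfc via its Taylor
            # series for erf around 0 (converges for these arguments)
            x = delta / math.sqrt(2)
            term, total, k = x, x, 0
            while abs(term) > 1e-20:
                k += 1
                term *= -x * x / k
                total += term / (2 * k + 1)
            erf = 2 / math.sqrt(math.pi) * total
            assert tc.deviation_to_p(delta) == pytest.approx(1 - erf, abs=1e-12)


class TestScanLambda:
    def test_single_value_grid(self, coupled_dataset):
        phi = coupled_dataset["phi"]
        res = tc.scan_lambda(
            coupled_dataset["ipd"], phi, [0.07],
            tc.EnergyConfig(n_iterations=200, seed=5),
        )
        assert res["argmax_lambda"] == 0.07

    def test_default_grid_finite(self, coupled_dataset):
        res = tc.scan_lambda(
            coupled_dataset["ipd"],
            coupled_dataset["phi"],
            np.round(np.arange(0.02, 0.801, 0.05), 4),
            tc.EnergyConfig(n_iterations=300, seed=6),
        )
        assert np.all(np.isfinite(res["delta_h"]))


class TestNetworkStatistics:
    def test_occupancy_fractions(self):
        counts = np.array([[1, 0], [2, 0], [0, 1], [0, 0]])
        phi_vals = np.where(counts > 0, 1.0, 0.0)
        phi = _phi(phi_vals, counts=counts)
        occ = tc.occupancy(phi)
        assert occ["net1"] == pytest.approx(0.5)
        assert occ["net2"] == pytest.approx(0.25)

    def test_occupancy_matches_brute_force(self, coupled_dataset):
        phi = coupled_dataset["phi"]
        occ = tc.occupancy(phi)
        catalog = coupled_dataset["catalog"]
        genes = coupled_dataset["genes"]
        gene_chrom = dict(zip(genes["gene_id"], genes["chromosome"]))
        for name in catalog.names:
            hit = {gene_chrom[g] for g in catalog.networks[name] if g in gene_chrom}
            assert occ[name] == pytest.approx(len(hit) / len(phi.chromosomes))

    def test_size_occupancy_law(self, coupled_dataset):
        """Occupancy grows with network size (rank correlation > 0.5)."""
        phi = coupled_dataset["phi"]
        occ = tc.occupancy(phi)
        rho = stats.spearmanr(phi.network_sizes(), occ.to_numpy()).statistic
        assert rho > 0.5

    def test_networks_per_chromosome_constructed_case(self):
        counts = np.array([[1, 1], [1, 0], [1, 0]])
        phi_vals = np.where(counts > 0, 2.0, 0.0)
        phi = _phi(phi_vals, counts=counts)
        ann = tc.GenomeAnnotation(
            basepairs={"chr1": 30.0, "chr2": 20.0, "chr3": 10.0},
            gene_counts={"chr1": 2, "chr2": 1, "chr3": 1},
        )
        out = tc.networks_per_chromosome(phi, ann)
        assert list(out["counts"]) == [2, 1, 1]
        assert out["pcc_vs_gene_count"] == pytest.approx(1.0)

    def test_sensitivity_determinism(self, coupled_dataset):
        adj = tc.build_adjacency(coupled_dataset["ipd"], 0.07)
        phi = coupled_dataset["phi"]
        a = tc.per_network_sensitivity(adj, phi, n_steps=50, reps=5, seed=9)
        b = tc.per_network_sensitivity(adj, phi, n_steps=50, reps=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_small_clustered_networks_gain_most(self, coupled_dataset):
        """dH/H0 falls with network size, and most networks rise."""
        adj = tc.build_adjacency(coupled_dataset["ipd"], 0.07)
        phi = coupled_dataset["phi"]
        sens = tc.per_network_sensitivity(adj, phi, n_steps=200, reps=20, seed=10)
        ok = sens.dropna()
        rho = stats.spearmanr(ok["size"], ok["delta_h_rel"]).statistic
        assert rho < 0
        assert (ok["delta_h_rel"] > 0).mean() > 0.5
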