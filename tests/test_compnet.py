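"""SparCC inference: fractions, log-ratio variances, basis correlations,
permutation pseudo-p-values, and network construction."""

import numpy as np
import pandas as pd
import pytest

from ticknet.compnet import (
    CorrelationModel,
    basis_correlation,
    build_network,
    log_ratio_variance,
    permutation_pvalues,
    sparcc,
    to_fractions,
)
from ticknet.containers import CountTable, ValidationError


def direct_basis_correlation(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent one-shot evaluation of the sparsity approximation.

    Explicit loops, no shared code with the implementation: solve
    sum_{j != i} t_ij = (d-1) w_i + sum_{j != i} w_j for w, then
    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1].
    """
    d = t.shape[0]
    m = np.empty((d, d))
    b = np.empty(d)
    for i in range(d):
        b[i] = sum(t[i, j] for j in range(d) if j != i)
        for j in range(d):
            m[i, j] = (d - 1) if i == j else 1.0
    w = np.linalg.solve(m, b)
    rho = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            if i == j:
                rho[i, j] = 1.0
            else:
                val = (w[i] + w[j] - t[i, j]) / (2.0 * np.sqrt(w[i] * w[j]))
                rho[i, j] = max(-1.0, min(1.0, val))
    return w, rho


def lognormal_counts(rng, d, n, depth=50_000, rho=None, pair=(0, 1), log_sd=1.0):
    """Counts from independent (or one-pair-correlated) log-normal bases."""
    z = rng.standard_normal((d, n))
    if rho is not None:
        i, j = pair
        z[j] = rho * z[i] + np.sqrt(1 - rho**2) * z[j]
    basis = np.exp(log_sd * z + rng.normal(2.0, 1.0, d)[:, None])
    frac = basis / basis.sum(axis=0)
    return np.vstack([rng.multinomial(depth, frac[:, k]) for k in range(n)]).T


class TestToFractions:
    def test_pseudocount_symmetric_sample(self):
        frac = to_fractions(np.array([[2], [2], [2], [2]]), method="pseudocount")
        assert frac[:, 0] == pytest.approx([0.25, 0.25, 0.25, 0.25])

    def test_dirichlet_valid_composition(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(6, 10))
        frac = to_fractions(counts, method="dirichlet_draw", seed=1)
        assert np.all((frac > 0) & (frac < 1))
        assert frac.sum(axis=0) == pytest.approx(np.ones(10), abs=1e-12)

    def test_seed_determinism(self):
        counts = np.arange(24).reshape(4, 6)
        a = to_fractions(counts, "dirichlet_draw", seed=5)
        b = to_fractions(counts, "dirichlet_draw", seed=5)
        np.testing.assert_array_equal(a, b)

    def test_zero_sample_column_named_in_error(self):
        counts = np.array([[1, 0], [2, 0], [1, 0], [3, 0]])
        with pytest.raises(ValidationError, match="1"):
            to_fractions(counts, "pseudocount")


class TestLogRatioVariance:
    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(1)
        frac = to_fractions(rng.integers(1, 100, (5, 12)), "pseudocount")
        t = log_ratio_variance(frac)
        assert np.all(np.diag(t) == 0)
        np.testing.assert_allclose(t, t.T, atol=1e-14)
        assert np.all(t >= 0)

    def test_proportional_taxa_have_zero_variance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 1.0, size=(1, 10))
        frac = np.vstack([x, 3 * x, rng.uniform(0.1, 1, (2, 10))])
        frac = frac / frac.sum(axis=0)
        t = log_ratio_variance(frac)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        frac = to_fractions(rng.integers(1, 500, (4, 6)), "pseudocount")
        t = log_ratio_variance(frac)
        logf = np.log(frac)
        for i in range(4):
            for j in range(4):
                naive = np.var(logf[i] - logf[j], ddof=1)
                assert t[i, j] == pytest.approx(naive, abs=1e-12)

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            log_ratio_variance(np.full((4, 1), 0.25))


class TestBasisCorrelation:
    def test_rejects_fewer_than_four_taxa(self):
        with pytest.raises(ValidationError):
            basis_correlation(np.zeros((3, 3)))

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(4)
        for d in (5, 8):
            frac = to_fractions(rng.integers(1, 300, (d, 20)), "pseudocount")
            t = log_ratio_variance(frac)
            omega, rho = basis_correlation(t)
            w_ref, rho_ref = direct_basis_correlation(t)
            np.testing.assert_allclose(omega, w_ref, atol=1e-10)
            np.testing.assert_allclose(rho, rho_ref, atol=1e-10)

    def test_independent_bases_give_near_zero_rho(self):
        rng = np.random.default_rng(5)
        counts = lognormal_counts(rng, d=10, n=500)
        frac = to_fractions(counts, "pseudocount")
        _, rho = basis_correlation(log_ratio_variance(frac))
        off = rho[np.triu_indices(10, 1)]
        assert np.abs(off).mean() < 0.1

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(6)
        counts = lognormal_counts(rng, d=10, n=500, rho=0.9)
        frac = to_fractions(counts, "pseudocount")
        _, rho = basis_correlation(log_ratio_variance(frac))
        assert rho[0, 1] == pytest.approx(0.9, abs=0.15)

    def test_taxon_relabeling_permutes_rho(self):
        rng = np.random.default_rng(7)
        counts = lognormal_counts(rng, d=6, n=40)
        frac = to_fractions(counts, "pseudocount")
        _, rho = basis_correlation(log_ratio_variance(frac))
        perm = np.array([2, 0, 5, 1, 4, 3])
        _, rho_p = basis_correlation(log_ratio_variance(frac[perm]))
        np.testing.assert_allclose(rho_p, rho[np.ix_(perm, perm)], atol=1e-10)


class TestSparcc:
    def test_exclusion_disabled_equals_median_of_plain_solutions(self):
        rng = np.random.default_rng(8)
        counts = lognormal_counts(rng, d=6, n=30)
        model = sparcc(counts, n_inference_iter=7, exclusion_threshold=1.0, seed=99)
        assert model.excluded_pairs == []
        # replay the identical Dirichlet stream through the plain formula
        replay_rng = np.random.default_rng(99)
        rhos = []
        for _ in range(7):
            frac = to_fractions(counts, "dirichlet_draw", seed=replay_rng)
            _, rho = basis_correlation(log_ratio_variance(frac))
            rhos.append(rho)
        expected = np.median(rhos, axis=0)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(model.rho, expected, atol=1e-12)

    def test_single_iteration_reproducible(self):
        rng = np.random.default_rng(9)
        counts = lognormal_counts(rng, d=5, n=20)
        a = sparcc(counts, n_inference_iter=1, seed=3)
        b = sparcc(counts, n_inference_iter=1, seed=3)
        np.testing.assert_array_equal(a.rho, b.rho)

    def test_planted_hub_rho_among_strongest(self, hub_counts):
        model = sparcc(hub_counts, seed=17)
        taxa = model.taxa
        hub = taxa.index("hub_genus")
        sat = taxa.index("satellite_00")
        abs_off = np.abs(model.rho[np.triu_indices(len(taxa), 1)])
        assert model.rho[hub, sat] > 0
        assert np.abs(model.rho[hub, sat]) >= np.quantile(abs_off, 0.95)

    def test_compositionally_robust_to_sample_scaling(self):
        rng = np.random.default_rng(10)
        counts = lognormal_counts(rng, d=8, n=60)
        scaled = counts.copy()
        scaled[:, 0] = np.rint(scaled[:, 0] * 7)
        a = sparcc(counts, seed=4)
        b = sparcc(scaled, seed=4)
        assert np.abs(a.rho - b.rho).max() < 0.15


class TestPermutationPvalues:
    def test_floor_is_one_over_nperm_plus_one(self):
        # well-conditioned table (moderate spread, many samples) so the
        # permutation null never clips at |rho| = 1
        rng = np.random.default_rng(11)
        counts = lognormal_counts(rng, d=8, n=80, log_sd=0.5)
        # duplicated taxon: observed rho for the duplicate pair is maximal
        dup = np.vstack([counts, counts[0]])
        model = sparcc(dup, seed=1)
        pv = permutation_pvalues(dup, model.rho, n_perm=99, seed=2)
        assert pv.min() >= 1.0 / 100
        assert pv[0, 8] == pytest.approx(1.0 / 100)

    def test_rejects_zero_permutations(self):
        with pytest.raises(ValidationError):
            permutation_pvalues(np.ones((4, 6)), np.eye(4), n_perm=0)


class TestBuildNetwork:
    def _model(self, counts):
        d = counts.n_taxa
        rho = np.zeros((d, d))
        np.fill_diagonal(rho, 1.0)
        rho[0, 1] = rho[1, 0] = 0.8
        rho[2, 3] = rho[3, 2] = -0.6
        pvals = np.full((d, d), 0.001)
        np.fill_diagonal(pvals, 1.0)
        return CorrelationModel(taxa=counts.taxa, t=np.zeros((d, d)),
                                omega=np.ones(d), rho=rho, pvals=pvals)

    @pytest.fixture
    def toy_counts(self):
        df = pd.DataFrame(
            np.arange(1, 26).reshape(5, 5),
            index=[f"t{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(5)],
        )
        return CountTable(df)

    def test_hand_set_model_yields_two_signed_edges(self, toy_counts):
        net = build_network(self._model(toy_counts), toy_counts, r_min=0.3, alpha=0.05)
        g = net.graph
        assert g.number_of_nodes() == 5  # isolated nodes retained
        assert g.number_of_edges() == 2
        assert g["t0"]["t1"]["sign"] == "positive"
        assert g["t2"]["t3"]["sign"] == "negative"

    def test_zero_alpha_gives_no_edges(self, toy_counts):
        net = build_network(self._model(toy_counts), toy_counts, alpha=0.0)
        assert net.graph.number_of_edges() == 0

    def test_r_min_out_of_range_rejected(self, toy_counts):
        with pytest.raises(ValidationError):
            build_network(self._model(toy_counts), toy_counts, r_min=1.5)

    def test_edge_count_monotone_in_thresholds(self, hub_counts):
        model = sparcc(hub_counts, seed=20)
        model.pvals = permutation_pvalues(hub_counts, model.rho, n_perm=99, seed=21)
        edges = [
            build_network(model, hub_counts, r_min=r, alpha=a).graph.number_of_edges()
            for r, a in [(0.2, 0.10), (0.3, 0.10), (0.3, 0.05), (0.5, 0.05)]
        ]
        assert edges == sorted(edges, reverse=True)

    def test_node_attributes_present(self, toy_counts):
        net = build_network(self._model(toy_counts), toy_counts)
        attrs = net.graph.nodes["t0"]
        assert 0 <= attrs["ubiquity"] <= 1
        assert attrs["abundance"] > 0
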