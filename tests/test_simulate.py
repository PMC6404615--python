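import numpy as np
import pytest

from hetblup import (
    SimConfig,
    marker_kernel,
    omega_mixture,
    population_effect_correlation,
    simulate_dataset,
    simulate_effects,
    simulate_genotypes,
    simulate_phenotypes,
)


class TestSimulateGenotypes:
    def test_pure_memberships_at_zero_concentration(self):
        cfg = SimConfig(n=50, m=100, admixture_alpha=0.0, seed=1)
        _, A, _ = simulate_genotypes(cfg)
        assert set(np.unique(A.coeff)) == {0.0, 1.0}
        np.testing.assert_array_equal(A.coeff.sum(axis=1), 1.0)

    def test_vanishing_divergence_leaves_no_structure(self):
        cfg = SimConfig(n=150, m=600, fst=1e-6, seed=2)
        D, _, _ = simulate_genotypes(cfg)
        from hetblup import compute_G

        G, _ = compute_G(D)
        eigvals = np.sort(np.linalg.eigvalsh(G))[::-1]
        # leading eigenvalue not dominant: no population axis stands out
        assert eigvals[0] / eigvals[1] < 2.0

    def test_moderate_divergence_separates_clusters(self):
        from sklearn.metrics import silhouette_score

        from hetblup import compute_G, compute_pcs

        cfg = SimConfig(n_pops=4, fst=0.2, n=400, m=2000, seed=3)
        D, _, meta = simulate_genotypes(cfg)
        G, _ = compute_G(D)
        P = compute_pcs(G, d=3)
        score = silhouette_score(P.scores, meta.population.values)
        assert score > 0.5

    def test_serial_divergence_grades_distances(self):
        from hetblup import compute_G, compute_pcs

        cfg = SimConfig(n_pops=4, fst=0.2, n=200, m=1000,
                        divergence="serial", seed=4)
        D, _, meta = simulate_genotypes(cfg)
        G, _ = compute_G(D)
        P = compute_pcs(G, d=3)
        labels = meta.population.values
        cents = {p: P.scores[labels == p].mean(axis=0)
                 for p in sorted(set(labels))}
        d01 = np.linalg.norm(cents["pop0"] - cents["pop1"])
        d03 = np.linalg.norm(cents["pop0"] - cents["pop3"])
        assert d01 < d03

    def test_degenerate_divergence_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            SimConfig(fst=0.0)


class TestSimulateEffects:
    def test_homogeneous_effects_shared(self):
        cfg = SimConfig(n=40, m=200, seed=5, effect_model="homogeneous")
        D, A, _ = simulate_genotypes(cfg)
        g, effects = simulate_effects(cfg, D, A)
        assert effects.shape == (1, 200)
        Xc = D.values - D.values.mean(axis=0)
        np.testing.assert_allclose(g, Xc @ effects[0])

    def test_pure_clusters_full_interaction_decorrelates_effects(self):
        """rho = 1 with pure clusters: effect vectors of different clusters
        are uncorrelated (Monte-Carlo over markers)."""
        cfg = SimConfig(n=30, m=5000, n_pops=3, admixture_alpha=0.0,
                        seed=6, effect_model="mixture", rho_true=1.0)
        D, A, _ = simulate_genotypes(cfg)
        _, effects = simulate_effects(cfg, D, A)
        corr = np.corrcoef(effects)
        off = corr[np.triu_indices(3, k=1)]
        assert np.abs(off).max() < 0.05

    def test_matern_effect_correlation_matches_kernel(self):
        """Population coordinates one unit apart with h chosen so kappa is
        exp(-1): empirical effect correlation ~ 0.368."""
        coords = np.array([[0.0], [1.0]])
        cfg = SimConfig(n=20, m=5000, n_pops=2, seed=7, effect_model="matern",
                        nu_true=0.5, h_true=1.0, pop_coords=coords)
        D, A, _ = simulate_genotypes(cfg)
        _, effects = simulate_effects(cfg, D, A)
        emp = np.corrcoef(effects)[0, 1]
        assert emp == pytest.approx(np.exp(-1.0), abs=0.05)

    def test_simulated_covariance_matches_interaction_kernel(self):
        """Empirical Cov(g) over many effect draws matches the mixture
        interaction covariance (Omega o XX') entrywise."""
        cfg = SimConfig(n=10, m=50, n_pops=2, admixture_alpha=0.5, seed=8,
                        effect_model="mixture", rho_true=0.6)
        D, A, _ = simulate_genotypes(cfg)
        rng = np.random.default_rng(99)
        draws = np.array([simulate_effects(cfg, D, A, rng)[0]
                          for _ in range(4000)])
        emp = draws.T @ draws / len(draws)
        theo = omega_mixture(A, cfg.rho_true).omega * marker_kernel(D)
        scale = np.abs(theo).max()
        assert np.abs(emp - theo).max() < 0.05 * scale

    def test_individual_gp_effects_follow_kernel(self):
        """With per-individual GP effects, pairwise effect correlation
        tracks kappa of the coordinate distance."""
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(15, 2))
        cfg = SimConfig(n=15, m=4000, n_pops=2, seed=12, effect_model="matern",
                        nu_true=0.5, h_true=1.0, indiv_coords=coords)
        D, A, _ = simulate_genotypes(cfg)
        _, effects = simulate_effects(cfg, D, A)
        assert effects.shape == (15, 4000)
        emp = np.corrcoef(effects)
        d01 = np.linalg.norm(coords[0] - coords[1])
        assert emp[0, 1] == pytest.approx(np.exp(-d01), abs=0.06)

    def test_effect_correlation_matrix_by_model(self):
        cfg = SimConfig(n_pops=3, effect_model="mixture", rho_true=0.4)
        corr = population_effect_correlation(cfg)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert corr[0, 1] == pytest.approx(0.6)


class TestSimulatePhenotypes:
    def test_full_heritability_returns_genetic_values(self):
        g = np.random.default_rng(0).normal(size=100)
        y = simulate_phenotypes(g, 1.0, 0)
        np.testing.assert_array_equal(y, g)

    def test_variance_ratio_tracks_target(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=2000)
        y = simulate_phenotypes(g, 0.5, 2)
        ratio = g.var() / y.var()
        assert ratio == pytest.approx(0.5, abs=0.03)

    def test_deterministic_under_seed(self):
        g = np.random.default_rng(3).normal(size=50)
        np.testing.assert_array_equal(
            simulate_phenotypes(g, 0.3, 7), simulate_phenotypes(g, 0.3, 7)
        )

    def test_zero_variance_g_with_positive_h2_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            simulate_phenotypes(np.ones(10), 0.5, 0)


class TestSimulateDataset:
    def test_heritability_invariant(self):
        data = simulate_dataset(SimConfig(n=400, m=800, seed=9,
                                          effect_model="mixture",
                                          rho_true=0.3, h2=0.5))
        ratio = data.g_true.var() / data.y.var()
        assert abs(ratio - 0.5) < 0.05

    def test_dataset_components_consistent(self, small_sim):
        assert small_sim.X.n == len(small_sim.y) == len(small_sim.g_true)
        np.testing.assert_allclose(small_sim.A_true.coeff.sum(axis=1), 1.0)
        assert small_sim.X.n_missing() == 0
        # labels agree with the dominant admixture component
        labels = small_sim.labels.population.values
        argmax = small_sim.A_true.coeff.argmax(axis=1)
        assert all(lab == f"pop{k}" for lab, k in zip(labels, argmax))
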