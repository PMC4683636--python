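"""Sampler correctness: conditionals, oracles, invariances, determinism."""

import numpy as np
import pytest

from imprintvar.gibbs import (ModelSpec, fit_model, gaussian_deviance,
                              refreshed_residual, sample_variance)
from imprintvar.simulate import make_snp_panel, simulate_genotypes
from imprintvar.regressors import compute_regressors


class TestModelSpec:
    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="imprinting requires dominance"):
            ModelSpec(components=("additive", "imprinting"), chain_length=10, burn_in=5)
        with pytest.raises(ValueError, match="additive"):
            ModelSpec(components=("dominance",), chain_length=10, burn_in=5)

    def test_names(self):
        assert ModelSpec.from_name("ma", chain_length=10, burn_in=5).name == "MA"
        assert ModelSpec.from_name("MADI", chain_length=10, burn_in=5).name == "MADI"
        with pytest.raises(ValueError):
            ModelSpec.from_name("MADX")

    def test_n_saved(self):
        spec = ModelSpec.from_name("MA", chain_length=1000, burn_in=400, thin=100)
        assert spec.n_saved == 6


class TestSampleVariance:
    def test_too_few_effects(self):
        with pytest.raises(ValueError, match="improper"):
            sample_variance(1.0, 2)

    def test_zero_sum_sq_floored(self):
        assert sample_variance(0.0, 10) == 1e-12

    def test_inverse_chisq_moment(self):
        """sum_sq=10, count=12 draws 10/chisq_10 with mean 10/8 = 1.25."""
        rng = np.random.default_rng(123)
        draws = np.array([sample_variance(10.0, 12, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1.25, rel=0.01)

    def test_determinism(self):
        a = [sample_variance(3.0, 8, np.random.default_rng(5)) for _ in range(3)]
        b = [sample_variance(3.0, 8, np.random.default_rng(5)) for _ in range(3)]
        assert a == b


class TestDeviance:
    def test_closed_form(self):
        assert gaussian_deviance(0.0, 1.0, 2) == pytest.approx(2 * np.log(2 * np.pi))

    def test_scale_identity(self):
        """Scaling residuals by c and sigma2_e by c^2 shifts D by 2n log c."""
        n, sse, s2 = 50, 12.5, 0.8
        c = 3.0
        d0 = gaussian_deviance(sse, s2, n)
        d1 = gaussian_deviance(sse * c**2, s2 * c**2, n)
        assert d1 - d0 == pytest.approx(2 * n * np.log(c))

    def test_nonpositive_variance(self):
        with pytest.raises(ValueError):
            gaussian_deviance(1.0, 0.0, 10)


def _quick_spec(model="MADI", **kw):
    kw.setdefault("chain_length", 2000)
    kw.setdefault("burn_in", 1000)
    kw.setdefault("thin", 2)
    kw.setdefault("seed", 17)
    return ModelSpec.from_name(model, **kw)


class TestFitModel:
    def test_null_data(self, small_fit_data):
        """y = 0 pulls every explained variance to ~0."""
        _, R = small_fit_data
        y = np.zeros(R.n_individuals)
        chain = fit_model(y, R, _quick_spec())
        assert chain.var_Aa.mean() < 1e-3
        assert chain.var_Dd.mean() < 1e-3
        assert chain.var_Ii.mean() < 1e-3
        assert abs(chain.post_mean_mu) < 1e-3

    def test_determinism(self, small_fit_data):
        G, R = small_fit_data
        y = np.random.default_rng(1).normal(size=R.n_individuals)
        c1 = fit_model(y, R, _quick_spec())
        c2 = fit_model(y, R, _quick_spec())
        assert np.array_equal(c1.sigma2_e, c2.sigma2_e)
        assert np.array_equal(c1.var_Aa, c2.var_Aa)

    def test_residual_maintenance_guard(self, small_fit_data):
        """Maintained residual equals the residual recomputed from scratch."""
        G, R = small_fit_data
        rng = np.random.default_rng(2)
        y = rng.normal(size=R.n_individuals)
        chain = fit_model(y, R, _quick_spec())
        fresh = refreshed_residual(y, R, chain, chain.final_effects, chain.final_mu)
        assert np.max(np.abs(fresh - chain.final_residual)) < 1e-6

    def test_variance_additivity_per_iteration(self, small_fit_data):
        """var_Aa + var_Dd + var_Ii + var_L + sigma2_e == sigma2_P exactly."""
        _, R = small_fit_data
        y = np.random.default_rng(3).normal(size=R.n_individuals)
        chain = fit_model(y, R, _quick_spec())
        total = chain.var_Aa + chain.var_Dd + chain.var_Ii + chain.var_L + chain.sigma2_e
        assert np.array_equal(total, chain.sigma2_P)

    def test_scale_equivariance(self, small_fit_data):
        """Fitting c*y multiplies posterior variance draws by ~c^2."""
        _, R = small_fit_data
        y = np.random.default_rng(4).normal(size=R.n_individuals)
        c = 10.0
        c1 = fit_model(y, R, _quick_spec(chain_length=4000, burn_in=2000))
        c2 = fit_model(c * y, R, _quick_spec(chain_length=4000, burn_in=2000))
        assert c2.sigma2_e.mean() / c1.sigma2_e.mean() == pytest.approx(c**2, rel=0.1)
        assert c2.var_Aa.mean() / c1.var_Aa.mean() == pytest.approx(c**2, rel=0.35)

    def test_snp_order_exchangeability(self, small_fit_data):
        """Permuting SNP columns leaves posterior summaries unchanged up to
        Monte-Carlo error."""
        G, R = small_fit_data
        rng = np.random.default_rng(5)
        y = R.A[:, 3] * 0.5 + rng.normal(0, 1, R.n_individuals)
        from imprintvar.regressors import RegressorSet
        perm = rng.permutation(R.n_snps)
        Rp = RegressorSet(A=R.A[:, perm], D=R.D[:, perm], I=R.I[:, perm],
                          snps=[R.snps[j] for j in perm], individuals=R.individuals)
        spec = _quick_spec(chain_length=6000, burn_in=3000)
        c1 = fit_model(y, R, spec)
        c2 = fit_model(y, Rp, spec)
        assert c1.var_Aa.mean() == pytest.approx(c2.var_Aa.mean(), abs=0.05)
        assert c1.sigma2_e.mean() == pytest.approx(c2.sigma2_e.mean(), rel=0.1)

    def test_zero_variance_column_rejected(self, small_fit_data):
        G, R = small_fit_data
        from imprintvar.regressors import RegressorSet
        A = R.A.copy()
        A[:, 5] = 1.0
        Rbad = RegressorSet(A=A, D=R.D, I=R.I, snps=R.snps, individuals=R.individuals)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_model(np.zeros(R.n_individuals), Rbad, _quick_spec())

    def test_nonfinite_phenotype_rejected(self, small_fit_data):
        _, R = small_fit_data
        y = np.zeros(R.n_individuals)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_model(y, R, _quick_spec())

    def test_litter_effects_fitted(self, small_fit_data):
        """A strong common-litter signal shows up in var_L."""
        _, R = small_fit_data
        from imprintvar.simulate import simulate_litters
        labels, values = simulate_litters(R.n_individuals, 10, variance=1.0, seed=6)
        y = values + np.random.default_rng(7).normal(0, 0.3, R.n_individuals)
        chain = fit_model(y, R, _quick_spec(use_litter=True), litter=labels)
        assert chain.var_L.mean() > 0.4
        assert chain.sigma2_e.mean() < 0.4


class TestBLUPOracle:
    def test_fixed_variance_posterior_matches_ridge_solve(self):
        """With variances held at truth the Gibbs posterior mean of (mu, a)
        equals the closed-form solution of the mixed-model equations within
        3 Monte-Carlo standard errors (n=30, m=8)."""
        n, m = 30, 8
        rng = np.random.default_rng(21)
        snps = make_snp_panel(m, 2, rng=rng, freq_range=(0.3, 0.7))
        G = simulate_genotypes(n, snps, seed=22).with_frequencies()
        R = compute_regressors(G)
        sig2_a, sig2_e = 0.05, 0.5
        a_true = rng.normal(0, np.sqrt(sig2_a), m)
        y = 1.0 + R.A @ a_true + rng.normal(0, np.sqrt(sig2_e), n)

        # independent oracle: solve [W'W + Lambda] theta = W'y
        W = np.column_stack([np.ones(n), R.A])
        lam = np.diag([0.0] + [sig2_e / sig2_a] * m)
        theta = np.linalg.solve(W.T @ W + lam, W.T @ y)

        spec = ModelSpec.from_name(
            "MA", chain_length=40_000, burn_in=4000, thin=4, seed=23,
            update_variances=False, store_effects=True,
            init_variances={"additive": sig2_a, "residual": sig2_e})
        chain = fit_model(y, R, spec)
        draws = np.column_stack([chain.mu, chain.effect_draws["additive"]])
        post_mean = draws.mean(axis=0)
        # batch-means Monte-Carlo SE (20 batches)
        nb = 20
        batches = draws[: (draws.shape[0] // nb) * nb].reshape(nb, -1, m + 1)
        se = batches.mean(axis=1).std(axis=0, ddof=1) / np.sqrt(nb)
        assert np.all(np.abs(post_mean - theta) < 3 * se + 1e-3)

    def test_flat_prior_variance_concentration(self):
        """With many SNPs and a true common per-SNP variance v, the posterior
        mean of sigma2_a lands near v."""
        n, m, v = 500, 2000, 2.5e-4
        rng = np.random.default_rng(31)
        snps = make_snp_panel(m, 18, rng=rng, freq_range=(0.2, 0.8))
        G = simulate_genotypes(n, snps, seed=32).with_frequencies()
        R = compute_regressors(G)
        a_true = rng.normal(0, np.sqrt(v), m)
        y = R.A @ a_true + rng.normal(0, np.sqrt(0.7), n)
        spec = ModelSpec.from_name("MA", chain_length=4000, burn_in=2000,
                                   thin=4, seed=33)
        chain = fit_model(y, R, spec)
        assert chain.sigma2_a.mean() == pytest.approx(v, rel=0.5)
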