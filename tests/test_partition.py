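"""Explained variance, per-chromosome splits, length regression and the
genotypic-to-breeding-model transformation."""

import numpy as np
import pytest

from imprintvar.gibbs import ModelSpec, fit_model
from imprintvar.partition import (chromosome_length_regression, explained_variance,
                                  genotypic_value_variance, gram_scaling,
                                  per_chromosome_variance, to_breeding_model)
from imprintvar.regressors import RegressorSet, SNPInfo, compute_regressors
from imprintvar.simulate import (QTLSpec, make_snp_panel, qtl_effect_size,
                                 simulate_genotypes, simulate_phenotype)


class TestGenotypicValueVariance:
    def test_single_column(self):
        """Population variance of (-1, 0, 1) with unit effect is 2/3."""
        X = np.array([[-1.0], [0.0], [1.0]])
        assert genotypic_value_variance(X, np.array([1.0])) == pytest.approx(2 / 3)

    def test_zero_effects(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        assert genotypic_value_variance(X, np.zeros(4)) == 0.0


class TestGramScaling:
    def test_identity(self):
        assert gram_scaling(2.0, np.eye(3)) == pytest.approx(2.0)

    def test_single_column(self):
        X = np.array([[-1.0], [0.0], [1.0]])
        assert gram_scaling(3.0, X) == pytest.approx(2.0)

    def test_agreement_with_sample_variance_route(self):
        """On HWE genotypes both routes estimate the same total variance
        (sum over SNPs of var(x_j) * per-SNP variance)."""
        snps = make_snp_panel(40, 4, rng=np.random.default_rng(1))
        G = simulate_genotypes(4000, snps, seed=2).with_frequencies()
        R = compute_regressors(G)
        rng = np.random.default_rng(3)
        sigma2 = 0.01
        draws = rng.normal(0, np.sqrt(sigma2), size=(200, 40))
        sample_route = np.mean([genotypic_value_variance(R.A, d) for d in draws])
        gram_route = gram_scaling(sigma2, R.A - R.A.mean(axis=0))
        assert sample_route == pytest.approx(gram_route, rel=0.10)


class TestExplainedVariance:
    def test_empty_chain_rejected(self, small_fit_data):
        _, R = small_fit_data
        spec = ModelSpec.from_name("MA", chain_length=300, burn_in=100, thin=2, seed=1)
        chain = fit_model(np.zeros(R.n_individuals), R, spec)
        chain.var_Aa = chain.var_Aa[:0]
        chain.sigma2_e = chain.sigma2_e[:0]
        with pytest.raises(ValueError):
            explained_variance(chain)

    def test_ratios_bounded_and_summing(self, small_fit_data):
        _, R = small_fit_data
        rng = np.random.default_rng(9)
        y = R.A @ rng.normal(0, 0.1, R.n_snps) + rng.normal(0, 0.8, R.n_individuals)
        spec = ModelSpec.from_name("MADI", chain_length=2000, burn_in=1000, thin=2, seed=4)
        est = explained_variance(fit_model(y, R, spec))
        ratios = [est.ratio_means[c] for c in
                  ("additive", "dominance", "imprinting", "litter", "residual")]
        assert all(0 <= r <= 1 for r in ratios)
        assert sum(ratios) == pytest.approx(1.0, abs=1e-9)


def _polygenic_fit(seed=101, store=True):
    """Uniform polygenic additive trait over 18 chromosomes of unequal
    length: per-chromosome variance should track SNP count, i.e. length."""
    rng = np.random.default_rng(seed)
    # descending chromosome lengths (in SNPs) totalling 500
    counts = np.linspace(50, 6, 18).astype(int)
    counts[0] += 500 - counts.sum()
    snps = []
    j = 0
    for c, k in enumerate(counts):
        for s in range(k):
            snps.append(SNPInfo(f"c{c}s{s}", str(c + 1), (s + 1) * 1_000_000,
                                p=float(rng.uniform(0.2, 0.8))))
            j += 1
    G = simulate_genotypes(800, snps, seed=seed + 1).with_frequencies()
    R = compute_regressors(G)
    a_true = rng.normal(0, np.sqrt(6e-4), len(snps))
    y = R.A @ a_true + rng.normal(0, np.sqrt(0.7), 800)
    spec = ModelSpec.from_name("MA", chain_length=4000, burn_in=2000, thin=5,
                               seed=seed + 2, store_effects=store)
    return fit_model(y, R, spec), R


class TestPerChromosome:
    def test_requires_stored_effects(self):
        chain, R = _polygenic_fit(store=False)
        with pytest.raises(ValueError, match="store_effects"):
            per_chromosome_variance(chain, R)

    def test_concentrated_signal_lands_on_one_chromosome(self):
        """QTL only on chromosome 1: that chromosome carries essentially all
        explained additive variance."""
        snps = make_snp_panel(120, 6, rng=np.random.default_rng(5),
                              freq_range=(0.3, 0.7))
        G = simulate_genotypes(500, snps, seed=6).with_frequencies()
        R = compute_regressors(G)
        qtls = [QTLSpec(snp_index=j, qtl_type="additive",
                        a=qtl_effect_size(G.snps[j].p, "additive", 0.08))
                for j in range(5)]  # first chromosome holds SNPs 0..19
        trait = simulate_phenotype(R, qtls, residual_variance=0.2, seed=7)
        spec = ModelSpec.from_name("MA", chain_length=4000, burn_in=2000,
                                   thin=5, seed=8, store_effects=True)
        chain = fit_model(trait.phenotypes, R, spec)
        part = per_chromosome_variance(chain, R)
        t = part.table.set_index("chromosome")
        total = t["var_additive"].sum()
        assert t.loc["1", "var_additive"] / total > 0.6
        others = t.drop("1")["var_additive"] / total
        assert (others < 0.15).all()

    def test_within_chromosome_permutation_invariance(self):
        chain, R = _polygenic_fit()
        part = per_chromosome_variance(chain, R)
        # permute SNPs within chromosome 1 and re-partition
        cols = R.columns_for_chromosome("1")
        perm = np.random.default_rng(0).permutation(cols)
        order = np.arange(R.n_snps)
        order[cols] = perm
        Rp = RegressorSet(A=R.A[:, order], D=R.D[:, order], I=R.I[:, order],
                          snps=[R.snps[j] for j in order], individuals=R.individuals)
        chain.effect_draws = {"additive": chain.effect_draws["additive"][:, order]}
        part2 = per_chromosome_variance(chain, Rp)
        v1 = part.table.set_index("chromosome")["var_additive"]
        v2 = part2.table.set_index("chromosome")["var_additive"]
        assert np.allclose(v1.sort_index(), v2.sort_index())

    def test_sum_close_to_genome_total(self):
        """Summed per-chromosome variances agree with the genome-wide total
        within 15% under linkage equilibrium."""
        chain, R = _polygenic_fit()
        part = per_chromosome_variance(chain, R)
        summed = part.summed_totals()["additive"]
        assert summed == pytest.approx(part.genome_totals["additive"], rel=0.15)


class TestLengthRegression:
    def _partition_from_table(self, lengths, values):
        import pandas as pd
        from imprintvar.partition import ChromosomePartition
        table = pd.DataFrame({"chromosome": [str(i) for i in range(len(lengths))],
                              "length_bp": lengths, "n_snps": 10,
                              "var_additive": values})
        return ChromosomePartition(table=table, genome_totals={},
                                   components=("additive",))

    def test_exact_proportionality(self):
        lengths = np.arange(1, 19) * 1e7
        part = self._partition_from_table(lengths, 1e-9 * lengths)
        slope, intercept, r2 = chromosome_length_regression(part, "additive")
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1e-9)

    def test_permuted_lengths_kill_r2(self):
        rng = np.random.default_rng(12)
        lengths = np.arange(1, 19) * 1e7
        values = 1e-9 * rng.permutation(lengths)
        part = self._partition_from_table(lengths, values)
        _, _, r2 = chromosome_length_regression(part, "additive")
        assert r2 < 0.3

    def test_degenerate_lengths_error(self):
        part = self._partition_from_table(np.full(18, 1e7), np.random.rand(18))
        with pytest.raises(ValueError, match="degenerate"):
            chromosome_length_regression(part, "additive")

    def test_polygenic_trait_tracks_length(self):
        """Equal-variance SNPs spread over chromosomes of unequal length give
        a strong variance-vs-length relationship (r2 >= 0.8)."""
        chain, R = _polygenic_fit()
        part = per_chromosome_variance(chain, R)
        _, _, r2 = chromosome_length_regression(part, "additive")
        assert r2 >= 0.8


class TestBreedingModel:
    def test_p_half_reduction(self):
        a = np.array([0.3, -0.2])
        d = np.array([0.1, 0.4])
        p = np.array([0.5, 0.5])
        res = to_breeding_model(a, d, p)
        assert np.allclose(res.alpha, a)
        assert res.V_A_breeding == pytest.approx(float(np.sum(0.5 * a**2)))
        assert res.V_D_breeding == pytest.approx(float(np.sum(0.25 * d**2)))

    def test_no_dominance_reduces_to_genotypic(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=5)
        p = rng.uniform(0.1, 0.9, 5)
        res = to_breeding_model(a, np.zeros(5), p)
        assert res.V_A_breeding == pytest.approx(float(np.sum(2 * p * (1 - p) * a**2)))
        assert res.V_D_breeding == 0.0

    def test_hand_computed_example(self):
        res = to_breeding_model(np.array([0.0]), np.array([1.0]), np.array([0.4]))
        assert res.alpha[0] == pytest.approx(0.2)
        assert res.V_A_breeding == pytest.approx(0.0192)
        assert res.V_D_breeding == pytest.approx(0.2304)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            to_breeding_model(np.zeros(3), np.zeros(2), np.zeros(3))
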