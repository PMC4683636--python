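"""Simulate the 15-QTL validation trait and verify its variance structure.

The design: 5 additive, 5 dominance and 5 imprinting QTL on distinct
chromosomes, MAF 0.45-0.50, each calibrated to explain 2% of the phenotypic
variance; residual variance 0.70. Expected: genetic variance 0.30,
phenotypic variance 1.0, and 10% per component.
"""

import numpy as np

from imprintvar import compute_regressors, qtl_variance, select_qtl
from imprintvar.simulate import make_snp_panel, simulate_genotypes, simulate_phenotype

panel = make_snp_panel(720, n_chromosomes=18, rng=np.random.default_rng(10))
G = simulate_genotypes(10_000, panel, seed=11).with_frequencies()
R = compute_regressors(G)
qtls = select_qtl(G.snps, seed=12)
trait = simulate_phenotype(R, qtls, residual_variance=0.70, seed=13)

analytic = {"additive": 0.0, "dominance": 0.0, "imprinting": 0.0}
for q in qtls:
    Va, Vd, Vi, _ = qtl_variance(G.snps[q.snp_index].p, q.a, q.d, q.i)
    analytic["additive"] += Va
    analytic["dominance"] += Vd
    analytic["imprinting"] += Vi

print("analytic per-component variance (target 0.10 each):")
for comp, v in analytic.items():
    print(f"  {comp:<11} {v:.4f}")
print(f"empirical genetic variance  {trait.genetic_values.var():.3f}  (target 0.30)")
print(f"empirical phenotypic variance {trait.phenotypes.var():.3f}  (target 1.00)")
print("The tiny additive excess over 0.10 is the dominance QTLs' "
      "2pq[d(p-q)]^2 leakage, < 4.1e-4 per QTL at MAF >= 0.45.")
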