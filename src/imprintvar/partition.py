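"""From sampled SNP effects to explained variances, heritabilities,
per-chromosome partitions and the breeding-model transformation.

A SNP-based random-regression model does not directly yield a total explained
variance; two equivalent routes are provided. The primary route evaluates, at
each saved MCMC iteration, the sample variance of the genotypic-value vectors
Aa, Dd and Ii (recorded by the sampler), which also gives posterior SDs and
splits trivially by chromosome. The cross-check route scales the per-SNP
variance by the mean diagonal of the Gram matrix, var(Aa) = mean(diag(AA'))
* sig2_a.

Heritabilities are the per-iteration ratios of explained variance to total
phenotypic variance sigma2_P (narrow-sense h2 = var(Aa)/sigma2_P), averaged
over iterations; the ratio of posterior means is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gibbs import ChainSamples
from .regressors import RegressorSet, SNPInfo

logger = logging.getLogger(__name__)

COMPONENT_VARS = {"additive": "var_Aa", "dominance": "var_Dd", "imprinting": "var_Ii"}


@dataclass
class VarianceEstimates:
    """Posterior summaries of variance components and their ratios.

    ``means``/``sds`` map component names ('additive', 'dominance',
    'imprinting', 'litter', 'residual', 'phenotypic') to posterior means/SDs
    of the explained variances. ``ratio_means``/``ratio_sds`` summarize the
    per-iteration ratios to sigma2_P; ``ratio_of_means`` gives the alternative
    mean(var)/mean(sigma2_P) summary.
    """

    means: dict
    sds: dict
    ratio_means: dict
    ratio_sds: dict
    ratio_of_means: dict
    n_saved: int

    @property
    def h2_narrow(self) -> float:
        return self.ratio_means["additive"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.means:
            rows.append({
                "component": comp,
                "mean": self.means[comp],
                "sd": self.sds[comp],
                "ratio_mean": self.ratio_means.get(comp, np.nan),
                "ratio_sd": self.ratio_sds.get(comp, np.nan),
                "ratio_of_means": self.ratio_of_means.get(comp, np.nan),
            })
        return pd.DataFrame(rows)


def explained_variance(chain: ChainSamples) -> VarianceEstimates:
    """Summarize a chain's explained variances and their ratios to sigma2_P."""
    if chain.n_saved == 0:
        raise ValueError("empty chain")
    comps = {
        "additive": chain.var_Aa,
        "dominance": chain.var_Dd,
        "imprinting": chain.var_Ii,
        "litter": chain.var_L,
        "residual": chain.sigma2_e,
    }
    sigma2_P = chain.sigma2_P
    means = {k: float(v.mean()) for k, v in comps.items()}
    sds = {k: float(v.std(ddof=1)) if v.size > 1 else 0.0 for k, v in comps.items()}
    means["phenotypic"] = float(sigma2_P.mean())
    sds["phenotypic"] = float(sigma2_P.std(ddof=1)) if sigma2_P.size > 1 else 0.0
    ratio_means, ratio_sds, ratio_of_means = {}, {}, {}
    for k, v in comps.items():
        ratios = v / sigma2_P
        ratio_means[k] = float(ratios.mean())
        ratio_sds[k] = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
        ratio_of_means[k] = means[k] / means["phenotypic"]
    return VarianceEstimates(means=means, sds=sds, ratio_means=ratio_means,
                             ratio_sds=ratio_sds, ratio_of_means=ratio_of_means,
                             n_saved=chain.n_saved)


def genotypic_value_variance(X: np.ndarray, effects: np.ndarray) -> float:
    """Population variance (denominator n) of the genotypic-value vector
    X @ effects — the per-iteration explained-variance statistic."""
    g = X @ effects
    return float(g.var())


def gram_scaling(sigma2_snp: float, X: np.ndarray) -> float:
    """Total explained variance via the Gram-diagonal route:
    mean(diag(XX')) * sigma2_snp = mean_i(sum_j x_ij^2) * sigma2_snp."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    return float(np.mean(np.einsum("ij,ij->i", X, X)) * sigma2_snp)


@dataclass
class ChromosomePartition:
    """Per-chromosome explained variances with physical lengths."""

    table: pd.DataFrame  # chromosome, length_bp, n_snps, var_<comp> columns
    genome_totals: dict  # component -> genome-wide posterior mean (all columns)
    components: tuple[str, ...]

    def summed_totals(self) -> dict:
        return {c: float(self.table[f"var_{c}"].sum()) for c in self.components}


def _chromosome_lengths(snps: list[SNPInfo]) -> dict:
    by_chrom: dict[str, list[int]] = {}
    for s in snps:
        by_chrom.setdefault(s.chromosome, []).append(s.position_bp)
    return {c: (max(pos) - min(pos)) for c, pos in by_chrom.items()}


def per_chromosome_variance(chain: ChainSamples, R: RegressorSet) -> ChromosomePartition:
    """Split each component's explained variance by chromosome.

    Requires the chain to have been run with ``store_effects=True``. At every
    saved iteration and for every chromosome, the sample variance of the
    genotypic-value vector restricted to that chromosome's columns is
    computed; posterior means are tabulated next to the chromosome's physical
    length (bp between its first and last retained SNP). Genome-wide totals
    (all columns jointly) are also reported — they differ from the sum across
    chromosomes by cross-chromosome covariance terms.
    """
    if chain.effect_draws is None:
        raise ValueError("chain was run without store_effects=True")
    comps = tuple(chain.spec.components)
    mats = {"additive": R.A, "dominance": R.D, "imprinting": R.I}
    lengths = _chromosome_lengths(R.snps)
    chrom_cols: dict[str, np.ndarray] = {}
    for j, s in enumerate(R.snps):
        chrom_cols.setdefault(s.chromosome, []).append(j)
    rows = []
    for chrom, cols in chrom_cols.items():
        cols = np.asarray(cols, dtype=int)
        if cols.size == 0:
            logger.warning("chromosome %s has no SNPs; omitted", chrom)
            continue
        row = {"chromosome": chrom, "length_bp": lengths[chrom], "n_snps": cols.size}
        for comp in comps:
            draws = chain.effect_draws[comp][:, cols]       # (n_saved, m_c)
            G = mats[comp][:, cols] @ draws.T               # (n, n_saved)
            row[f"var_{comp}"] = float(G.var(axis=0).mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    genome_totals = {}
    for comp in comps:
        draws = chain.effect_draws[comp]
        G = mats[comp] @ draws.T
        genome_totals[comp] = float(G.var(axis=0).mean())
    return ChromosomePartition(table=table, genome_totals=genome_totals, components=comps)


def chromosome_length_regression(partition: ChromosomePartition,
                                 component: str) -> tuple[float, float, float]:
    """OLS of per-chromosome explained variance on physical length;
    returns (slope, intercept, r2)."""
    if component not in partition.components:
        raise ValueError(f"component {component!r} not in partition")
    table = partition.table
    ok = table["length_bp"] > 0
    x = table.loc[ok, "length_bp"].to_numpy(dtype=float)
    yv = table.loc[ok, f"var_{component}"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 chromosomes with positive length")
    if np.var(x) == 0:
        raise ValueError("degenerate regressor: all chromosome lengths equal")
    fit = stats.linregress(x, yv)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass
class BreedingModelVariances:
    """Genotypic-model estimates re-expressed on the classical (breeding)
    parameterization via allele substitution effects alpha = a + d(q - p)."""

    V_A_breeding: float
    V_D_breeding: float
    alpha: np.ndarray


def to_breeding_model(a: np.ndarray, d: np.ndarray,
                      freqs: np.ndarray) -> BreedingModelVariances:
    """Transform per-SNP genotypic effects (a, d) at frequencies p into
    breeding-model variances under linkage equilibrium:
    alpha = a + d(q - p); V_A = sum 2pq alpha^2; V_D = sum (2pq d)^2."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if not (a.shape == d.shape == p.shape):
        raise ValueError("effect and frequency vectors must have equal length")
    q = 1.0 - p
    alpha = a + d * (q - p)
    V_A = float(np.sum(2 * p * q * alpha ** 2))
    V_D = float(np.sum((2 * p * q * d) ** 2))
    return BreedingModelVariances(V_A_breeding=V_A, V_D_breeding=V_D, alpha=alpha)


def breeding_model_from_chain(chain: ChainSamples, freqs: np.ndarray) -> pd.DataFrame:
    """Apply the breeding-model transformation at every saved iteration and
    summarize posterior mean and SD of V_A and V_D."""
    if chain.effect_draws is None:
        raise ValueError("chain was run without store_effects=True")
    a_draws = chain.effect_draws["additive"]
    d_draws = chain.effect_draws.get("dominance")
    if d_draws is None:
        d_draws = np.zeros_like(a_draws)
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    alpha = a_draws + d_draws * (q - p)
    V_A = np.sum(2 * p * q * alpha ** 2, axis=1)
    V_D = np.sum((2 * p * q * d_draws) ** 2, axis=1)
    return pd.DataFrame({
        "quantity": ["V_A_breeding", "V_D_breeding"],
        "mean": [float(V_A.mean()), float(V_D.mean())],
        "sd": [float(V_A.std(ddof=1)), float(V_D.std(ddof=1))],
    })


def plot_variance_vs_length(partition: ChromosomePartition, path: str) -> None:
    """Scatter of per-chromosome explained variance against physical length,
    one panel per component, with the OLS line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = partition.components
    fig, axes = plt.subplots(1, len(comps), figsize=(4 * len(comps), 3.5), squeeze=False)
    for ax, comp in zip(axes[0], comps):
        x = partition.table["length_bp"] / 1e6
        yv = partition.table[f"var_{comp}"]
        ax.scatter(x, yv, s=18)
        slope, intercept, r2 = chromosome_length_regression(partition, comp)
        xs = np.linspace(x.min(), x.max(), 2)
        ax.plot(xs, intercept + slope * xs * 1e6, color="k", lw=1)
        ax.set_title(f"{comp} (r$^2$={r2:.2f})")
        ax.set_xlabel("chromosome length (Mb)")
        ax.set_ylabel("explained variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
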