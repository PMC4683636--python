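"""Synthetic phased genotypes and phenotypes for validating the variance models.

The generator reproduces the statistical structure of a livestock-style
validation design: a cohort of individuals with phased biallelic SNPs in
Hardy-Weinberg equilibrium and linkage equilibrium across 18 autosomes, a
trait controlled by 15 QTL — 5 purely additive, 5 purely dominant, 5 purely
imprinted — each calibrated to explain 2% of the phenotypic variance, and an
independent normal residual of variance 0.70. Total genetic variance is then
0.30 and total phenotypic variance 1, with additive, dominance and imprinting
"heritabilities" of 0.10 each.

Single-QTL variance components follow the classical decomposition

    Va = 2pq [a + d(p - q)]^2      Vd = (2pq d)^2      Vi = 2pq i^2

where ``p`` is the counted-allele frequency and ``a``, ``d``, ``i`` the
additive, dominance and imprinting effects. Effects are calibrated by
inverting these formulas at each QTL's realized frequency so the own-type
component hits its target exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .regressors import PhasedGenotypeMatrix, RegressorSet, SNPInfo, compute_regressors

QTL_TYPES = ("additive", "dominance", "imprinting")

DEFAULT_N_CHROMOSOMES = 18
DEFAULT_RESIDUAL_VARIANCE = 0.70
DEFAULT_QTL_VARIANCE = 0.02
DEFAULT_MAF_RANGE = (0.45, 0.50)
DEFAULT_QTL_COUNTS = (5, 5, 5)


@dataclass(frozen=True)
class QTLSpec:
    """A causal SNP with exactly one nonzero effect, matching its type."""

    snp_index: int
    qtl_type: str
    a: float = 0.0
    d: float = 0.0
    i: float = 0.0
    target_variance: float = DEFAULT_QTL_VARIANCE

    def __post_init__(self) -> None:
        if self.qtl_type not in QTL_TYPES:
            raise ValueError(f"unknown QTL type {self.qtl_type!r}")
        nonzero = {"additive": self.a, "dominance": self.d, "imprinting": self.i}[self.qtl_type]
        others = [v for k, v in (("additive", self.a), ("dominance", self.d),
                                 ("imprinting", self.i)) if k != self.qtl_type]
        if nonzero == 0.0 or any(v != 0.0 for v in others):
            raise ValueError("exactly the effect matching qtl_type must be nonzero")


@dataclass
class SimulatedTrait:
    phenotypes: np.ndarray
    genetic_values: np.ndarray
    residuals: np.ndarray
    qtls: list[QTLSpec]
    residual_variance: float
    replicate_id: int = 0
    seed: int = 0


def qtl_variance(p: float, a: float, d: float, i: float) -> tuple[float, float, float, float]:
    """Single-locus variance components (Va, Vd, Vi, VG) at counted-allele
    frequency ``p`` under HWE. Total function of its inputs."""
    q = 1.0 - p
    two_pq = 2.0 * p * q
    Va = two_pq * (a + d * (p - q)) ** 2
    Vd = (two_pq * d) ** 2
    Vi = two_pq * i * i
    return Va, Vd, Vi, Va + Vd + Vi


def qtl_effect_size(p: float, qtl_type: str, target_variance: float = DEFAULT_QTL_VARIANCE) -> float:
    """The unique positive effect whose own-type variance equals
    ``target_variance`` at frequency ``p``: a = sqrt(v/2pq) for additive,
    d = sqrt(v)/2pq for dominance, i = sqrt(v/2pq) for imprinting."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"monomorphic QTL: p={p}")
    if target_variance <= 0:
        raise ValueError("target_variance must be positive")
    two_pq = 2.0 * p * (1.0 - p)
    if qtl_type == "additive" or qtl_type == "imprinting":
        return math.sqrt(target_variance / two_pq)
    if qtl_type == "dominance":
        return math.sqrt(target_variance) / two_pq
    raise ValueError(f"unknown QTL type {qtl_type!r}")


def make_snp_panel(
    n_snps: int,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    spacing_bp: int = 1_000_000,
    freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> list[SNPInfo]:
    """Evenly spaced SNP map over ``n_chromosomes`` autosomes of unequal size
    (SNP counts, and hence physical lengths, decline roughly 2.5-fold from the
    largest to the smallest chromosome, as in livestock genomes). Frequencies
    are drawn uniformly over ``freq_range`` (a post-QC panel) unless provided.
    """
    if freqs is None:
        if rng is None:
            rng = np.random.default_rng()
        freqs = rng.uniform(*freq_range, size=n_snps)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (n_snps,):
        raise ValueError("freqs length must equal n_snps")
    if n_snps <= n_chromosomes:
        counts = np.array([1] * n_snps + [0] * (n_chromosomes - n_snps))
    elif n_chromosomes > 1:
        weights = np.linspace(1.8, 0.7, n_chromosomes)
        counts = np.maximum((n_snps * weights / weights.sum()).astype(int), 1)
        counts[0] += n_snps - counts.sum()
    else:
        counts = np.array([n_snps])
    snps: list[SNPInfo] = []
    j = 0
    for c in range(n_chromosomes):
        count = int(counts[c])
        for k in range(count):
            snps.append(SNPInfo(
                snp_id=f"snp{j:06d}",
                chromosome=str(c + 1),
                position_bp=(k + 1) * spacing_bp,
                allele_counted="B",
                allele_other="A",
                p=float(freqs[j]),
            ))
            j += 1
    return snps


def simulate_genotypes(
    n_individuals: int,
    snps: list[SNPInfo] | np.ndarray,
    seed: int,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
) -> PhasedGenotypeMatrix:
    """Draw paternal and maternal alleles independently Bernoulli(p) per SNP
    (HWE, linkage equilibrium) with parental origin known exactly.

    ``snps`` may be a list of SNPInfo (whose ``p`` is the generating
    frequency) or a bare frequency vector, in which case an evenly spaced
    panel over ``n_chromosomes`` is created.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not isinstance(snps, list):
        snps = make_snp_panel(len(np.atleast_1d(snps)), n_chromosomes,
                              freqs=np.atleast_1d(snps))
    freqs = np.array([s.p for s in snps], dtype=float)
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("generating frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    P1 = (rng.random((n_individuals, len(snps))) < freqs).astype(np.float64)
    P2 = (rng.random((n_individuals, len(snps))) < freqs).astype(np.float64)
    individuals = [f"ind{i:05d}" for i in range(n_individuals)]
    return PhasedGenotypeMatrix(individuals, list(snps), P1, P2)


def select_qtl(
    snps: list[SNPInfo],
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    counts: tuple[int, int, int] = DEFAULT_QTL_COUNTS,
    one_per_chromosome: bool = True,
    seed: int = 0,
    target_variance: float = DEFAULT_QTL_VARIANCE,
    exclude_indices: set[int] | None = None,
) -> list[QTLSpec]:
    """Randomly pick causal SNPs with MAF in ``maf_range`` (optionally on
    distinct chromosomes) and calibrate each effect at the SNP's own
    frequency so its own-type variance equals ``target_variance``.

    ``exclude_indices`` supports disjoint QTL sets across replicates drawn
    from a shared panel.
    """
    n_total = sum(counts)
    if n_total == 0:
        return []
    rng = np.random.default_rng(seed)
    exclude = exclude_indices or set()
    eligible = [j for j, s in enumerate(snps)
                if j not in exclude and maf_range[0] <= s.maf <= maf_range[1]]
    if one_per_chromosome:
        by_chrom: dict[str, list[int]] = {}
        for j in eligible:
            by_chrom.setdefault(snps[j].chromosome, []).append(j)
        if len(by_chrom) < n_total:
            raise ValueError(
                f"need {n_total} chromosomes with an eligible SNP "
                f"(MAF in {maf_range}), found {len(by_chrom)}")
        chroms = list(by_chrom)
        chosen_chroms = rng.choice(len(chroms), size=n_total, replace=False)
        chosen = [int(rng.choice(by_chrom[chroms[c]])) for c in chosen_chroms]
    else:
        if len(eligible) < n_total:
            raise ValueError(
                f"need {n_total} eligible SNPs (MAF in {maf_range}), found {len(eligible)}")
        chosen = [int(j) for j in rng.choice(eligible, size=n_total, replace=False)]

    qtls: list[QTLSpec] = []
    types = [t for t, c in zip(QTL_TYPES, counts) for _ in range(c)]
    for j, qtl_type in zip(chosen, types):
        eff = qtl_effect_size(snps[j].p, qtl_type, target_variance)
        qtls.append(QTLSpec(
            snp_index=j,
            qtl_type=qtl_type,
            a=eff if qtl_type == "additive" else 0.0,
            d=eff if qtl_type == "dominance" else 0.0,
            i=eff if qtl_type == "imprinting" else 0.0,
            target_variance=target_variance,
        ))
    return qtls


def simulate_phenotype(
    R: RegressorSet,
    qtls: list[QTLSpec],
    residual_variance: float = DEFAULT_RESIDUAL_VARIANCE,
    seed: int = 0,
    replicate_id: int = 0,
) -> SimulatedTrait:
    """Genetic value per individual = sum over QTL of A·a + D·d + I·i at the
    QTL columns; phenotype adds an iid Normal(0, residual_variance) residual."""
    if residual_variance < 0:
        raise ValueError("residual_variance must be non-negative")
    n = R.n_individuals
    g = np.zeros(n)
    for q in qtls:
        if not 0 <= q.snp_index < R.n_snps:
            raise IndexError(f"QTL index {q.snp_index} out of range")
        g += R.A[:, q.snp_index] * q.a + R.D[:, q.snp_index] * q.d + R.I[:, q.snp_index] * q.i
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, math.sqrt(residual_variance), size=n) if residual_variance > 0 else np.zeros(n)
    return SimulatedTrait(
        phenotypes=g + e,
        genetic_values=g,
        residuals=e,
        qtls=list(qtls),
        residual_variance=residual_variance,
        replicate_id=replicate_id,
        seed=seed,
    )


@dataclass
class Replicate:
    genotypes: PhasedGenotypeMatrix
    regressors: RegressorSet
    trait: SimulatedTrait
    replicate_id: int


def simulate_replicates(
    n_replicates: int = 10,
    n_individuals: int = 1000,
    n_snps: int = 1500,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    counts: tuple[int, int, int] = DEFAULT_QTL_COUNTS,
    qtl_variance_target: float = DEFAULT_QTL_VARIANCE,
    residual_variance: float = DEFAULT_RESIDUAL_VARIANCE,
    base_seed: int = 1,
    share_genotypes: bool = False,
) -> list[Replicate]:
    """Generate validation replicates of the 15-QTL design.

    By default each replicate draws its own genotype cohort (seed
    ``base_seed + k``). With ``share_genotypes=True`` one cohort is reused and
    the replicate QTL sets are kept disjoint, mirroring a design that reuses a
    single real genotype panel.
    """
    reps: list[Replicate] = []
    used: set[int] = set()
    panel_rng = np.random.default_rng(base_seed)
    shared_snps = make_snp_panel(n_snps, n_chromosomes, rng=panel_rng)
    if share_genotypes:
        G = simulate_genotypes(n_individuals, shared_snps, seed=base_seed).with_frequencies()
        R = compute_regressors(G)
    for k in range(n_replicates):
        seed_k = base_seed + k
        if not share_genotypes:
            snps = make_snp_panel(n_snps, n_chromosomes, rng=np.random.default_rng(10_000 + seed_k))
            G = simulate_genotypes(n_individuals, snps, seed=seed_k).with_frequencies()
            R = compute_regressors(G)
        qtls = select_qtl(
            G.snps, maf_range=maf_range, counts=counts, one_per_chromosome=True,
            seed=20_000 + seed_k, target_variance=qtl_variance_target,
            exclude_indices=used if share_genotypes else None,
        )
        if share_genotypes:
            used.update(q.snp_index for q in qtls)
        trait = simulate_phenotype(R, qtls, residual_variance, seed=30_000 + seed_k,
                                   replicate_id=k)
        reps.append(Replicate(genotypes=G, regressors=R, trait=trait, replicate_id=k))
    return reps


def simulate_litters(n_individuals: int, litter_size: int, variance: float,
                     seed: int) -> tuple[list[str], np.ndarray]:
    """Optional iid random litter intercepts for exercising the common-litter
    model term: returns per-individual litter labels and their effects."""
    rng = np.random.default_rng(seed)
    n_litters = -(-n_individuals // litter_size)
    effects = rng.normal(0.0, math.sqrt(variance), size=n_litters)
    labels = [f"litter{i // litter_size:04d}" for i in range(n_individuals)]
    values = np.array([effects[i // litter_size] for i in range(n_individuals)])
    return labels, values
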