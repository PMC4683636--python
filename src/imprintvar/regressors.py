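"""Quality control of phased genotypes and construction of the A/D/I regressors.

The central objects are :class:`PhasedGenotypeMatrix`, holding for every
individual and SNP the probabilities that the counted allele was inherited
from the father (``P1``) and from the mother (``P2``), and
:class:`RegressorSet`, holding the derived design-matrix entries

* additive   ``A = P1 + P2 - 1``  (allele dosage, centred at the heterozygote),
* dominance  ``D = |P1 - P2|``    (1 for a certain heterozygote, 0 for homozygotes),
* imprinting ``I = P1 - P2``      (+1 when the counted allele is paternal,
  -1 when maternal, 0 for homozygotes).

With fully certain phase the four ordered genotypes (counted paternal /
counted maternal) map to A in {-1, 0, 0, +1}, D in {0, 1, 1, 0} and
I in {0, +1, -1, 0}; ``D == |I|`` holds identically for any probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: order in which QC rules are applied; a SNP is charged to the first failure
QC_RULE_ORDER = ("unmapped", "sex_chromosome", "call_rate", "maf", "hwe")

SEX_CHROMOSOMES = frozenset({"X", "Y", "x", "y"})
UNMAPPED_LABELS = frozenset({"", "0", "NA", "unmapped", None})

_HARD_CALL_TOL = 1e-6


@dataclass(frozen=True)
class SNPInfo:
    """A biallelic SNP: identity, map position and counted-allele frequency."""

    snp_id: str
    chromosome: str
    position_bp: int
    allele_counted: str = "B"
    allele_other: str = "A"
    p: float = float("nan")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def maf(self) -> float:
        return min(self.p, 1.0 - self.p)


@dataclass
class PhasedGenotypeMatrix:
    """Per-individual, per-SNP parental-origin probabilities of the counted allele.

    ``P1[i, j]`` is the probability that individual ``i`` received the counted
    allele of SNP ``j`` from its father, ``P2`` the analogous maternal
    probability. Hard calls are represented by probabilities in {0, 1}.
    """

    individuals: list[str]
    snps: list[SNPInfo]
    P1: np.ndarray
    P2: np.ndarray
    missing_mask: np.ndarray = None  # True where the call is missing

    def __post_init__(self) -> None:
        self.P1 = np.asarray(self.P1, dtype=np.float64)
        self.P2 = np.asarray(self.P2, dtype=np.float64)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.P1.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = len(self.individuals), len(self.snps)
        for name, arr in (("P1", self.P1), ("P2", self.P2), ("missing_mask", self.missing_mask)):
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        valid = ~self.missing_mask
        for name, arr in (("P1", self.P1), ("P2", self.P2)):
            vals = arr[valid]
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def with_frequencies(self) -> "PhasedGenotypeMatrix":
        """Return a copy whose SNPInfo ``p`` fields hold the realized frequencies."""
        freqs = [allele_frequency(self, j) for j in range(self.n_snps)]
        snps = [replace(s, p=f) for s, f in zip(self.snps, freqs)]
        return PhasedGenotypeMatrix(self.individuals, snps, self.P1.copy(),
                                    self.P2.copy(), self.missing_mask.copy())


@dataclass
class RegressorSet:
    """Additive, dominance and imprinting design-matrix entries per SNP."""

    A: np.ndarray
    D: np.ndarray
    I: np.ndarray
    snps: list[SNPInfo]
    individuals: list[str]

    @property
    def n_individuals(self) -> int:
        return self.A.shape[0]

    @property
    def n_snps(self) -> int:
        return self.A.shape[1]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.chromosome, None)
        return list(seen)

    def columns_for_chromosome(self, chromosome: str) -> np.ndarray:
        return np.array([j for j, s in enumerate(self.snps) if s.chromosome == chromosome],
                        dtype=int)


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    removed_by_rule: dict = field(default_factory=dict)
    n_individuals_removed: int = 0

    def __post_init__(self) -> None:
        total_removed = sum(self.removed_by_rule.values())
        if self.n_snps_out + total_removed != self.n_snps_in:
            raise ValueError("QC accounting does not balance")


def allele_frequency(G: PhasedGenotypeMatrix, snp_index: int) -> float:
    """Frequency of the counted allele at one SNP, i.e. mean of (P1+P2)/2
    over non-missing individuals (equals the allele frequency for hard calls)."""
    keep = ~G.missing_mask[:, snp_index]
    if not keep.any():
        raise ValueError(f"monomorphic/empty column: all calls missing at SNP index {snp_index}")
    return float(np.mean((G.P1[keep, snp_index] + G.P2[keep, snp_index]) / 2.0))


def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df goodness-of-fit chi-square of genotype counts against
    Hardy-Weinberg proportions (n p^2, 2npq, n q^2), with p estimated from
    the counts themselves. Monomorphic input returns 0 (no test possible)."""
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("no genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        return 0.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    return float(np.sum((observed - expected) ** 2 / expected))


def _hard_call_counts(G: PhasedGenotypeMatrix, snp_index: int) -> tuple[int, int, int]:
    """Genotype counts (hom counted, het, hom other) using only entries whose
    P1 and P2 are within 1e-6 of {0,1}; soft calls are excluded."""
    keep = ~G.missing_mask[:, snp_index]
    p1 = G.P1[keep, snp_index]
    p2 = G.P2[keep, snp_index]
    certain = (np.minimum(p1, 1 - p1) < _HARD_CALL_TOL) & (np.minimum(p2, 1 - p2) < _HARD_CALL_TOL)
    dosage = np.rint(p1[certain]) + np.rint(p2[certain])
    return int(np.sum(dosage == 2)), int(np.sum(dosage == 1)), int(np.sum(dosage == 0))


def _subset(G: PhasedGenotypeMatrix, rows: np.ndarray, cols: np.ndarray) -> PhasedGenotypeMatrix:
    return PhasedGenotypeMatrix(
        [G.individuals[i] for i in np.flatnonzero(rows)],
        [G.snps[j] for j in np.flatnonzero(cols)],
        G.P1[np.ix_(rows, cols)],
        G.P2[np.ix_(rows, cols)],
        G.missing_mask[np.ix_(rows, cols)],
    )


def qc_filter(
    G: PhasedGenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_chisq_max: float = 600.0,
    indiv_missing_max: float = 0.05,
) -> tuple[PhasedGenotypeMatrix, QCReport]:
    """Remove SNPs failing, in fixed order: unmapped / sex chromosome,
    call rate < ``call_rate_min``, MAF < ``maf_min`` (monomorphic SNPs are
    charged here too), HWE chi-square > ``hwe_chisq_max``; then remove
    individuals whose missing fraction exceeds ``indiv_missing_max``.
    Every removal is charged to exactly one rule."""
    if G.n_snps == 0 or G.n_individuals == 0:
        raise ValueError("empty genotype matrix")

    n, m = G.n_individuals, G.n_snps
    removed = {rule: 0 for rule in QC_RULE_ORDER}
    keep_snp = np.ones(m, dtype=bool)

    for j, snp in enumerate(G.snps):
        chrom = snp.chromosome
        if chrom in UNMAPPED_LABELS:
            removed["unmapped"] += 1
            keep_snp[j] = False
            continue
        if chrom in SEX_CHROMOSOMES:
            removed["sex_chromosome"] += 1
            keep_snp[j] = False
            continue
        n_called = int(np.sum(~G.missing_mask[:, j]))
        if n_called / n < call_rate_min:
            removed["call_rate"] += 1
            keep_snp[j] = False
            continue
        if n_called == 0:
            # call_rate_min == 0 with an all-missing column: unusable
            removed["call_rate"] += 1
            keep_snp[j] = False
            continue
        p = allele_frequency(G, j)
        if min(p, 1 - p) < maf_min or p <= 0.0 or p >= 1.0:
            removed["maf"] += 1
            keep_snp[j] = False
            continue
        chi2 = hwe_chisq(*_hard_call_counts(G, j))
        if chi2 > hwe_chisq_max:
            removed["hwe"] += 1
            keep_snp[j] = False

    if not keep_snp.any():
        raise ValueError("no SNPs survive QC")

    missing_frac = G.missing_mask[:, keep_snp].mean(axis=1)
    keep_ind = missing_frac <= indiv_missing_max
    n_ind_removed = int(np.sum(~keep_ind))
    if not keep_ind.any():
        raise ValueError("no individuals survive QC")

    out = _subset(G, keep_ind, keep_snp)
    out = out.with_frequencies()
    report = QCReport(
        n_snps_in=m,
        n_snps_out=int(keep_snp.sum()),
        removed_by_rule={k: v for k, v in removed.items() if v},
        n_individuals_removed=n_ind_removed,
    )
    logger.info("QC: %d/%d SNPs retained, %d individuals removed (%s)",
                report.n_snps_out, m, n_ind_removed, report.removed_by_rule or "no SNP removals")
    return out, report


def compute_regressors(G: PhasedGenotypeMatrix, impute: bool = False) -> RegressorSet:
    """Build the A, D, I regressor matrices from parental-origin probabilities.

    Requires complete data; with ``impute=True`` missing entries are filled
    with the column means of P1 and P2 (a convenience fallback — proper
    pedigree-based imputation is expected upstream).
    """
    P1, P2 = G.P1, G.P2
    if G.missing_mask.any():
        if not impute:
            raise ValueError(
                "missing genotype entries present: impute upstream, drop the "
                "individuals/SNPs in QC, or pass impute=True for mean imputation"
            )
        P1 = P1.copy()
        P2 = P2.copy()
        for j in range(G.n_snps):
            miss = G.missing_mask[:, j]
            if miss.any():
                if miss.all():
                    raise ValueError(f"all calls missing at SNP index {j}")
                P1[miss, j] = P1[~miss, j].mean()
                P2[miss, j] = P2[~miss, j].mean()
    A = P1 + P2 - 1.0
    I = P1 - P2
    D = np.abs(I)
    return RegressorSet(A=A, D=D, I=I, snps=list(G.snps), individuals=list(G.individuals))
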