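"""Reading and writing the pipeline's file formats.

Formats:

* **Phased VCF** (VCFv4.2, GT only). Convention: the left allele of each
  phased ``a|b`` genotype is paternal; the ALT allele is the counted allele,
  so ``1|0`` means the counted allele came from the father (P1=1, P2=0).
  Unphased genotypes are an error (parental origin undefined); ``./.`` is
  missing. Hard calls only — probabilistic phase goes in the TSV form.
* **Probability TSV**: long table with columns individual_id, snp_id, P1, P2
  (values in [0,1], written to 6 decimals) — the lossless representation of
  pedigree-phasing output.
* **SNP map TSV**: snp_id, chromosome, position_bp, counted_allele,
  other_allele.
* **Phenotype TSV**: individual_id, phenotype[, litter_id].
* **Chain TSV**: one row per saved MCMC iteration with '#'-prefixed metadata.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .gibbs import ChainSamples
from .regressors import PhasedGenotypeMatrix, QCReport, SNPInfo


# ---------------------------------------------------------------- phased VCF

def write_phased_vcf(G: PhasedGenotypeMatrix, path: str) -> None:
    """Write hard-call phased genotypes as VCF. Every non-missing P1/P2 entry
    must be exactly 0 or 1 (use the probability TSV for soft calls)."""
    valid = ~G.missing_mask
    vals = np.concatenate([G.P1[valid], G.P2[valid]])
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("VCF output requires hard calls (P1, P2 in {0, 1}); "
                         "write the probability TSV instead")
    contigs: dict[str, None] = {}
    for s in G.snps:
        contigs.setdefault(s.chromosome, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=imprintvar\n")
        fh.write("##phasing=full;convention=left_allele_paternal\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.individuals) + "\n")
        for j, s in enumerate(G.snps):
            gts = []
            for i in range(G.n_individuals):
                if G.missing_mask[i, j]:
                    gts.append(".|.")
                else:
                    gts.append(f"{int(G.P1[i, j])}|{int(G.P2[i, j])}")
            fh.write(f"{s.chromosome}\t{s.position_bp}\t{s.snp_id}\t{s.allele_other}\t"
                     f"{s.allele_counted}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def read_phased_vcf(path: str) -> PhasedGenotypeMatrix:
    """Read a phased VCF into parental-origin probabilities. The ALT allele
    is the counted allele; the left allele of each ``a|b`` call is paternal."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    snps: list[SNPInfo] = []
    p1_rows, p2_rows, miss_rows = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"SNP {rec.ID or rec.POS}: multi-allelic records unsupported")
        p1 = np.zeros(len(individuals))
        p2 = np.zeros(len(individuals))
        miss = np.zeros(len(individuals), dtype=bool)
        for i, gt in enumerate(rec.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                miss[i] = True
                continue
            if not phased:
                raise ValueError(
                    f"unphased genotype at record {rec.CHROM}:{rec.POS} "
                    f"({rec.ID or '.'}) sample {individuals[i]}: parental origin undefined")
            p1[i] = float(a)
            p2[i] = float(b)
        snps.append(SNPInfo(snp_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                            chromosome=str(rec.CHROM), position_bp=int(rec.POS),
                            allele_counted=rec.ALT[0], allele_other=rec.REF))
        p1_rows.append(p1)
        p2_rows.append(p2)
        miss_rows.append(miss)
    G = PhasedGenotypeMatrix(individuals, snps, np.array(p1_rows).T,
                             np.array(p2_rows).T, np.array(miss_rows).T)
    return G.with_frequencies()


# ----------------------------------------------------------- probability TSV

def write_prob_tsv(G: PhasedGenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tsnp_id\tP1\tP2\n")
        for i, ind in enumerate(G.individuals):
            for j, s in enumerate(G.snps):
                if G.missing_mask[i, j]:
                    fh.write(f"{ind}\t{s.snp_id}\tNA\tNA\n")
                else:
                    fh.write(f"{ind}\t{s.snp_id}\t{G.P1[i, j]:.6f}\t{G.P2[i, j]:.6f}\n")


def read_prob_tsv(path: str, map_path: str | None = None) -> PhasedGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "snp_id": str},
                     na_values=["NA"], comment="#")
    individuals = list(dict.fromkeys(df["individual_id"]))
    snp_ids = list(dict.fromkeys(df["snp_id"]))
    ind_idx = {v: k for k, v in enumerate(individuals)}
    snp_idx = {v: k for k, v in enumerate(snp_ids)}
    n, m = len(individuals), len(snp_ids)
    P1 = np.zeros((n, m))
    P2 = np.zeros((n, m))
    miss = np.ones((n, m), dtype=bool)
    rows = df["individual_id"].map(ind_idx).to_numpy()
    cols = df["snp_id"].map(snp_idx).to_numpy()
    p1v = df["P1"].to_numpy(dtype=float)
    p2v = df["P2"].to_numpy(dtype=float)
    ok = ~(np.isnan(p1v) | np.isnan(p2v))
    P1[rows[ok], cols[ok]] = p1v[ok]
    P2[rows[ok], cols[ok]] = p2v[ok]
    miss[rows[ok], cols[ok]] = False
    if map_path is not None:
        snp_map = {s.snp_id: s for s in read_snp_map(map_path)}
        snps = []
        for sid in snp_ids:
            if sid not in snp_map:
                raise ValueError(f"SNP {sid!r} missing from map file")
            snps.append(snp_map[sid])
    else:
        snps = [SNPInfo(snp_id=sid, chromosome="NA", position_bp=0) for sid in snp_ids]
    G = PhasedGenotypeMatrix(individuals, snps, P1, P2, miss)
    return G.with_frequencies()


# ------------------------------------------------------------------- SNP map

def write_snp_map(snps: list[SNPInfo], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchromosome\tposition_bp\tcounted_allele\tother_allele\n")
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.chromosome}\t{s.position_bp}\t"
                     f"{s.allele_counted}\t{s.allele_other}\n")


def read_snp_map(path: str) -> list[SNPInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return [SNPInfo(snp_id=r.snp_id, chromosome=r.chromosome,
                    position_bp=int(r.position_bp), allele_counted=r.counted_allele,
                    allele_other=r.other_allele)
            for r in df.itertuples()]


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(individuals: list[str], phenotypes: np.ndarray, path: str,
                     litter: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        cols = "individual_id\tphenotype" + ("\tlitter_id" if litter is not None else "")
        fh.write(cols + "\n")
        for i, ind in enumerate(individuals):
            row = f"{ind}\t{phenotypes[i]:.8f}"
            if litter is not None:
                row += f"\t{litter[i]}"
            fh.write(row + "\n")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual_id": str}, comment="#")


# ------------------------------------------------------------------ QC / misc

def write_qc_report(report: QCReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rule\tcount\n")
        fh.write(f"snps_in\t{report.n_snps_in}\n")
        fh.write(f"snps_out\t{report.n_snps_out}\n")
        for rule, count in report.removed_by_rule.items():
            fh.write(f"removed_{rule}\t{count}\n")
        fh.write(f"individuals_removed\t{report.n_individuals_removed}\n")


def write_truth(qtls, snps: list[SNPInfo], path: str) -> None:
    """Record the simulated QTL (index, type, effects, frequency) for harnesses."""
    with open(path, "w") as fh:
        fh.write("snp_id\tsnp_index\tqtl_type\ta\td\ti\tp\ttarget_variance\n")
        for q in qtls:
            s = snps[q.snp_index]
            fh.write(f"{s.snp_id}\t{q.snp_index}\t{q.qtl_type}\t{q.a:.8f}\t{q.d:.8f}\t"
                     f"{q.i:.8f}\t{s.p:.6f}\t{q.target_variance}\n")


# -------------------------------------------------------------- chain samples

def write_chain(chain: ChainSamples, directory: str, metadata: dict | None = None) -> None:
    os.makedirs(directory, exist_ok=True)
    header = [f"# model={chain.spec.name}",
              f"# chain_length={chain.spec.chain_length}",
              f"# burn_in={chain.spec.burn_in}",
              f"# thin={chain.spec.thin}",
              f"# seed={chain.spec.seed}"]
    for k, v in (metadata or {}).items():
        header.append(f"# {k}={v}")
    path = os.path.join(directory, "chain_samples.tsv")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        chain.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")
    for comp, draws in (chain.effect_draws or {}).items():
        np.savetxt(os.path.join(directory, f"effects_{comp}.tsv"), draws,
                   delimiter="\t", fmt="%.10g")


def read_chain_frame(directory: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(directory, "chain_samples.tsv"),
                       sep="\t", comment="#")
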