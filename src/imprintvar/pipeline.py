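"""End-to-end pipeline: QC -> regressors -> fit each model -> partition -> compare.

Every output table carries a '#'-prefixed metadata header recording the
package version, the seed and a hash of the configuration, so a run is
reproducible and self-describing. Given the same config and seed the chain
sample files are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__, io
from .dic import compare_models, compute_dic
from .gibbs import ModelSpec, fit_model
from .partition import (chromosome_length_regression, explained_variance,
                        per_chromosome_variance)
from .regressors import compute_regressors, qc_filter

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str                       # phased VCF or probability TSV
    phenotypes: str
    out_dir: str
    snp_map: str | None = None           # required with a probability TSV
    litter_col: str | None = None
    models: tuple[str, ...] = ("MA", "MAD", "MADI")
    chain_length: int = 100_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 1
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_chisq_max: float = 600.0
    indiv_missing_max: float = 0.05
    per_chromosome: bool = True
    store_effects: bool = True
    impute: bool = False

    def validate(self) -> None:
        for label, p in (("genotypes", self.genotypes), ("phenotypes", self.phenotypes)):
            if not os.path.exists(p):
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.snp_map is not None and not os.path.exists(self.snp_map):
            raise FileNotFoundError(f"snp_map path does not exist: {self.snp_map}")

    def config_hash(self) -> str:
        # out_dir is excluded: the hash identifies the analysis, not its destination
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _load_genotypes(config: RunConfig):
    if config.genotypes.endswith((".vcf", ".vcf.gz")):
        return io.read_phased_vcf(config.genotypes)
    return io.read_prob_tsv(config.genotypes, config.snp_map)


def _header(config: RunConfig) -> str:
    return (f"# imprintvar={__version__} seed={config.seed} "
            f"config_hash={config.config_hash()}\n")


def _write_table(df, path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> str:
    """Run the full analysis described by ``config``; returns the artifact
    directory. Stage errors propagate with the stage named."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    try:
        G = _load_genotypes(config)
    except Exception as err:
        raise RuntimeError(f"stage 'read genotypes' failed on {config.genotypes}: {err}") from err

    try:
        G, report = qc_filter(G, config.call_rate_min, config.maf_min,
                              config.hwe_chisq_max, config.indiv_missing_max)
        io.write_qc_report(report, os.path.join(config.out_dir, "qc_report.tsv"))
        R = compute_regressors(G, impute=config.impute)
    except Exception as err:
        raise RuntimeError(f"stage 'qc/regressors' failed: {err}") from err

    pheno = io.read_phenotypes(config.phenotypes)
    pheno = pheno.set_index("individual_id").loc[G.individuals].reset_index()
    y = pheno["phenotype"].to_numpy(dtype=float)
    litter = None
    if config.litter_col is not None:
        litter = pheno[config.litter_col].tolist()

    dics = {}
    last_chain = None
    for model in config.models:
        spec = ModelSpec.from_name(
            model, chain_length=config.chain_length, burn_in=config.burn_in,
            thin=config.thin, seed=config.seed, use_litter=litter is not None,
            store_effects=config.store_effects)
        try:
            chain = fit_model(y, R, spec, litter=litter)
        except Exception as err:
            raise RuntimeError(f"stage 'fit {model}' failed: {err}") from err
        model_dir = os.path.join(config.out_dir, model)
        io.write_chain(chain, model_dir,
                       metadata={"imprintvar": __version__,
                                 "config_hash": config.config_hash(),
                                 "n_individuals": R.n_individuals,
                                 "n_snps": R.n_snps})
        est = explained_variance(chain)
        _write_table(est.to_frame(), os.path.join(model_dir, "variance_table.tsv"), config)
        dics[model] = compute_dic(chain, y, R)
        last_chain = chain

    if config.per_chromosome and last_chain is not None and config.store_effects:
        try:
            part = per_chromosome_variance(last_chain, R)
            _write_table(part.table, os.path.join(config.out_dir, "per_chromosome.tsv"), config)
            rows = []
            for comp in part.components:
                try:
                    slope, intercept, r2 = chromosome_length_regression(part, comp)
                except ValueError as err:
                    logger.warning("length regression skipped for %s: %s", comp, err)
                    continue
                rows.append({"component": comp, "slope": slope,
                             "intercept": intercept, "r2": r2})
            if rows:
                import pandas as pd
                _write_table(pd.DataFrame(rows),
                             os.path.join(config.out_dir, "length_regression.tsv"), config)
        except Exception as err:
            raise RuntimeError(f"stage 'partition' failed: {err}") from err

    if len(dics) > 1:
        _write_table(compare_models(dics), os.path.join(config.out_dir, "dic_table.tsv"),
                     config)
    logger.info("pipeline complete: %s", config.out_dir)
    return config.out_dir
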