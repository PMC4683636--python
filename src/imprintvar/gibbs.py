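"""Bayesian random-regression on SNP genotypes: the MA / MAD / MADI models.

The model for a vector of (pre-adjusted) phenotypes y is

    y = 1 mu + (L b) + A a + D d + I i + e

with A, D, I the additive / dominance / imprinting regressor matrices,
a ~ N(0, I sig2_a), d ~ N(0, I sig2_d), i ~ N(0, I sig2_i) per-SNP effects,
optional common-litter effects b ~ N(0, I sig2_L) and residuals
e ~ N(0, I sig2_e). MA fits only the additive term, MAD adds dominance, MADI
adds imprinting. Priors on the mean and effects are flat; variance priors are
unbounded uniform, so the posterior is proportional to the likelihood.

The chain starts with all location parameters at zero and all variances at 1,
and runs single-site Gibbs updates with maintained residuals (the stationary
distribution is the full posterior regardless of the update blocking). Each
saved iteration records the variance parameters and the explained variances
var(Aa), var(Dd), var(Ii) — the sample variance of each genotypic-value
vector — from which heritability ratios are formed downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .regressors import RegressorSet

logger = logging.getLogger(__name__)

MODEL_NAMES = {"MA": ("additive",),
               "MAD": ("additive", "dominance"),
               "MADI": ("additive", "dominance", "imprinting")}
COMPONENT_ORDER = ("additive", "dominance", "imprinting")


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components to fit and how to run the chain.

    The component sets form a hierarchy: additive is always included and
    imprinting requires dominance (MA ⊂ MAD ⊂ MADI). ``init_variances`` maps
    {'additive','dominance','imprinting','litter','residual'} to starting
    values (default 1.0); with ``update_variances=False`` they stay fixed,
    which turns the sampler into a ridge/BLUP-style conditional sampler used
    by the correctness oracle.
    """

    components: tuple[str, ...] = COMPONENT_ORDER
    use_litter: bool = False
    chain_length: int = 100_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 1
    update_variances: bool = True
    store_effects: bool = False
    init_variances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if "additive" not in comps:
            raise ValueError("the additive component is always included")
        if "imprinting" in comps and "dominance" not in comps:
            raise ValueError("imprinting requires dominance (model hierarchy MA ⊂ MAD ⊂ MADI)")
        if any(c not in COMPONENT_ORDER for c in comps):
            raise ValueError(f"unknown components in {comps}")
        object.__setattr__(self, "components",
                           tuple(c for c in COMPONENT_ORDER if c in comps))
        if not (0 <= self.burn_in < self.chain_length):
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "ModelSpec":
        try:
            comps = MODEL_NAMES[name.upper()]
        except KeyError:
            raise ValueError(f"unknown model {name!r}; expected MA, MAD or MADI") from None
        return cls(components=comps, **kwargs)

    @property
    def name(self) -> str:
        for nm, comps in MODEL_NAMES.items():
            if comps == self.components:
                return nm
        return "+".join(self.components)

    @property
    def n_saved(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin


@dataclass
class ChainSamples:
    """Saved MCMC draws of variance components and explained variances."""

    spec: ModelSpec
    sigma2_a: np.ndarray
    sigma2_d: np.ndarray
    sigma2_i: np.ndarray
    sigma2_L: np.ndarray
    sigma2_e: np.ndarray
    var_Aa: np.ndarray
    var_Dd: np.ndarray
    var_Ii: np.ndarray
    var_L: np.ndarray
    deviance: np.ndarray
    mu: np.ndarray
    # posterior means of location parameters (accumulated over saved draws)
    post_mean_mu: float
    post_mean_effects: dict  # component -> vector of per-SNP posterior means
    post_mean_b: np.ndarray | None
    # optional full effect draws, component -> (n_saved, m)
    effect_draws: dict | None
    b_draws: np.ndarray | None
    final_residual: np.ndarray
    # final sweep state, kept for the residual-maintenance guard
    final_effects: dict | None = None
    final_mu: float = 0.0
    final_b: np.ndarray | None = None
    litter_index: np.ndarray | None = None

    @property
    def n_saved(self) -> int:
        return self.sigma2_e.shape[0]

    @property
    def sigma2_P(self) -> np.ndarray:
        """Per-iteration total phenotypic variance: sum of the included
        explained variances, the litter variance and the residual variance."""
        return self.var_Aa + self.var_Dd + self.var_Ii + self.var_L + self.sigma2_e

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "sigma2_a": self.sigma2_a, "sigma2_d": self.sigma2_d,
            "sigma2_i": self.sigma2_i, "sigma2_L": self.sigma2_L,
            "sigma2_e": self.sigma2_e, "var_Aa": self.var_Aa,
            "var_Dd": self.var_Dd, "var_Ii": self.var_Ii, "var_L": self.var_L,
            "sigma2_P": self.sigma2_P, "deviance": self.deviance, "mu": self.mu,
        })


def _encode_litters(litter) -> tuple[np.ndarray, int]:
    labels = list(litter)
    uniq: dict = {}
    for lab in labels:
        uniq.setdefault(lab, len(uniq))
    idx = np.array([uniq[lab] for lab in labels], dtype=np.int64)
    return idx, len(uniq)


def fit_model(y: np.ndarray, R: RegressorSet, spec: ModelSpec,
              litter=None) -> ChainSamples:
    """Fit one of the MA/MAD/MADI models by Gibbs sampling.

    Parameters
    ----------
    y : phenotype vector (pre-adjusted for fixed effects), length n.
    R : regressor set built by :func:`imprintvar.regressors.compute_regressors`.
    spec : chain and model settings.
    litter : optional per-individual litter labels; fits the common-litter
        random intercept when given and ``spec.use_litter`` is True (or when
        labels are supplied at all).
    """
    y = np.asarray(y, dtype=np.float64)
    n = R.n_individuals
    if y.shape != (n,):
        raise ValueError(f"phenotype length {y.shape} does not match {n} individuals")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values present")

    mats = {"additive": R.A, "dominance": R.D, "imprinting": R.I}
    comps = spec.components
    blocks = []
    groups = []
    for gi, comp in enumerate(COMPONENT_ORDER):
        if comp in comps:
            Xc = mats[comp]
            col_var = Xc.var(axis=0)
            zero = np.flatnonzero(col_var == 0.0)
            if zero.size:
                raise ValueError(
                    f"zero-variance {comp} regressor column at SNP "
                    f"{R.snps[zero[0]].snp_id!r}: QC should have removed it")
            blocks.append(Xc)
            groups.append(np.full(Xc.shape[1], gi, dtype=np.int64))
    X = np.asfortranarray(np.concatenate(blocks, axis=1))
    group = np.concatenate(groups)
    m = X.shape[1]
    if spec.update_variances:
        counts = np.bincount(group, minlength=3)
        for gi, comp in enumerate(COMPONENT_ORDER):
            if comp in comps and counts[gi] <= 2:
                raise ValueError(
                    f"improper conditional; too few {comp} effects ({counts[gi]} <= 2)")
        if n <= 2:
            raise ValueError("improper residual conditional; need n > 2")
    colsq = np.einsum("ij,ij->j", X, X)

    if litter is not None:
        litter_idx, n_litters = _encode_litters(litter)
        if litter_idx.shape[0] != n:
            raise ValueError("litter labels length does not match phenotypes")
        if spec.update_variances and n_litters <= 2:
            raise ValueError("improper conditional; too few litters (<= 2)")
    else:
        litter_idx, n_litters = np.zeros(1, dtype=np.int64), 0

    iv = spec.init_variances
    sig2_init = np.array([iv.get("additive", 1.0), iv.get("dominance", 1.0),
                          iv.get("imprinting", 1.0)], dtype=np.float64)
    sig2_L0 = float(iv.get("litter", 1.0))
    sig2_e0 = float(iv.get("residual", 1.0))

    (samples, mu_save, b_save, eff, beta_sum, mu_sum, b_sum, r_final,
     beta_final, mu_final, b_final) = _kernels.run_chain(
        y, X, group, colsq, litter_idx, n_litters,
        spec.chain_length, spec.burn_in, spec.thin, spec.seed,
        sig2_init, sig2_L0, sig2_e0,
        spec.update_variances, spec.store_effects)

    n_saved = samples.shape[0]
    if n_saved == 0:
        raise ValueError("chain settings leave no saved iterations")
    if np.any(samples[:, :5] <= _kernels.VARIANCE_FLOOR):
        logger.warning("variance floor %g hit during sampling", _kernels.VARIANCE_FLOOR)

    beta_mean = beta_sum / n_saved
    post_effects = {comp: beta_mean[group == gi]
                    for gi, comp in enumerate(COMPONENT_ORDER) if comp in comps}
    effect_draws = None
    if spec.store_effects:
        effect_draws = {comp: np.ascontiguousarray(eff[:, group == gi])
                        for gi, comp in enumerate(COMPONENT_ORDER) if comp in comps}

    return ChainSamples(
        spec=spec,
        sigma2_a=samples[:, 0].copy(), sigma2_d=samples[:, 1].copy(),
        sigma2_i=samples[:, 2].copy(),
        sigma2_L=samples[:, 3].copy() if n_litters else np.zeros(n_saved),
        sigma2_e=samples[:, 4].copy(),
        var_Aa=samples[:, 5].copy(), var_Dd=samples[:, 6].copy(),
        var_Ii=samples[:, 7].copy(),
        var_L=samples[:, 8].copy(),
        deviance=samples[:, 9].copy(),
        mu=mu_save.copy(),
        post_mean_mu=float(mu_sum / n_saved),
        post_mean_effects=post_effects,
        post_mean_b=(b_sum / n_saved) if n_litters else None,
        effect_draws=effect_draws,
        b_draws=b_save.copy() if n_litters else None,
        final_residual=r_final.copy(),
        final_effects={comp: beta_final[group == gi]
                       for gi, comp in enumerate(COMPONENT_ORDER) if comp in comps},
        final_mu=float(mu_final),
        final_b=b_final.copy() if n_litters else None,
        litter_index=litter_idx if n_litters else None,
    )


def sample_variance(sum_sq: float, count: int,
                    rng: np.random.Generator | None = None) -> float:
    """One draw of sigma^2 = sum_sq / chisq(count - 2), the scaled
    inverse-chi-square full conditional under a flat prior on the variance.
    Proper only for count > 2; floored at 1e-12."""
    if count <= 2:
        raise ValueError("improper conditional; too few effects")
    if rng is None:
        rng = np.random.default_rng()
    draw = sum_sq / rng.chisquare(count - 2)
    if draw < _kernels.VARIANCE_FLOOR:
        logger.debug("variance draw floored at %g", _kernels.VARIANCE_FLOOR)
        return _kernels.VARIANCE_FLOOR
    return draw


def gaussian_deviance(sse: float, sigma2_e: float, n: int) -> float:
    """-2 x Gaussian log-likelihood conditional on the location effects:
    D = n log(2 pi sigma2_e) + SSE / sigma2_e."""
    if sigma2_e <= 0:
        raise ValueError("sigma2_e must be positive")
    return n * math.log(2.0 * math.pi * sigma2_e) + sse / sigma2_e


def refreshed_residual(y: np.ndarray, R: RegressorSet, chain: ChainSamples,
                       effects: dict, mu: float, b: np.ndarray | None = None) -> np.ndarray:
    """Recompute y - 1 mu - Lb - A a - D d - I i from scratch (the guard used
    to validate the kernel's maintained residual)."""
    mats = {"additive": R.A, "dominance": R.D, "imprinting": R.I}
    r = y - mu
    for comp, eff in effects.items():
        r = r - mats[comp] @ eff
    if b is not None and chain.litter_index is not None:
        r = r - b[chain.litter_index]
    return r
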