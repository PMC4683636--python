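"""Deviance Information Criterion for fitted chains and MA/MAD/MADI ranking.

DIC = D_bar + p_D where D_bar is the posterior mean deviance over saved
iterations and p_D = D_bar - D_hat is the effective number of parameters,
with D_hat the deviance evaluated at posterior means. The focus here is the
conditional DIC: deviance is conditional on the location parameters
(mu, litter effects, SNP effects), evaluated at their posterior means and at
the posterior mean residual variance. Lower DIC indicates the better-fitting
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import ChainSamples, gaussian_deviance
from .regressors import RegressorSet


@dataclass
class DICResult:
    D_bar: float
    D_hat: float

    @property
    def p_D(self) -> float:
        return self.D_bar - self.D_hat

    @property
    def DIC(self) -> float:
        return self.D_bar + self.p_D  # == 2 * D_bar - D_hat


def compute_dic(chain: ChainSamples, y: np.ndarray, R: RegressorSet) -> DICResult:
    """DIC from a chain's saved deviances and posterior-mean parameters.

    D_hat plugs the posterior means of mu, the litter effects and the SNP
    effects into the fitted values and uses the posterior mean of sigma2_e.
    """
    if chain.deviance.size == 0:
        raise ValueError("chain has no stored deviance trace")
    y = np.asarray(y, dtype=float)
    D_bar = float(chain.deviance.mean())
    mats = {"additive": R.A, "dominance": R.D, "imprinting": R.I}
    fitted = np.full(y.shape, chain.post_mean_mu)
    for comp, eff in chain.post_mean_effects.items():
        fitted = fitted + mats[comp] @ eff
    if chain.post_mean_b is not None and chain.litter_index is not None:
        fitted = fitted + chain.post_mean_b[chain.litter_index]
    sse = float(np.sum((y - fitted) ** 2))
    sigma2_e_bar = float(chain.sigma2_e.mean())
    D_hat = gaussian_deviance(sse, sigma2_e_bar, y.shape[0])
    result = DICResult(D_bar=D_bar, D_hat=D_hat)
    if result.p_D < 0:
        warnings.warn(f"negative effective number of parameters (p_D={result.p_D:.3f})",
                      RuntimeWarning, stacklevel=2)
    return result


def compare_models(results: dict) -> pd.DataFrame:
    """Rank fitted models by DIC (lowest = best). ``results`` maps model
    names to DICResult; returns a table with the winner flagged."""
    if not results:
        raise ValueError("no models to compare")
    rows = [{"model": name, "D_bar": r.D_bar, "D_hat": r.D_hat,
             "p_D": r.p_D, "DIC": r.DIC} for name, r in results.items()]
    table = pd.DataFrame(rows).sort_values("DIC", kind="stable").reset_index(drop=True)
    table["best"] = [i == 0 for i in range(len(table))]
    return table
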