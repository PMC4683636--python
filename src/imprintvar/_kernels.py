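"""Numba inner loops for the single-site Gibbs sampler.

The kernel maintains the residual vector r = y - 1*mu - Lb - X*beta across
sweeps so each SNP update costs O(n): restore the SNP's contribution via its
precomputed column norm, draw from the normal full conditional, subtract the
new contribution. Variance parameters get scaled inverse-chi-square draws
sigma^2 = SS / chisq(count - 2), the conditional under a flat prior on the
variance. All randomness comes from numba's internal RNG seeded once per call.
"""

import numpy as np
from numba import njit

VARIANCE_FLOOR = 1e-12


@njit(cache=True, fastmath=True)
def run_chain(y, X, group, colsq, litter, n_litters,
              n_iter, burn_in, thin, seed,
              sig2_init, sig2_L_init, sig2_e_init,
              update_variances, store_effects):
    """Run one Gibbs chain; see gibbs.fit_model for the user-facing contract.

    Returns (samples, mu_save, b_save, eff, beta_sum, mu_sum, b_sum, r, beta,
    mu, b) — the last four being the final sweep's maintained residual and
    location state. samples has one row per saved iteration with columns
    [sig2_a, sig2_d, sig2_i, sig2_L, sig2_e, var_Aa, var_Dd, var_Ii, var_L,
    deviance].
    """
    n = y.shape[0]
    m = X.shape[1]
    np.random.seed(seed)

    mg = np.zeros(3, dtype=np.int64)
    for j in range(m):
        mg[group[j]] += 1

    litter_size = np.zeros(max(n_litters, 1), dtype=np.int64)
    if n_litters > 0:
        for i in range(n):
            litter_size[litter[i]] += 1

    beta = np.zeros(m)
    mu = 0.0
    b = np.zeros(max(n_litters, 1))
    sig2 = sig2_init.copy()
    sig2_L = sig2_L_init
    sig2_e = sig2_e_init

    r = y.copy()  # all location parameters start at zero

    n_saved = (n_iter - burn_in) // thin
    samples = np.zeros((n_saved, 10))
    mu_save = np.zeros(n_saved)
    b_save = np.zeros((n_saved, max(n_litters, 1)))
    if store_effects:
        eff = np.zeros((n_saved, m))
    else:
        eff = np.zeros((1, 1))
    beta_sum = np.zeros(m)
    mu_sum = 0.0
    b_sum = np.zeros(max(n_litters, 1))

    gval = np.zeros((3, n))
    bsum_restored = np.zeros(max(n_litters, 1))

    isave = 0
    for it in range(n_iter):
        # --- mean (flat prior) ---
        s = 0.0
        for i in range(n):
            s += r[i]
        mean_mu = s / n + mu
        mu_new = mean_mu + np.sqrt(sig2_e / n) * np.random.standard_normal()
        delta = mu_new - mu
        for i in range(n):
            r[i] -= delta
        mu = mu_new

        # --- litter effects ---
        if n_litters > 0:
            for l in range(n_litters):
                bsum_restored[l] = litter_size[l] * b[l]
            for i in range(n):
                bsum_restored[litter[i]] += r[i]
            lam_L = sig2_e / sig2_L
            for l in range(n_litters):
                denom = litter_size[l] + lam_L
                mean_b = bsum_restored[l] / denom
                b_new = mean_b + np.sqrt(sig2_e / denom) * np.random.standard_normal()
                bsum_restored[l] = b_new - b[l]  # reuse as delta
                b[l] = b_new
            for i in range(n):
                r[i] -= bsum_restored[litter[i]]

        # --- SNP effects, one component group at a time via the group array ---
        for j in range(m):
            g = group[j]
            old = beta[j]
            xj = X[:, j]
            dot = 0.0
            for i in range(n):
                dot += xj[i] * r[i]
            dot += colsq[j] * old
            lam = sig2_e / sig2[g]
            denom = colsq[j] + lam
            mean_j = dot / denom
            new = mean_j + np.sqrt(sig2_e / denom) * np.random.standard_normal()
            diff = new - old
            for i in range(n):
                r[i] -= diff * xj[i]
            beta[j] = new

        # --- variance parameters ---
        if update_variances:
            ss0 = 0.0
            ss1 = 0.0
            ss2 = 0.0
            for j in range(m):
                g = group[j]
                if g == 0:
                    ss0 += beta[j] * beta[j]
                elif g == 1:
                    ss1 += beta[j] * beta[j]
                else:
                    ss2 += beta[j] * beta[j]
            if mg[0] > 2:
                sig2[0] = max(ss0 / np.random.chisquare(mg[0] - 2), VARIANCE_FLOOR)
            if mg[1] > 2:
                sig2[1] = max(ss1 / np.random.chisquare(mg[1] - 2), VARIANCE_FLOOR)
            if mg[2] > 2:
                sig2[2] = max(ss2 / np.random.chisquare(mg[2] - 2), VARIANCE_FLOOR)
            if n_litters > 2:
                ssb = 0.0
                for l in range(n_litters):
                    ssb += b[l] * b[l]
                sig2_L = max(ssb / np.random.chisquare(n_litters - 2), VARIANCE_FLOOR)
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            sig2_e = max(sse / np.random.chisquare(n - 2), VARIANCE_FLOOR)

        # --- record ---
        if it >= burn_in and (it - burn_in) % thin == 0:
            for g in range(3):
                for i in range(n):
                    gval[g, i] = 0.0
            for j in range(m):
                g = group[j]
                bj = beta[j]
                xj = X[:, j]
                for i in range(n):
                    gval[g, i] += bj * xj[i]
            for g in range(3):
                msum = 0.0
                for i in range(n):
                    msum += gval[g, i]
                msum /= n
                v = 0.0
                for i in range(n):
                    dv = gval[g, i] - msum
                    v += dv * dv
                samples[isave, 5 + g] = v / n
            if n_litters > 0:
                msum = 0.0
                for i in range(n):
                    msum += b[litter[i]]
                msum /= n
                v = 0.0
                for i in range(n):
                    dv = b[litter[i]] - msum
                    v += dv * dv
                samples[isave, 8] = v / n
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            samples[isave, 0] = sig2[0]
            samples[isave, 1] = sig2[1]
            samples[isave, 2] = sig2[2]
            samples[isave, 3] = sig2_L
            samples[isave, 4] = sig2_e
            samples[isave, 9] = n * np.log(2.0 * np.pi * sig2_e) + sse / sig2_e
            mu_save[isave] = mu
            for l in range(b.shape[0]):
                b_save[isave, l] = b[l]
            if store_effects:
                for j in range(m):
                    eff[isave, j] = beta[j]
            beta_sum += beta
            mu_sum += mu
            b_sum += b
            isave += 1

    return samples, mu_save, b_save, eff, beta_sum, mu_sum, b_sum, r, beta, mu, b
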