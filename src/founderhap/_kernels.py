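"""Numba inner loops for the whole-genome regression models.

Both samplers operate on a column-contiguous design matrix and maintain
the residual vector incrementally; the MCMC kernel additionally samples a
polygenic effect in the eigenbasis of the genomic relationship matrix,
where its conditional distribution factorizes into independent normals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG_CLIP = 500.0


@njit(cache=True)
def _sigmoid(z):
    if z > _LOG_CLIP:
        return 1.0
    if z < -_LOG_CLIP:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


@njit(cache=True)
def em_bayesb_kernel(X, y, gamma, sig_nodes, tol, max_iter):
    """Mean-field EM for the spike-and-slab (BayesB) regression with the
    effect variance integrated out.

    The scaled-inv-chi-square(v, S) prior on each effect variance makes
    the slab marginal heavy-tailed (Student-t with v df; near-Cauchy at
    v = 1), which is what lets strong effects through while borderline
    ones shrink partially.  A point estimate of sigma_j^2 loses that tail
    and collapses the fit, so the slab is handled as a discrete mixture
    over ``sig_nodes`` — equal-probability quantile nodes of the prior —
    and each column's E-step averages the conditional posterior over the
    mixture.  Per-column updates of q(gamma_j, b_j) are exact coordinate
    ascent given the nodes; intercept and residual variance (E[RSS]/n)
    get exact block updates.  Deterministic: effects start at 0, residual
    variance at var(y).  The objective trace is the residual
    log-likelihood term of the bound.  X should be Fortran-ordered.
    """
    n, p = X.shape
    K = sig_nodes.shape[0]
    d = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        d[j] = acc
    theta = np.zeros(p)  # w_j * E[b_j | included], the working effect
    b = np.zeros(p)  # E[b_j | included]
    bvar = np.zeros(p)  # Var[b_j | included]
    w = np.zeros(p)  # E[gamma_j]
    mu = y.mean()
    r = y - mu
    sige = max(np.dot(r, r) / n, 1e-10)
    obj = np.empty(max_iter)
    log_odds_prior = math.log(gamma / (1.0 - gamma)) if gamma < 1.0 else _LOG_CLIP
    logK = math.log(K)
    lrk = np.empty(K)
    n_iter = 0
    converged = False
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            if d[j] <= 0.0:
                continue
            s = d[j] * theta[j]
            for i in range(n):
                s += X[i, j] * r[i]
            # mixture over the slab-variance prior nodes
            lmax = -1e300
            for k in range(K):
                tau = sige + sig_nodes[k] * d[j]
                lrk[k] = 0.5 * math.log(sige / tau) + 0.5 * s * s * sig_nodes[k] / (sige * tau)
                if lrk[k] > lmax:
                    lmax = lrk[k]
            acc = 0.0
            for k in range(K):
                acc += math.exp(lrk[k] - lmax)
            log_ratio = lmax + math.log(acc) - logK  # log m1/m0
            wj = _sigmoid(log_odds_prior + log_ratio) if gamma < 1.0 else 1.0
            # posterior mean/variance of b given inclusion: mixture average
            eb = 0.0
            eb2 = 0.0
            for k in range(K):
                pk = math.exp(lrk[k] - lmax) / acc
                denom = d[j] + sige / sig_nodes[k]
                bh = s / denom
                eb += pk * bh
                eb2 += pk * (bh * bh + sige / denom)
            tn = wj * eb
            if tn != theta[j]:
                diff = theta[j] - tn
                for i in range(n):
                    r[i] += X[i, j] * diff
                if abs(diff) > delta:
                    delta = abs(diff)
            theta[j] = tn
            b[j] = eb
            bvar[j] = eb2 - eb * eb
            w[j] = wj
        mbar = r.mean()
        mu += mbar
        for i in range(n):
            r[i] -= mbar
        if abs(mbar) > delta:
            delta = abs(mbar)
        rss = np.dot(r, r)
        varsum = 0.0
        for j in range(p):
            varsum += d[j] * (w[j] * (b[j] * b[j] + bvar[j]) - theta[j] * theta[j])
        e_rss = rss + varsum
        sige_new = max(e_rss / n, 1e-12)
        if abs(sige_new - sige) > delta:
            delta = abs(sige_new - sige)
        sige = sige_new
        obj[it] = -0.5 * n * math.log(sige) - 0.5 * e_rss / sige
        n_iter = it + 1
        if delta < tol:
            converged = True
            break
    return mu, w, b, bvar, sige, n_iter, obj[:n_iter], converged


@njit(cache=True)
def bayesb_mcmc_kernel(
    X,
    y,
    Q,
    lam,
    v_beta,
    S_beta2,
    v_e,
    S_e2,
    pi,
    n_cycles,
    burn_in,
    seed,
):
    """Partially collapsed Gibbs sampler for BayesB with a polygenic term.

    Per marker and cycle: effect variance from its conditional (prior when
    excluded), then the inclusion indicator with the effect marginalized
    out, then the effect given inclusion.  The polygenic vector u = Q a is
    sampled componentwise in the eigenbasis (lam holds the positive
    eigenvalues of G); sigma_u^2 gets a flat prior, sigma_e^2 the
    scaled-inv-chi-square(v_e, S_e2) prior.

    Returns (gamma, effect_mean, u_mean, mu_mean, sige_mean, sigu_mean, ok).
    """
    np.random.seed(seed)
    n, p = X.shape
    k = lam.shape[0]
    d = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        d[j] = acc
    vary = np.var(y)
    if vary <= 0.0:
        vary = 1.0
    delta = np.zeros(p, dtype=np.uint8)
    beta = np.zeros(p)
    mu = y.mean()
    u = np.zeros(n)
    r = y - mu
    sige = max(vary / 2.0, 1e-10)
    sigu = max(vary / 4.0, 1e-10)
    log_odds_prior = math.log(pi / (1.0 - pi)) if pi < 1.0 else _LOG_CLIP

    n_keep = n_cycles - burn_in
    gamma_acc = np.zeros(p)
    beta_acc = np.zeros(p)
    u_acc = np.zeros(n)
    mu_acc = 0.0
    sige_acc = 0.0
    sigu_acc = 0.0
    ok = True

    for cyc in range(n_cycles):
        # intercept
        shift = r.mean() + np.random.normal(0.0, math.sqrt(sige / n))
        mu += shift
        for i in range(n):
            r[i] -= shift
        # markers
        for j in range(p):
            if d[j] <= 0.0:
                continue
            bj = beta[j]
            s = d[j] * bj
            for i in range(n):
                s += X[i, j] * r[i]
            if delta[j] == 1:
                sj = (v_beta * S_beta2 + bj * bj) / np.random.chisquare(v_beta + 1.0)
            else:
                sj = v_beta * S_beta2 / np.random.chisquare(v_beta)
            if sj < 1e-12:
                sj = 1e-12
            tau = sige + sj * d[j]
            lr = 0.5 * math.log(sige / tau) + 0.5 * s * s * sj / (sige * tau)
            pj = _sigmoid(log_odds_prior + lr) if pi < 1.0 else 1.0
            if np.random.random() < pj:
                denom = d[j] + sige / sj
                bnew = s / denom + np.random.normal(0.0, math.sqrt(sige / denom))
                delta[j] = 1
            else:
                bnew = 0.0
                delta[j] = 0
            if bnew != bj:
                diff = bj - bnew
                for i in range(n):
                    r[i] += X[i, j] * diff
            beta[j] = bnew
        # polygenic effect in the eigenbasis of G
        if k > 0:
            rwu = r + u
            z = Q.T @ rwu
            a = np.empty(k)
            ss = 0.0
            for i in range(k):
                c = lam[i] * sigu
                m_ = z[i] * c / (c + sige)
                v_ = sige * c / (c + sige)
                a[i] = m_ + np.random.normal(0.0, math.sqrt(v_))
                ss += a[i] * a[i] / lam[i]
            u = Q @ a
            for i in range(n):
                r[i] = rwu[i] - u[i]
            if k > 2:
                sigu = max(ss / np.random.chisquare(k - 2.0), 1e-12)
        # residual variance
        df = n + v_e
        ssr = np.dot(r, r) + v_e * S_e2
        sige = max(ssr / np.random.chisquare(df), 1e-12)
        if not math.isfinite(sige) or sige > 1e12:
            ok = False
            break
        if cyc >= burn_in:
            for j in range(p):
                gamma_acc[j] += delta[j]
                beta_acc[j] += beta[j]
            for i in range(n):
                u_acc[i] += u[i]
            mu_acc += mu
            sige_acc += sige
            sigu_acc += sigu
    if n_keep > 0:
        gamma_acc /= n_keep
        beta_acc /= n_keep
        u_acc /= n_keep
        mu_acc /= n_keep
        sige_acc /= n_keep
        sigu_acc /= n_keep
    return gamma_acc, beta_acc, u_acc, mu_acc, sige_acc, sigu_acc, ok
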