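"""Numba MCMC kernel for the hierarchical drift-diffusion model.

Adaptive random-walk Metropolis-within-Gibbs: subject-level parameters are
updated coordinate-wise against a per-trial log-likelihood cache (only the
trials a coordinate touches are re-evaluated, and only for the proposal);
group means and precisions have prior-only conditionals.  Proposal scales
adapt toward a 0.44 acceptance rate during warmup in batches of 50 sweeps.

Family codes: 0=beta, 1=alpha, 2=delta, 3=ndt.
"""

import math

import numpy as np
from numba import njit

from ._wfpt import logpdf_lower, survivor

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def _log_trunc_z(mu, tau, lo, hi):
    s = 1.0 / math.sqrt(tau)
    z = _norm_cdf((hi - mu) / s) - _norm_cdf((lo - mu) / s)
    if z < 1e-300:
        z = 1e-300
    return math.log(z)


@njit(cache=True)
def _ll_trial(i, b, al, d, nd, rt, choice, win, tol):
    c = choice[i]
    if c < 0:
        s = survivor(win[i] - nd, al, d, b)
        if s <= 0.0:
            return -np.inf
        return math.log(s)
    t = rt[i] - nd
    if t <= 0.0:
        return -np.inf
    if c == 1:
        return logpdf_lower(t, al, -d, 1.0 - b, tol)
    return logpdf_lower(t, al, d, b, tol)


@njit(cache=True)
def total_loglik(starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol):
    """Data log-likelihood at one parameter configuration."""
    J = starts.shape[0] - 1
    s = 0.0
    for j in range(J):
        for i in range(starts[j], starts[j + 1]):
            ll = _ll_trial(i, B[j, cb[i]], A[j, ca[i]], D[j, cd[i]], N[j, cn[i]],
                           rt, choice, win, tol)
            if ll == -np.inf:
                return -np.inf
            s += ll
    return s


@njit(cache=True)
def _fill_ll_cache(starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc):
    J = starts.shape[0] - 1
    for j in range(J):
        for i in range(starts[j], starts[j + 1]):
            llc[i] = _ll_trial(i, B[j, cb[i]], A[j, ca[i]], D[j, cd[i]], N[j, cn[i]],
                               rt, choice, win, tol)


@njit(cache=True)
def _update_subjects(fam, theta, mu, tau, lo, hi_subj, pres, scale, acc,
                     starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N,
                     tol, llc, prop):
    """One sweep of coordinate updates for one family's subject parameters.

    ``theta`` aliases the family's array among B/A/D/N.  ``llc`` is the
    per-trial log-likelihood cache, ``prop`` a scratch buffer for proposed
    per-trial values.
    """
    J, K = theta.shape
    for j in range(J):
        for k in range(K):
            if not pres[j, k]:
                continue
            x = theta[j, k]
            xp = x + scale[j, k] * np.random.normal()
            if xp < lo or xp > hi_subj[j]:
                continue
            ll0 = 0.0
            ll1 = 0.0
            theta[j, k] = xp
            npts = 0
            bad = False
            for i in range(starts[j], starts[j + 1]):
                if fam == 0:
                    hit = cb[i] == k
                elif fam == 1:
                    hit = ca[i] == k
                elif fam == 2:
                    hit = cd[i] == k
                else:
                    hit = cn[i] == k
                if not hit:
                    continue
                ll0 += llc[i]
                v = _ll_trial(i, B[j, cb[i]], A[j, ca[i]], D[j, cd[i]], N[j, cn[i]],
                              rt, choice, win, tol)
                if v == -np.inf:
                    bad = True
                    break
                prop[npts] = v
                ll1 += v
                npts += 1
            if bad:
                theta[j, k] = x
                continue
            dprior = -0.5 * tau[0] * ((xp - mu[k]) ** 2 - (x - mu[k]) ** 2)
            if math.log(np.random.random()) < ll1 - ll0 + dprior:
                acc[j, k] += 1
                # write accepted values back into the cache
                npts = 0
                for i in range(starts[j], starts[j + 1]):
                    if fam == 0:
                        hit = cb[i] == k
                    elif fam == 1:
                        hit = ca[i] == k
                    elif fam == 2:
                        hit = cd[i] == k
                    else:
                        hit = cn[i] == k
                    if hit:
                        llc[i] = prop[npts]
                        npts += 1
            else:
                theta[j, k] = x


@njit(cache=True)
def _update_mu(theta, mu, tau, lo, hi_subj, mulo, muhi, pres, scale, acc):
    J, K = theta.shape
    for k in range(K):
        m = mu[k]
        mp = m + scale[k] * np.random.normal()
        if mp < mulo or mp > muhi:
            continue
        d = 0.0
        for j in range(J):
            if not pres[j, k]:
                continue
            x = theta[j, k]
            d += -0.5 * tau[0] * ((x - mp) ** 2 - (x - m) ** 2)
            d += _log_trunc_z(m, tau[0], lo, hi_subj[j]) - _log_trunc_z(mp, tau[0], lo, hi_subj[j])
        if math.log(np.random.random()) < d:
            mu[k] = mp
            acc[k] += 1


@njit(cache=True)
def _translate(fam, theta, mu, tau, lo, hi_subj, mulo, muhi, pres, scale, acc,
               starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N,
               tol, llc, prop):
    """Joint translation of one cell's group mean and its subject values.

    Moves along the location ridge (mu_k, theta_{.,k}) that coordinate-wise
    updates traverse slowly; subject deviations from the mean are unchanged
    so only the likelihood, the mu bound and the truncation normalizer enter
    the ratio.
    """
    J, K = theta.shape
    for k in range(K):
        eps = scale[k] * np.random.normal()
        mp = mu[k] + eps
        if mp < mulo or mp > muhi:
            continue
        ok = True
        for j in range(J):
            if pres[j, k]:
                x = theta[j, k] + eps
                if x < lo or x > hi_subj[j]:
                    ok = False
                    break
        if not ok:
            continue
        n_pres = 0
        for j in range(J):
            if pres[j, k]:
                theta[j, k] += eps
                n_pres += 1
        d = n_pres * (_log_trunc_z(mu[k], tau[0], lo, hi_subj[0]) -
                      _log_trunc_z(mp, tau[0], lo, hi_subj[0]))
        npts = 0
        bad = False
        for j in range(J):
            if not pres[j, k]:
                continue
            for i in range(starts[j], starts[j + 1]):
                if fam == 0:
                    hit = cb[i] == k
                elif fam == 1:
                    hit = ca[i] == k
                elif fam == 2:
                    hit = cd[i] == k
                else:
                    hit = cn[i] == k
                if not hit:
                    continue
                v = _ll_trial(i, B[j, cb[i]], A[j, ca[i]], D[j, cd[i]], N[j, cn[i]],
                              rt, choice, win, tol)
                if v == -np.inf:
                    bad = True
                    break
                d += v - llc[i]
                prop[npts] = v
                npts += 1
            if bad:
                break
        if (not bad) and math.log(np.random.random()) < d:
            mu[k] = mp
            acc[k] += 1
            npts = 0
            for j in range(J):
                if not pres[j, k]:
                    continue
                for i in range(starts[j], starts[j + 1]):
                    if fam == 0:
                        hit = cb[i] == k
                    elif fam == 1:
                        hit = ca[i] == k
                    elif fam == 2:
                        hit = cd[i] == k
                    else:
                        hit = cn[i] == k
                    if hit:
                        llc[i] = prop[npts]
                        npts += 1
        else:
            for j in range(J):
                if pres[j, k]:
                    theta[j, k] -= eps


@njit(cache=True)
def _update_tau(theta, mu, tau, lo, hi_subj, pres, shape, rate, scale, acc):
    J, K = theta.shape
    t0 = tau[0]
    lt = math.log(t0)
    ltp = lt + scale[0] * np.random.normal()
    tp = math.exp(ltp)
    # gamma prior difference plus the log-scale Jacobian
    d = shape * (ltp - lt) - rate * (tp - t0)
    for j in range(J):
        for k in range(K):
            if not pres[j, k]:
                continue
            x = theta[j, k]
            d += 0.5 * (ltp - lt) - 0.5 * (tp - t0) * (x - mu[k]) ** 2
            d += _log_trunc_z(mu[k], t0, lo, hi_subj[j]) - _log_trunc_z(mu[k], tp, lo, hi_subj[j])
    if math.log(np.random.random()) < d:
        tau[0] = tp
        acc[0] += 1


@njit(cache=True)
def _adapt(scale, acc, n_attempts, step):
    it = scale.flat
    ia = acc.flat
    for i in range(scale.size):
        rate = ia[i] / n_attempts
        if rate > 0.44:
            it[i] = it[i] * math.exp(step)
        else:
            it[i] = it[i] * math.exp(-step)
        ia[i] = 0.0


@njit(cache=True)
def run_chain(seed, n_warmup, n_keep,
              starts, rt, choice, win, cb, ca, cd, cn,
              presB, presA, presD, presN,
              lo4, hiB, hiA, hiD, hiN,
              mulo4, muhi4, tau_shape, tau_rate, tol,
              B, A, D, N, muB, muA, muD, muN, tau4):
    """Run one MCMC chain; parameter arrays are taken as the initial state.

    Returns kept draws of group means, precisions, subject parameters and
    the total data log-likelihood of each kept draw.
    """
    np.random.seed(seed)
    J = starts.shape[0] - 1
    Kb, Ka, Kd, Kn = muB.shape[0], muA.shape[0], muD.shape[0], muN.shape[0]
    T = rt.shape[0]
    llc = np.empty(T)
    prop = np.empty(T)
    _fill_ll_cache(starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc)

    sB = np.full((J, Kb), 0.05)
    sA = np.full((J, Ka), 0.15)
    sD = np.full((J, Kd), 0.5)
    sN = np.full((J, Kn), 0.03)
    aB = np.zeros((J, Kb))
    aA = np.zeros((J, Ka))
    aD = np.zeros((J, Kd))
    aN = np.zeros((J, Kn))
    smB = np.full(Kb, 0.03)
    smA = np.full(Ka, 0.08)
    smD = np.full(Kd, 0.2)
    smN = np.full(Kn, 0.02)
    stB = np.full(Kb, 0.03)
    stA = np.full(Ka, 0.08)
    stD = np.full(Kd, 0.2)
    stN = np.full(Kn, 0.02)
    atB = np.zeros(Kb)
    atA = np.zeros(Ka)
    atD = np.zeros(Kd)
    atN = np.zeros(Kn)
    amB = np.zeros(Kb)
    amA = np.zeros(Ka)
    amD = np.zeros(Kd)
    amN = np.zeros(Kn)
    st = np.full(4, 0.5)
    at = np.zeros(4)

    muB_d = np.empty((n_keep, Kb))
    muA_d = np.empty((n_keep, Ka))
    muD_d = np.empty((n_keep, Kd))
    muN_d = np.empty((n_keep, Kn))
    tau_d = np.empty((n_keep, 4))
    B_d = np.empty((n_keep, J, Kb))
    A_d = np.empty((n_keep, J, Ka))
    D_d = np.empty((n_keep, J, Kd))
    N_d = np.empty((n_keep, J, Kn))
    ll_d = np.empty(n_keep)

    batch = 50
    n_batches = 0
    for it in range(n_warmup + n_keep):
        _update_subjects(0, B, muB, tau4[0:1], lo4[0], hiB, presB, sB, aB,
                         starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _update_subjects(1, A, muA, tau4[1:2], lo4[1], hiA, presA, sA, aA,
                         starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _update_subjects(2, D, muD, tau4[2:3], lo4[2], hiD, presD, sD, aD,
                         starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _update_subjects(3, N, muN, tau4[3:4], lo4[3], hiN, presN, sN, aN,
                         starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _update_mu(B, muB, tau4[0:1], lo4[0], hiB, mulo4[0], muhi4[0], presB, smB, amB)
        _update_mu(A, muA, tau4[1:2], lo4[1], hiA, mulo4[1], muhi4[1], presA, smA, amA)
        _update_mu(D, muD, tau4[2:3], lo4[2], hiD, mulo4[2], muhi4[2], presD, smD, amD)
        _update_mu(N, muN, tau4[3:4], lo4[3], hiN, mulo4[3], muhi4[3], presN, smN, amN)
        _translate(0, B, muB, tau4[0:1], lo4[0], hiB, mulo4[0], muhi4[0], presB, stB, atB,
                   starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _translate(1, A, muA, tau4[1:2], lo4[1], hiA, mulo4[1], muhi4[1], presA, stA, atA,
                   starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _translate(2, D, muD, tau4[2:3], lo4[2], hiD, mulo4[2], muhi4[2], presD, stD, atD,
                   starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _translate(3, N, muN, tau4[3:4], lo4[3], hiN, mulo4[3], muhi4[3], presN, stN, atN,
                   starts, rt, choice, win, cb, ca, cd, cn, B, A, D, N, tol, llc, prop)
        _update_tau(B, muB, tau4[0:1], lo4[0], hiB, presB, tau_shape, tau_rate, st[0:1], at[0:1])
        _update_tau(A, muA, tau4[1:2], lo4[1], hiA, presA, tau_shape, tau_rate, st[1:2], at[1:2])
        _update_tau(D, muD, tau4[2:3], lo4[2], hiD, presD, tau_shape, tau_rate, st[2:3], at[2:3])
        _update_tau(N, muN, tau4[3:4], lo4[3], hiN, presN, tau_shape, tau_rate, st[3:4], at[3:4])

        if it < n_warmup and (it + 1) % batch == 0:
            n_batches += 1
            step = min(0.25, 1.0 / math.sqrt(n_batches))
            _adapt(sB, aB, batch, step)
            _adapt(sA, aA, batch, step)
            _adapt(sD, aD, batch, step)
            _adapt(sN, aN, batch, step)
            _adapt(smB, amB, batch, step)
            _adapt(smA, amA, batch, step)
            _adapt(smD, amD, batch, step)
            _adapt(smN, amN, batch, step)
            _adapt(stB, atB, batch, step)
            _adapt(stA, atA, batch, step)
            _adapt(stD, atD, batch, step)
            _adapt(stN, atN, batch, step)
            _adapt(st, at, batch, step)

        if it >= n_warmup:
            m = it - n_warmup
            muB_d[m] = muB
            muA_d[m] = muA
            muD_d[m] = muD
            muN_d[m] = muN
            tau_d[m] = tau4
            B_d[m] = B
            A_d[m] = A
            D_d[m] = D
            N_d[m] = N
            ll_d[m] = llc.sum()

    return muB_d, muA_d, muD_d, muN_d, tau_d, B_d, A_d, D_d, N_d, ll_d
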