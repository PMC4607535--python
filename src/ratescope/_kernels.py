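"""Numba kernels: linear-drift propagators, filter likelihood, MCMC chain.

The single-cell layer has linear drift

    dM = (u - dM_ * M) dt,   dP = (alpha * M - dP_ * P) dt,   u = c * tau(t),

so the mean propagates exactly through closed-form matrix exponentials; the
state covariance (chemical-Langevin diffusion evaluated along the predicted
mean) is accumulated with a trapezoidal rule over substeps.  Everything here
works on plain float arrays; the public modules wrap these kernels with
validated containers.
"""

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _em1(x):
    """(1 - exp(-x)) / x, stable near zero."""
    if abs(x) < 1e-5:
        return 1.0 - x / 2.0 + x * x / 6.0
    return -math.expm1(-x) / x


@njit(cache=True)
def _g2(x):
    """integral_0^1 s * exp(-x s) ds = (1 - (1+x) e^{-x}) / x^2, stable."""
    if abs(x) < 1e-4:
        return 0.5 - x / 3.0 + x * x / 8.0
    return (1.0 - (1.0 + x) * math.exp(-x)) / (x * x)


@njit(cache=True)
def propagators(h, dM_, dP_, alpha):
    """Closed-form flow of the linear drift over a step of length h.

    Returns (a, b, c, iM, iP) such that for constant production u:
        mM' = a*mM + u*iM
        mP' = b*mM + c*mP + u*iP
    """
    a = math.exp(-dM_ * h)
    c = math.exp(-dP_ * h)
    d = dP_ - dM_
    b = alpha * h * a * _em1(d * h)
    iM = h * _em1(dM_ * h)
    if abs(d * h) < 1e-5:
        db = 0.5 * (dM_ + dP_)
        J = h * h * _g2(db * h)
    else:
        J = h * (_em1(dM_ * h) - _em1(dP_ * h)) / d
    return a, b, c, iM, alpha * J


@njit(cache=True)
def _segment(mM, mP, sMM, sMP, sPP, dt, u, dM_, dP_, alpha, nsub):
    """Propagate mean and covariance over [0, dt] with constant u."""
    h = dt / nsub
    a, b, c, iM, iP = propagators(h, dM_, dP_, alpha)
    for _ in range(nsub):
        mMc = mM if mM > 0.0 else 0.0
        mPc = mP if mP > 0.0 else 0.0
        q0M = u + dM_ * mMc
        q0P = alpha * mMc + dP_ * mPc
        mM1 = a * mM + u * iM
        mP1 = b * mM + c * mP + u * iP
        mM1c = mM1 if mM1 > 0.0 else 0.0
        mP1c = mP1 if mP1 > 0.0 else 0.0
        qhM = u + dM_ * mM1c
        qhP = alpha * mM1c + dP_ * mP1c
        tMM = a * a * sMM
        tMP = a * (b * sMM + c * sMP)
        tPP = b * b * sMM + 2.0 * b * c * sMP + c * c * sPP
        sMM = tMM + 0.5 * h * (a * a * q0M + qhM)
        sMP = tMP + 0.5 * h * (a * b * q0M)
        sPP = tPP + 0.5 * h * (b * b * q0M + c * c * q0P + qhP)
        mM = mM1
        mP = mP1
    return mM, mP, sMM, sMP, sPP


@njit(cache=True)
def filter_loglik(ts, fs, n, c, tau0, tau1, T, M0, P0,
                  dM_, dP_, alpha, kappa, sig2, nsub):
    """Gaussian-filter log-likelihood of one trace under the two-state model.

    Latent moments start at the point mass (M0, P0) at t = 0 and are
    propagated piecewise (basal rate before the switch time T, active rate
    after), with a Kalman update at each observation F_i = kappa*P + noise.
    """
    mM = M0
    mP = P0
    sMM = 0.0
    sMP = 0.0
    sPP = 0.0
    ll = 0.0
    tprev = 0.0
    for i in range(n):
        t = ts[i]
        while t > tprev + 1e-12:
            if tprev < T and T < t:
                seg_end = T
                u = c * tau0
            elif t <= T:
                seg_end = t
                u = c * tau0
            else:
                seg_end = t
                u = c * tau1
            mM, mP, sMM, sMP, sPP = _segment(
                mM, mP, sMM, sMP, sPP, seg_end - tprev, u,
                dM_, dP_, alpha, nsub)
            tprev = seg_end
        S = kappa * kappa * sPP + sig2
        r = fs[i] - kappa * mP
        if S < 1e-300:
            if abs(r) > 1e-6:
                return -np.inf
            continue
        ll += -0.5 * (LOG2PI + math.log(S) + r * r / S)
        g = kappa / S
        kM = g * sMP
        kP = g * sPP
        mM += kM * r
        mP += kP * r
        kk = kappa * kappa / S
        sMM -= kk * sMP * sMP
        sMP -= kk * sMP * sPP
        sPP -= kk * sPP * sPP
    if not math.isfinite(ll):
        return -np.inf
    return ll


@njit(cache=True)
def _normal_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd)


@njit(cache=True)
def _cell_loglik(obs_t, obs_f, n_obs, i, th, dM_, dP_, alpha, kappa, sig2, nsub):
    return filter_loglik(
        obs_t[i], obs_f[i], n_obs[i],
        math.exp(th[0]), math.exp(th[1]), math.exp(th[2]), th[3],
        math.exp(th[4]), math.exp(th[5]),
        dM_, dP_, alpha, kappa, sig2, nsub)


@njit(cache=True)
def _prior_term(p, x, cons_i, s_c, mu1, s1, mu0, s0,
                pM0m, pM0s, pP0m, pP0s):
    """Log-prior contribution of one log-scale cell parameter."""
    if p == 0:
        return _normal_logpdf(x, 0.0, s_c)
    if p == 1:
        return _normal_logpdf(x, mu0[cons_i], s0[cons_i])
    if p == 2:
        return _normal_logpdf(x, mu1[cons_i], s1[cons_i])
    if p == 4:
        return _normal_logpdf(x, pM0m, pM0s)
    if p == 5:
        return _normal_logpdf(x, pP0m, pP0s)
    return 0.0  # T: flat on the window


@njit(cache=True)
def run_chain(obs_t, obs_f, n_obs, tmax, cons, n_cons,
              dM_, dP_, alpha, kappa, sig2_init,
              theta0, s_c0, mu1_0, s1_0, mu0_0, s0_0,
              pM0m, pM0s, pP0m, pP0s,
              a0c, b0c, a0r, b0r, hyper_m0, hyper_v0,
              steps, update_mask, do_swap, sample_sig2, sample_hypers,
              n_iter, burn, thin, nsub, seed):
    """One Metropolis-within-Gibbs chain over all cells and hyperparameters.

    theta layout per cell: (log c, log tau0, log tau1, T, log M0, log P0).
    Copy-number population log-median is anchored at 0 (median c = 1), so
    per-copy rates across constructs share one scale.
    """
    np.random.seed(seed)
    ncell = theta0.shape[0]
    theta = theta0.copy()
    s_c = s_c0
    mu1 = mu1_0.copy()
    s1 = s1_0.copy()
    mu0 = mu0_0.copy()
    s0 = s0_0.copy()
    sig2 = sig2_init

    cur_ll = np.empty(ncell)
    for i in range(ncell):
        cur_ll[i] = _cell_loglik(obs_t, obs_f, n_obs, i, theta[i],
                                 dM_, dP_, alpha, kappa, sig2, nsub)

    n_keep = (n_iter - burn + thin - 1) // thin
    kept_cells = np.empty((n_keep, ncell, 6))
    kept_hyper = np.empty((n_keep, 2 + 4 * n_cons))
    kept_lp = np.empty(n_keep)
    acc = np.zeros(8)
    prop_n = np.zeros(8)
    k_out = 0

    for it in range(n_iter):
        for i in range(ncell):
            ci = cons[i]
            for p in range(6):
                if not update_mask[p]:
                    continue
                x = theta[i, p]
                if p == 3:
                    xp = x + steps[3] * np.random.normal()
                    hi = tmax[i]
                    # reflect into [0, hi]
                    for _ in range(100):
                        if xp < 0.0:
                            xp = -xp
                        elif xp > hi:
                            xp = 2.0 * hi - xp
                        else:
                            break
                    dprior = 0.0
                else:
                    xp = x + steps[p] * np.random.normal()
                    if p == 1 and xp > theta[i, 2]:
                        continue  # tau0 must stay <= tau1
                    if p == 2 and xp < theta[i, 1]:
                        continue
                    dprior = (_prior_term(p, xp, ci, s_c, mu1, s1, mu0, s0,
                                          pM0m, pM0s, pP0m, pP0s)
                              - _prior_term(p, x, ci, s_c, mu1, s1, mu0, s0,
                                            pM0m, pM0s, pP0m, pP0s))
                prop_n[p] += 1.0
                theta[i, p] = xp
                new_ll = _cell_loglik(obs_t, obs_f, n_obs, i, theta[i],
                                      dM_, dP_, alpha, kappa, sig2, nsub)
                if math.log(np.random.random()) < new_ll - cur_ll[i] + dprior:
                    cur_ll[i] = new_ll
                    acc[p] += 1.0
                else:
                    theta[i, p] = x
            if do_swap:
                # scale exchange c -> g*c, tau -> tau/g leaves the
                # likelihood invariant; only the population layer decides
                lg = steps[6] * np.random.normal()
                prop_n[6] += 1.0
                dprior = 0.0
                dprior += (_normal_logpdf(theta[i, 0] + lg, 0.0, s_c)
                           - _normal_logpdf(theta[i, 0], 0.0, s_c))
                dprior += (_normal_logpdf(theta[i, 1] - lg, mu0[ci], s0[ci])
                           - _normal_logpdf(theta[i, 1], mu0[ci], s0[ci]))
                dprior += (_normal_logpdf(theta[i, 2] - lg, mu1[ci], s1[ci])
                           - _normal_logpdf(theta[i, 2], mu1[ci], s1[ci]))
                if math.log(np.random.random()) < dprior:
                    theta[i, 0] += lg
                    theta[i, 1] -= lg
                    theta[i, 2] -= lg
                    acc[6] += 1.0

        if sample_sig2:
            prop_n[7] += 1.0
            lsp = math.log(sig2) + steps[7] * np.random.normal()
            sig2_p = math.exp(lsp)
            dprior = (_normal_logpdf(lsp, math.log(sig2_init), 2.0)
                      - _normal_logpdf(math.log(sig2), math.log(sig2_init), 2.0))
            new_tot = 0.0
            new_ll_all = np.empty(ncell)
            ok = True
            for i in range(ncell):
                v = _cell_loglik(obs_t, obs_f, n_obs, i, theta[i],
                                 dM_, dP_, alpha, kappa, sig2_p, nsub)
                new_ll_all[i] = v
                new_tot += v
                if not math.isfinite(v):
                    ok = False
                    break
            if ok and math.log(np.random.random()) < new_tot - np.sum(cur_ll) + dprior:
                sig2 = sig2_p
                for i in range(ncell):
                    cur_ll[i] = new_ll_all[i]
                acc[7] += 1.0

        if sample_hypers:
            # shared copy-number scale (log-median anchored at 0)
            ssq = 0.0
            for i in range(ncell):
                ssq += theta[i, 0] * theta[i, 0]
            s2 = (b0c + 0.5 * ssq) / np.random.gamma(a0c + 0.5 * ncell, 1.0)
            s_c = math.sqrt(s2)
            for j in range(n_cons):
                for col in (2, 1):
                    nj = 0
                    sx = 0.0
                    for i in range(ncell):
                        if cons[i] == j:
                            nj += 1
                            sx += theta[i, col]
                    s_cur = s1[j] if col == 2 else s0[j]
                    prec = nj / (s_cur * s_cur) + 1.0 / (hyper_v0 * hyper_v0)
                    mean = (sx / (s_cur * s_cur)
                            + hyper_m0 / (hyper_v0 * hyper_v0)) / prec
                    mu_new = mean + np.random.normal() / math.sqrt(prec)
                    ssd = 0.0
                    for i in range(ncell):
                        if cons[i] == j:
                            d = theta[i, col] - mu_new
                            ssd += d * d
                    s2_new = (b0r + 0.5 * ssd) / np.random.gamma(a0r + 0.5 * nj, 1.0)
                    if col == 2:
                        mu1[j] = mu_new
                        s1[j] = math.sqrt(s2_new)
                    else:
                        mu0[j] = mu_new
                        s0[j] = math.sqrt(s2_new)

        if it >= burn and (it - burn) % thin == 0:
            lp = 0.0
            for i in range(ncell):
                lp += cur_ll[i]
                for p in range(6):
                    lp += _prior_term(p, theta[i, p], cons[i], s_c,
                                      mu1, s1, mu0, s0,
                                      pM0m, pM0s, pP0m, pP0s)
                kept_cells[k_out, i, 0] = math.exp(theta[i, 0])
                kept_cells[k_out, i, 1] = math.exp(theta[i, 1])
                kept_cells[k_out, i, 2] = math.exp(theta[i, 2])
                kept_cells[k_out, i, 3] = theta[i, 3]
                kept_cells[k_out, i, 4] = math.exp(theta[i, 4])
                kept_cells[k_out, i, 5] = math.exp(theta[i, 5])
            kept_hyper[k_out, 0] = sig2
            kept_hyper[k_out, 1] = s_c
            for j in range(n_cons):
                kept_hyper[k_out, 2 + 4 * j] = mu1[j]
                kept_hyper[k_out, 3 + 4 * j] = s1[j]
                kept_hyper[k_out, 4 + 4 * j] = mu0[j]
                kept_hyper[k_out, 5 + 4 * j] = s0[j]
            kept_lp[k_out] = lp
            k_out += 1

    return kept_cells, kept_hyper, kept_lp, acc, prop_n
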