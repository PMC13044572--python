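"""Numba kernels: compiled joint log-density and the MCMC transition.

Everything here operates on flat parameter vectors and the array encoding
produced by ``aemeta._compile``.  The Python-facing model definition lives
in ``aemeta.hierarchy``; the equivalence of the two evaluation routes is
asserted in the test-suite.

Parameter encoding
------------------
``kind[d]`` selects the prior treatment of coordinate ``d``:

* 0 — standard-normal deviate of a non-centered hierarchical level,
* 1 — coordinate with an explicit (mixture) prior,
* 2 — logit of a (0,1) coordinate with a beta-mixture prior on the
  probability scale (log-Jacobian included),
* 3 — nonnegative coordinate with a (mixture) prior; negative values are
  rejected outright,
* 4 — centered hierarchical coordinate with a Normal(nu, sigma^2) prior
  whose hyperparameters are themselves coordinates.

Trial-level mode codes (``t_mode*``, ``h_mode``): 0 non-centered deviate,
1 direct coordinate with its own prior (stratified borrowing), 2 centered.

Mixture component families: 0 normal(loc, scale), 1 half-normal(scale),
2 cauchy(loc, scale), 3 beta(a, b), 4 normal(loc, scale) truncated to
[0, inf).

The sampler factorizes the posterior into a global-prior part plus
per-trial blocks (the block's prior terms and its arms' likelihoods) and
caches block values per walker, so trial-local proposals re-evaluate only
the arms they touch.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_NEG_INF = -math.inf

# indices into the global-parameter index table
G_NU1, G_SIG1, G_NU2, G_SIG2, G_NU3, G_SIG3, G_A0, G_A1, G_PHI, G_ETA = range(10)


@njit(cache=True)
def _norm_logpdf(x, loc, scale):
    if scale <= 0.0:
        return _NEG_INF
    z = (x - loc) / scale
    return -0.5 * z * z - math.log(scale) - _LOG_SQRT_2PI


@njit(cache=True)
def _mix_logpdf(x, off, length, mfam, mlogw, mp1, mp2):
    best = _NEG_INF
    vals = np.empty(length)
    for k in range(length):
        fam = mfam[off + k]
        p1 = mp1[off + k]
        p2 = mp2[off + k]
        if fam == 0:  # normal
            z = (x - p1) / p2
            v = -0.5 * z * z - math.log(p2) - _LOG_SQRT_2PI
        elif fam == 1:  # half-normal
            if x < 0.0:
                v = _NEG_INF
            else:
                z = x / p1
                v = math.log(2.0) - 0.5 * z * z - math.log(p1) - _LOG_SQRT_2PI
        elif fam == 2:  # cauchy
            z = (x - p1) / p2
            v = -math.log(math.pi * p2 * (1.0 + z * z))
        elif fam == 3:  # beta on (0,1)
            if x <= 0.0 or x >= 1.0:
                v = _NEG_INF
            else:
                v = ((p1 - 1.0) * math.log(x) + (p2 - 1.0) * math.log1p(-x)
                     + math.lgamma(p1 + p2) - math.lgamma(p1) - math.lgamma(p2))
        else:  # 4: normal truncated to [0, inf)
            if x < 0.0:
                v = _NEG_INF
            else:
                z = (x - p1) / p2
                tail = 0.5 * (1.0 + math.erf(p1 / (p2 * math.sqrt(2.0))))
                v = (-0.5 * z * z - math.log(p2) - _LOG_SQRT_2PI
                     - math.log(tail))
        vals[k] = mlogw[off + k] + v
        if vals[k] > best:
            best = vals[k]
    if best == _NEG_INF:
        return _NEG_INF
    acc = 0.0
    for k in range(length):
        acc += math.exp(vals[k] - best)
    return best + math.log(acc)


@njit(cache=True)
def _arm_ll(lam, mu, q, i,
            a_m, a_ybase, a_zbase, a_nbase, a_r1, a_r2, a_tau, a_coff, coef):
    """Marginalized aggregate-data log likelihood of arm ``i``."""
    tau = a_tau[i]
    s = lam + mu
    x = s * tau
    if x < 1e-8:
        f = tau * (1.0 - x / 2.0 + x * x / 6.0)
    else:
        f = -math.expm1(-x) / s
    p1 = q * lam * f
    p2 = (1.0 - q) * (-math.expm1(-lam * tau)) * math.exp(-mu * tau)
    p3 = (1.0 - q) * (-math.expm1(-mu * tau) - mu * f)
    if p3 < 0.0:
        p3 = 0.0
    p4 = math.exp(-x)
    p5 = mu * f

    lp1 = math.log(p1) if p1 > 0.0 else _NEG_INF
    lp2 = math.log(p2) if p2 > 0.0 else _NEG_INF
    lp3 = math.log(p3) if p3 > 0.0 else _NEG_INF
    lp4 = math.log(p4) if p4 > 0.0 else _NEG_INF
    lp5 = math.log(p5) if p5 > 0.0 else _NEG_INF

    m = a_m[i]
    if m > 0:
        if lp1 == _NEG_INF:
            return _NEG_INF
        base = m * lp1
    else:
        base = 0.0

    r1 = a_r1[i]
    r2 = a_r2[i]
    off = a_coff[i]
    best = _NEG_INF
    nterm = r2 - r1 + 1
    terms = np.empty(nterm)
    for k in range(nterm):
        r = r1 + k
        e2 = a_ybase[i] - r
        e4 = a_nbase[i] + r
        e5 = a_zbase[i] - r
        v = coef[off + k]
        ok = True
        if e2 > 0:
            if lp2 == _NEG_INF:
                ok = False
            else:
                v += e2 * lp2
        if ok and r > 0:
            if lp3 == _NEG_INF:
                ok = False
            else:
                v += r * lp3
        if ok and e4 > 0:
            if lp4 == _NEG_INF:
                ok = False
            else:
                v += e4 * lp4
        if ok and e5 > 0:
            if lp5 == _NEG_INF:
                ok = False
            else:
                v += e5 * lp5
        if not ok:
            v = _NEG_INF
        terms[k] = v
        if v > best:
            best = v
    if best == _NEG_INF:
        return _NEG_INF
    acc = 0.0
    for k in range(nterm):
        acc += math.exp(terms[k] - best)
    return base + best + math.log(acc)


@njit(cache=True)
def _global_prior(th, kind, c_trial, moff, mlen, mfam, mlogw, mp1, mp2):
    """Prior terms of all coordinates not belonging to a trial block."""
    lp = 0.0
    for d in range(th.shape[0]):
        k = kind[d]
        x = th[d]
        if k == 3 and x < 0.0:
            return _NEG_INF
        if c_trial[d] >= 0:
            continue
        if k == 1:
            lp += _mix_logpdf(x, moff[d], mlen[d], mfam, mlogw, mp1, mp2)
        elif k == 2:
            q = 1.0 / (1.0 + math.exp(-x))
            lp += (_mix_logpdf(q, moff[d], mlen[d], mfam, mlogw, mp1, mp2)
                   + math.log(q) + math.log1p(-q))
        elif k == 3:
            lp += _mix_logpdf(x, moff[d], mlen[d], mfam, mlogw, mp1, mp2)
        if lp == _NEG_INF:
            return _NEG_INF
    return lp


@njit(cache=True)
def _trial_block(th, tt, meta, gidx,
                 t_u1, t_u2, t_u3, t_v, t_mode1, t_mode2, t_mode3, t_modev,
                 h_u1, h_u2, h_mode,
                 kind, moff, mlen, mfam, mlogw, mp1, mp2,
                 ta_off, ta_cnt, ta_idx,
                 a_treat, a_m, a_ybase, a_zbase, a_nbase,
                 a_r1, a_r2, a_tau, a_coff, coef):
    """Contribution of trial block ``tt`` (0..T+H-1) as (prior, likelihood)."""
    T = meta[0]
    anchor = meta[2]
    random_effects = meta[3]

    nu1 = th[gidx[G_NU1]] if gidx[G_NU1] >= 0 else 0.0
    sig1 = th[gidx[G_SIG1]] if gidx[G_SIG1] >= 0 else 0.0
    nu2 = th[gidx[G_NU2]] if gidx[G_NU2] >= 0 else 0.0
    sig2 = th[gidx[G_SIG2]] if gidx[G_SIG2] >= 0 else 0.0
    nu3 = th[gidx[G_NU3]] if gidx[G_NU3] >= 0 else 0.0
    sig3 = th[gidx[G_SIG3]] if gidx[G_SIG3] >= 0 else 0.0
    q0 = 1.0 / (1.0 + math.exp(-th[gidx[G_A0]])) if gidx[G_A0] >= 0 else 0.5
    q1 = 1.0 / (1.0 + math.exp(-th[gidx[G_A1]])) if gidx[G_A1] >= 0 else 0.5
    phi = th[gidx[G_PHI]] if gidx[G_PHI] >= 0 else 0.0
    eta = th[gidx[G_ETA]] if gidx[G_ETA] >= 0 else 0.0

    pr = 0.0
    ll = 0.0
    if tt < T:
        t = tt
        if t_mode1[t] == 0:
            u = th[t_u1[t]]
            pr += -0.5 * u * u - _LOG_SQRT_2PI
            anc = nu1 + sig1 * u
        elif t_mode1[t] == 2:
            anc = th[t_u1[t]]
            pr += _norm_logpdf(anc, nu1, sig1)
        else:
            anc = th[t_u1[t]]
            d = t_u1[t]
            pr += _mix_logpdf(anc, moff[d], mlen[d], mfam, mlogw, mp1, mp2)
        if t_mode2[t] == 0:
            u = th[t_u2[t]]
            pr += -0.5 * u * u - _LOG_SQRT_2PI
            lmu0 = nu2 + sig2 * u
        elif t_mode2[t] == 2:
            lmu0 = th[t_u2[t]]
            pr += _norm_logpdf(lmu0, nu2, sig2)
        else:
            lmu0 = th[t_u2[t]]
            d = t_u2[t]
            pr += _mix_logpdf(lmu0, moff[d], mlen[d], mfam, mlogw, mp1, mp2)
        if t_mode3[t] == 0:
            u = th[t_u3[t]]
            pr += -0.5 * u * u - _LOG_SQRT_2PI
            lmu1 = nu3 + sig3 * u
        else:
            lmu1 = th[t_u3[t]]
            pr += _norm_logpdf(lmu1, nu3, sig3)
        if random_effects == 1:
            if t_modev[t] == 0:
                u = th[t_v[t]]
                pr += -0.5 * u * u - _LOG_SQRT_2PI
                ph = phi + eta * u
            else:
                ph = th[t_v[t]]
                pr += _norm_logpdf(ph, phi, eta)
        else:
            ph = phi
        if pr == _NEG_INF:
            return _NEG_INF, 0.0
        if anchor == 0:
            ll0 = anc
            ll1 = anc + ph
        else:
            ll1 = anc
            ll0 = anc - ph
        lam0 = math.exp(ll0)
        lam1 = math.exp(ll1)
        mu0 = math.exp(lmu0)
        mu1 = math.exp(lmu1)
        for k in range(ta_cnt[tt]):
            i = ta_idx[ta_off[tt] + k]
            if a_treat[i] == 1:
                ll += _arm_ll(lam1, mu1, q1, i, a_m, a_ybase, a_zbase,
                              a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
            else:
                ll += _arm_ll(lam0, mu0, q0, i, a_m, a_ybase, a_zbase,
                              a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
            if ll == _NEG_INF:
                return pr, _NEG_INF
        return pr, ll

    h = tt - T
    if h_mode[h] == 0:
        u = th[h_u1[h]]
        pr += -0.5 * u * u - _LOG_SQRT_2PI
        llh = nu1 + sig1 * u
        u = th[h_u2[h]]
        pr += -0.5 * u * u - _LOG_SQRT_2PI
        lmh = nu2 + sig2 * u
    else:
        llh = th[h_u1[h]]
        lmh = th[h_u2[h]]
        pr += _norm_logpdf(llh, nu1, sig1)
        pr += _norm_logpdf(lmh, nu2, sig2)
    if pr == _NEG_INF:
        return _NEG_INF, 0.0
    lamh = math.exp(llh)
    muh = math.exp(lmh)
    for k in range(ta_cnt[tt]):
        i = ta_idx[ta_off[tt] + k]
        ll += _arm_ll(lamh, muh, q0, i, a_m, a_ybase, a_zbase,
                      a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
        if ll == _NEG_INF:
            return pr, _NEG_INF
    return pr, ll


@njit(cache=True)
def _log_posterior(th, meta, gidx,
                   t_u1, t_u2, t_u3, t_v, t_mode1, t_mode2, t_mode3, t_modev,
                   h_u1, h_u2, h_mode,
                   kind, c_trial, moff, mlen, mfam, mlogw, mp1, mp2,
                   ta_off, ta_cnt, ta_idx,
                   a_treat, a_m, a_ybase, a_zbase, a_nbase,
                   a_r1, a_r2, a_tau, a_coff, coef):
    lp = _global_prior(th, kind, c_trial, moff, mlen, mfam, mlogw, mp1, mp2)
    if lp == _NEG_INF:
        return _NEG_INF
    nblocks = meta[0] + meta[1]
    for tt in range(nblocks):
        pr, ll = _trial_block(th, tt, meta, gidx,
                              t_u1, t_u2, t_u3, t_v, t_mode1, t_mode2,
                              t_mode3, t_modev, h_u1, h_u2, h_mode,
                              kind, moff, mlen, mfam, mlogw, mp1, mp2,
                              ta_off, ta_cnt, ta_idx,
                              a_treat, a_m, a_ybase, a_zbase, a_nbase,
                              a_r1, a_r2, a_tau, a_coff, coef)
        if pr == _NEG_INF or ll == _NEG_INF:
            return _NEG_INF
        lp += pr + ll
    return lp


@njit(cache=True)
def _lev_cond(val, nu, sig, is_scale, th, memb, mstart, mcount,
              moffd, mlend, mfam, mlogw, mp1, mp2):
    """Full conditional log-density of one hyperparameter of a centered
    hierarchical level: its own (mixture) prior plus the Normal terms of
    the level's member coordinates.  Exact because centered members shield
    the hyperparameters from the likelihood."""
    if is_scale:
        if val <= 0.0:
            return _NEG_INF
        sig = val
    else:
        nu = val
    lp = _mix_logpdf(val, moffd, mlend, mfam, mlogw, mp1, mp2)
    if lp == _NEG_INF:
        return _NEG_INF
    for k in range(mcount):
        lp += _norm_logpdf(th[memb[mstart + k]], nu, sig)
        if lp == _NEG_INF:
            return _NEG_INF
    return lp


@njit(cache=True)
def _slice_1d(cur, nu, sig, is_scale, th, memb, mstart, mcount,
              moffd, mlend, mfam, mlogw, mp1, mp2, width):
    """One univariate slice-sampling update (stepping out + shrinkage).
    Returns (new value, conditional log-density change)."""
    f0 = _lev_cond(cur, nu, sig, is_scale, th, memb, mstart, mcount,
                   moffd, mlend, mfam, mlogw, mp1, mp2)
    y = f0 + math.log(np.random.random())
    L = cur - width * np.random.random()
    R = L + width
    for _ in range(200):
        if _lev_cond(L, nu, sig, is_scale, th, memb, mstart, mcount,
                     moffd, mlend, mfam, mlogw, mp1, mp2) <= y:
            break
        L -= width
    for _ in range(200):
        if _lev_cond(R, nu, sig, is_scale, th, memb, mstart, mcount,
                     moffd, mlend, mfam, mlogw, mp1, mp2) <= y:
            break
        R += width
    for _ in range(200):
        val = L + np.random.random() * (R - L)
        fv = _lev_cond(val, nu, sig, is_scale, th, memb, mstart, mcount,
                       moffd, mlend, mfam, mlogw, mp1, mp2)
        if fv > y:
            return val, fv - f0
        if val < cur:
            L = val
        else:
            R = val
    return cur, 0.0


@njit(cache=True)
def _run_ensemble(x0, nsteps, burn, thin, a_stretch, seed,
                  lev_act, lev_nu, lev_sig, lev_off, lev_cnt, lev_memb,
                  tc_off, tc_cnt, tc_idx, tcr_off, tcr_cnt,
                  meta, gidx,
                  t_u1, t_u2, t_u3, t_v, t_mode1, t_mode2, t_mode3, t_modev,
                  h_u1, h_u2, h_mode,
                  kind, c_trial, moff, mlen, mfam, mlogw, mp1, mp2,
                  ta_off, ta_cnt, ta_idx,
                  a_treat, a_m, a_ybase, a_zbase, a_nbase,
                  a_r1, a_r2, a_tau, a_coff, coef):
    """Walker-ensemble MCMC with trial-local refreshment.

    Per sweep and walker the kernel composes: (a) when the ensemble is
    large enough for affine moves (walkers >= 2 (dim + 1)), one global
    stretch or differential-evolution move over the complementary half;
    (b) per trial block, one joint shift of its log-rate coordinates (the
    near scale-invariant lambda-mu ridge of drop-out-saturated arms) and
    one single-coordinate move (differential evolution across walkers, or
    a random-walk fallback), re-evaluating only that block; (c) exact
    slice-sampling Gibbs updates of the centered hierarchy's
    hyperparameters, which are conditionally likelihood-free; (d) a
    random-walk refresh of the logit fatality probabilities; (e) for the
    RE log-HR level, collective shift and scale moves (the non-centered
    phi and eta updates at fixed deviates), or a plain random walk on phi
    under the CE model.  Proposal scales adapt during burn-in only
    (diminishing Robbins-Monro), so the post-burn kernel is fixed.

    Saves the ensemble every ``thin`` sweeps after ``burn`` sweeps and
    returns (draws[kept, walkers, dim], logp[kept, walkers],
    accepted-move count over the non-Gibbs moves).
    """
    np.random.seed(seed)
    W, D = x0.shape
    half = W // 2
    T = meta[0]
    NB = T + meta[1]
    use_global = W >= 2 * (D + 1)
    x = x0.copy()

    gp = np.empty(W)
    bpr = np.empty((W, NB))
    bll = np.empty((W, NB))
    lp = np.empty(W)
    for w in range(W):
        gp[w] = _global_prior(x[w], kind, c_trial, moff, mlen, mfam,
                              mlogw, mp1, mp2)
        tot = gp[w]
        for tt in range(NB):
            pr, ll = _trial_block(
                x[w], tt, meta, gidx, t_u1, t_u2, t_u3, t_v, t_mode1,
                t_mode2, t_mode3, t_modev, h_u1, h_u2, h_mode,
                kind, moff, mlen, mfam, mlogw, mp1, mp2,
                ta_off, ta_cnt, ta_idx, a_treat, a_m, a_ybase, a_zbase,
                a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
            bpr[w, tt] = pr
            bll[w, tt] = ll
            tot += pr + ll
        lp[w] = tot

    nkeep = 0
    if nsteps > burn:
        nkeep = (nsteps - burn + thin - 1) // thin
    out = np.empty((nkeep, W, D))
    outlp = np.empty((nkeep, W))
    prop = np.empty(D)
    newpr = np.empty(NB)
    newll = np.empty(NB)
    gamma0 = 2.38 / math.sqrt(2.0 * D)
    shift_scale = 0.2
    coll_scale = 0.5
    phi_scale = 0.2
    trial_scale = np.full(NB, 0.3)
    nq = 0
    for d in range(D):
        if kind[d] == 2:
            nq += 1
    q_idx = np.empty(nq, dtype=np.int64)
    q_scale = np.empty(nq)
    nq = 0
    for d in range(D):
        if kind[d] == 2:
            q_idx[nq] = d
            q_scale[nq] = 1.0
            nq += 1
    has_re_level = lev_act.shape[0] > 3 and lev_act[3] == 1
    iphi = gidx[G_PHI]
    ieta = lev_sig[3] if has_re_level else -1
    nacc = 0
    ksave = 0
    zero_cnt = np.zeros_like(ta_cnt)

    for step in range(nsteps):
        # ---- (a) global ensemble moves (two halves) ---------------------
        if use_global:
            for group in range(2):
                if group == 0:
                    lo, hi, clo, chi = 0, half, half, W
                else:
                    lo, hi, clo, chi = half, W, 0, half
                nc = chi - clo
                for w in range(lo, hi):
                    if np.random.random() < 0.5:
                        j = clo + np.random.randint(0, nc)
                        z = ((a_stretch - 1.0) * np.random.random() + 1.0) ** 2 / a_stretch
                        for d in range(D):
                            prop[d] = x[j, d] + z * (x[w, d] - x[j, d])
                        logfac = (D - 1) * math.log(z)
                    else:
                        ja = clo + np.random.randint(0, nc)
                        jb = clo + np.random.randint(0, nc - 1)
                        if jb >= ja:
                            jb += 1
                        if np.random.random() < 0.1:
                            gam = 1.0
                        else:
                            gam = gamma0 * (1.0 + 0.1 * np.random.standard_normal())
                        for d in range(D):
                            prop[d] = x[w, d] + gam * (x[ja, d] - x[jb, d])
                        logfac = 0.0
                    gnew = _global_prior(prop, kind, c_trial, moff, mlen,
                                         mfam, mlogw, mp1, mp2)
                    if gnew == _NEG_INF:
                        continue
                    tot = gnew
                    ok = True
                    for tt in range(NB):
                        pr, ll = _trial_block(
                            prop, tt, meta, gidx, t_u1, t_u2, t_u3, t_v,
                            t_mode1, t_mode2, t_mode3, t_modev, h_u1, h_u2,
                            h_mode, kind, moff, mlen, mfam, mlogw, mp1, mp2,
                            ta_off, ta_cnt, ta_idx, a_treat, a_m, a_ybase,
                            a_zbase, a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
                        if pr == _NEG_INF or ll == _NEG_INF:
                            ok = False
                            break
                        newpr[tt] = pr
                        newll[tt] = ll
                        tot += pr + ll
                    if not ok:
                        continue
                    logr = logfac + tot - lp[w]
                    if logr >= 0.0 or math.log(np.random.random()) < logr:
                        for d in range(D):
                            x[w, d] = prop[d]
                        gp[w] = gnew
                        for tt in range(NB):
                            bpr[w, tt] = newpr[tt]
                            bll[w, tt] = newll[tt]
                        lp[w] = tot
                        nacc += 1

        # ---- (b) trial-local refreshment --------------------------------
        for tt in range(NB):
            ncoord = tc_cnt[tt]
            if ncoord == 0:
                continue
            nrate = tcr_cnt[tt]
            nsh = 0
            for w in range(W):
                if nrate > 0:
                    delta = (trial_scale[tt]
                             * math.exp(0.8 * np.random.standard_normal())
                             * np.random.standard_normal())
                    for d in range(D):
                        prop[d] = x[w, d]
                    for k in range(nrate):
                        prop[tc_idx[tcr_off[tt] + k]] += delta
                    pr, ll = _trial_block(
                        prop, tt, meta, gidx, t_u1, t_u2, t_u3, t_v,
                        t_mode1, t_mode2, t_mode3, t_modev, h_u1, h_u2,
                        h_mode, kind, moff, mlen, mfam, mlogw, mp1, mp2,
                        ta_off, ta_cnt, ta_idx, a_treat, a_m, a_ybase,
                        a_zbase, a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
                    if pr > _NEG_INF and ll > _NEG_INF:
                        logr = pr + ll - bpr[w, tt] - bll[w, tt]
                        if logr >= 0.0 or math.log(np.random.random()) < logr:
                            for k in range(nrate):
                                dd = tc_idx[tcr_off[tt] + k]
                                x[w, dd] = prop[dd]
                            lp[w] += logr
                            bpr[w, tt] = pr
                            bll[w, tt] = ll
                            nsh += 1
                # single-coordinate move within the block
                dd = tc_idx[tc_off[tt] + np.random.randint(0, ncoord)]
                for d in range(D):
                    prop[d] = x[w, d]
                if W >= 4 and np.random.random() < 0.7:
                    ja = np.random.randint(0, W - 1)
                    if ja >= w:
                        ja += 1
                    jb = np.random.randint(0, W - 2)
                    if jb >= min(w, ja):
                        jb += 1
                    if jb >= max(w, ja):
                        jb += 1
                    diff = x[ja, dd] - x[jb, dd]
                    if diff == 0.0:
                        continue
                    gam = 1.68 * (1.0 + 0.3 * np.random.standard_normal())
                    prop[dd] = x[w, dd] + gam * diff
                else:
                    prop[dd] = (x[w, dd] + trial_scale[tt]
                                * math.exp(0.8 * np.random.standard_normal())
                                * np.random.standard_normal())
                pr, ll = _trial_block(
                    prop, tt, meta, gidx, t_u1, t_u2, t_u3, t_v,
                    t_mode1, t_mode2, t_mode3, t_modev, h_u1, h_u2,
                    h_mode, kind, moff, mlen, mfam, mlogw, mp1, mp2,
                    ta_off, ta_cnt, ta_idx, a_treat, a_m, a_ybase,
                    a_zbase, a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
                if pr > _NEG_INF and ll > _NEG_INF:
                    logr = pr + ll - bpr[w, tt] - bll[w, tt]
                    if logr >= 0.0 or math.log(np.random.random()) < logr:
                        x[w, dd] = prop[dd]
                        lp[w] += logr
                        bpr[w, tt] = pr
                        bll[w, tt] = ll
            if step < burn and nrate > 0:
                rate = nsh / W
                trial_scale[tt] *= math.exp(
                    0.5 * (rate - 0.35) / math.sqrt(1.0 + step))

        # ---- (c) Gibbs rejuvenation of shielded hyperparameters ---------
        any_gibbs = False
        for lev in range(lev_act.shape[0]):
            if lev_act[lev] == 0:
                continue
            any_gibbs = True
            inu = lev_nu[lev]
            isig = lev_sig[lev]
            for w in range(W):
                cur = x[w, inu]
                new, dlp = _slice_1d(
                    cur, cur, x[w, isig], False, x[w], lev_memb,
                    lev_off[lev], lev_cnt[lev], moff[inu], mlen[inu],
                    mfam, mlogw, mp1, mp2, 0.5)
                x[w, inu] = new
                lp[w] += dlp
                cur = x[w, isig]
                new, dlp = _slice_1d(
                    cur, x[w, inu], cur, True, x[w], lev_memb,
                    lev_off[lev], lev_cnt[lev], moff[isig], mlen[isig],
                    mfam, mlogw, mp1, mp2, 0.5)
                x[w, isig] = new
                lp[w] += dlp
        if any_gibbs:
            # refresh the prior-side caches (likelihoods are untouched by
            # hyperparameter moves because all members are centered)
            for w in range(W):
                gp[w] = _global_prior(x[w], kind, c_trial, moff, mlen,
                                      mfam, mlogw, mp1, mp2)
                tot = gp[w]
                for tt in range(NB):
                    pr, ll = _trial_block(
                        x[w], tt, meta, gidx, t_u1, t_u2, t_u3, t_v,
                        t_mode1, t_mode2, t_mode3, t_modev, h_u1, h_u2,
                        h_mode, kind, moff, mlen, mfam, mlogw, mp1, mp2,
                        ta_off, zero_cnt, ta_idx, a_treat, a_m,
                        a_ybase, a_zbase, a_nbase, a_r1, a_r2, a_tau,
                        a_coff, coef)
                    bpr[w, tt] = pr
                    tot += pr + bll[w, tt]
                lp[w] = tot

        # ---- (d) random-walk refresh of logit fatality probabilities ----
        # (every other sweep; the tail walk is slow but far from the HR)
        for qi in range(nq if step % 2 == 0 else 0):
            dq = q_idx[qi]
            nq_acc = 0
            for w in range(W):
                for d in range(D):
                    prop[d] = x[w, d]
                prop[dq] = (x[w, dq] + q_scale[qi]
                            * math.exp(0.8 * np.random.standard_normal())
                            * np.random.standard_normal())
                gnew = _global_prior(prop, kind, c_trial, moff, mlen,
                                     mfam, mlogw, mp1, mp2)
                if gnew == _NEG_INF:
                    continue
                tot = gnew
                ok = True
                for tt in range(NB):
                    pr, ll = _trial_block(
                        prop, tt, meta, gidx, t_u1, t_u2, t_u3, t_v,
                        t_mode1, t_mode2, t_mode3, t_modev, h_u1, h_u2,
                        h_mode, kind, moff, mlen, mfam, mlogw, mp1, mp2,
                        ta_off, ta_cnt, ta_idx, a_treat, a_m, a_ybase,
                        a_zbase, a_nbase, a_r1, a_r2, a_tau, a_coff, coef)
                    if pr == _NEG_INF or ll == _NEG_INF:
                        ok = False
                        break
                    newpr[tt] = pr
                    newll[tt] = ll
                    tot += pr + ll
                if not ok:
                    continue
                logr = tot - lp[w]
                if logr >= 0.0 or math.log(np.random.random()) < logr:
                    x[w, dq] = prop[dq]
                    gp[w] = gnew
                    for tt in range(NB):
                        bpr[w, tt] = newpr[tt]
                        bll[w, tt] = newll[tt]
                    lp[w] = tot
                    nq_acc += 1
            if step < burn:
                rate = nq_acc / W
                q_scale[qi] *= math.exp(0.5 * (rate - 0.35) / math.sqrt(1.0 + step))

        # ---- (e) overall log-HR moves -----------------------------------
        if iphi >= 0 and T > 0:
            all_anchor_direct = True
            for t in range(T):
                if t_mode1[t] == 0:
                    all_anchor_direct = False
            nsh_acc = 0
            nsc_acc = 0
            nmoves = 2
            for w in range(W):
                for rep in range(nmoves):
                    for d in range(D):
                        prop[d] = x[w, d]
                    if rep == 0:
                        # shift phi (and, in the RE model, every phi_i)
                        delta = ((shift_scale if has_re_level else phi_scale)
                                 * math.exp(0.8 * np.random.standard_normal())
                                 * np.random.standard_normal())
                        prop[iphi] += delta
                        if has_re_level:
                            for k in range(lev_cnt[3]):
                                prop[lev_memb[lev_off[3] + k]] += delta
                        logfac = 0.0
                    elif not has_re_level:
                        # CE: shift phi together with every anchor log
                        # hazard (moves one arm's rates, keeps the other's)
                        if not all_anchor_direct:
                            continue
                        delta = (phi_scale
                                 * math.exp(0.8 * np.random.standard_normal())
                                 * np.random.standard_normal())
                        prop[iphi] += delta
                        for t in range(T):
                            prop[t_u1[t]] += delta
                        logfac = 0.0
                    else:
                        # rescale eta and the phi_i fan jointly
                        eps = (coll_scale
                               * math.exp(0.8 * np.random.standard_normal())
                               * np.random.standard_normal())
                        c = math.exp(eps)
                        phi_cur = x[w, iphi]
                        prop[ieta] = x[w, ieta] * c
                        for k in range(lev_cnt[3]):
                            dd = lev_memb[lev_off[3] + k]
                            prop[dd] = phi_cur + c * (x[w, dd] - phi_cur)
                        logfac = (lev_cnt[3] + 1) * eps
                    gnew = _global_prior(prop, kind, c_trial, moff, mlen,
                                         mfam, mlogw, mp1, mp2)
                    if gnew == _NEG_INF:
                        continue
                    tot = gnew
                    ok = True
                    for tt in range(NB):
                        if tt < T:
                            pr, ll = _trial_block(
                                prop, tt, meta, gidx, t_u1, t_u2, t_u3, t_v,
                                t_mode1, t_mode2, t_mode3, t_modev, h_u1,
                                h_u2, h_mode, kind, moff, mlen, mfam, mlogw,
                                mp1, mp2, ta_off, ta_cnt, ta_idx, a_treat,
                                a_m, a_ybase, a_zbase, a_nbase, a_r1, a_r2,
                                a_tau, a_coff, coef)
                            if pr == _NEG_INF or ll == _NEG_INF:
                                ok = False
                                break
                            newpr[tt] = pr
                            newll[tt] = ll
                        else:
                            newpr[tt] = bpr[w, tt]
                            newll[tt] = bll[w, tt]
                        tot += newpr[tt] + newll[tt]
                    if not ok:
                        continue
                    logr = logfac + tot - lp[w]
                    if logr >= 0.0 or math.log(np.random.random()) < logr:
                        for d in range(D):
                            x[w, d] = prop[d]
                        gp[w] = gnew
                        for tt in range(NB):
                            bpr[w, tt] = newpr[tt]
                            bll[w, tt] = newll[tt]
                        lp[w] = tot
                        if rep == 0:
                            nsh_acc += 1
                        else:
                            nsc_acc += 1
            if step < burn:
                if has_re_level:
                    shift_scale *= math.exp(
                        0.5 * (nsh_acc / W - 0.35) / math.sqrt(1.0 + step))
                    coll_scale *= math.exp(
                        0.5 * (nsc_acc / W - 0.35) / math.sqrt(1.0 + step))
                else:
                    phi_scale *= math.exp(
                        0.5 * (nsh_acc / W - 0.35) / math.sqrt(1.0 + step))

        if step >= burn and (step - burn) % thin == 0:
            for w in range(W):
                for d in range(D):
                    out[ksave, w, d] = x[w, d]
                outlp[ksave, w] = lp[w]
            ksave += 1
    return out, outlp, nacc
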