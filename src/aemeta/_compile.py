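"""Flat-vector encoding of a (dataset, ModelSpec) pair for the MCMC kernels.

Hierarchical levels for the log event and drop-out hazards are sampled
*centered* by default (the aggregate counts pin the trial-level log rates
tightly, so the centered geometry is close to independent); the trial-level
log hazard ratios of the RE model, which are individually weakly
identified, are sampled *non-centered* (``phi_i = phi + eta * u_i`` with
standard-normal ``u_i``).  Fatality probabilities are sampled on the logit
scale with the beta prior's Jacobian correction; scales are sampled on
their natural nonnegative scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from .core import ArmAggregate, feasible_w3_range
from .hierarchy import HistoricalParams, ModelSpec, ParameterState, TrialParams
from .priors import PriorSpec
from . import _speed

_FAMILY_CODE = {"normal": 0, "half-normal": 1, "cauchy": 2, "beta": 3, "trunc-normal": 4}

_KIND_ALLOWED = {
    1: {"normal", "cauchy", "trunc-normal"},
    2: {"beta"},
    3: {"half-normal", "trunc-normal"},
}

# trial-level parameterization modes
MODE_NONCENTERED = 0
MODE_DIRECT = 1      # own (mixture) prior; stratified borrowing
MODE_CENTERED = 2


def _components(prior: PriorSpec):
    if prior.family == "mixture":
        return list(zip(prior.weights, prior.components))
    return [(1.0, prior)]


@dataclass
class CompiledModel:
    arms: list
    spec: ModelSpec
    main_ids: list
    hist_ids: list
    centered: bool = True
    names: list = field(default_factory=list)      # sampled coordinates
    _arrays: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @classmethod
    def build(cls, dataset, spec: ModelSpec,
              parameterization: str = "centered") -> "CompiledModel":
        if parameterization not in ("centered", "non-centered"):
            raise ValueError(f"unknown parameterization {parameterization!r}")
        arms = list(dataset)
        main_ids: list = []
        hist_ids: list = []
        for a in arms:
            pool = hist_ids if a.historical else main_ids
            if a.trial_id not in pool:
                pool.append(a.trial_id)
        self = cls(arms=arms, spec=spec, main_ids=main_ids, hist_ids=hist_ids,
                   centered=(parameterization == "centered"))
        self._build()
        return self

    # ------------------------------------------------------------------
    def _build(self) -> None:
        spec = self.spec
        T, H = len(self.main_ids), len(self.hist_ids)
        empty = len(self.arms) == 0
        stratified = spec.borrowing == "stratified"
        re = spec.random_effects
        hier_mode = MODE_CENTERED if self.centered else MODE_NONCENTERED
        hier_kind = 4 if self.centered else 0

        names: list[str] = []
        kinds: list[int] = []
        prior_of: list[PriorSpec | None] = []

        def add(name: str, kind: int, prior: PriorSpec | None) -> int:
            names.append(name)
            kinds.append(kind)
            prior_of.append(prior)
            return len(names) - 1

        gidx = -np.ones(10, dtype=np.int64)
        need = {
            "nu1": empty or H > 0 or (T > 0 and not stratified),
            "nu2": empty or H > 0 or (T > 0 and not stratified),
            "nu3": empty or T > 0,
            "q0": True,
            "q1": empty or T > 0,
            "phi": empty or T > 0,
            "eta": re and (empty or T > 0),
        }
        if need["nu1"]:
            gidx[_speed.G_NU1] = add("nu1", 1, spec.priors["nu1"])
            gidx[_speed.G_SIG1] = add("sigma1", 3, spec.priors["sigma1"])
        if need["nu2"]:
            gidx[_speed.G_NU2] = add("nu2", 1, spec.priors["nu2"])
            gidx[_speed.G_SIG2] = add("sigma2", 3, spec.priors["sigma2"])
        if need["nu3"]:
            gidx[_speed.G_NU3] = add("nu3", 1, spec.priors["nu3"])
            gidx[_speed.G_SIG3] = add("sigma3", 3, spec.priors["sigma3"])
        if need["q0"]:
            gidx[_speed.G_A0] = add("logit_q0", 2, spec.priors["q0"])
        if need["q1"]:
            gidx[_speed.G_A1] = add("logit_q1", 2, spec.priors["q1"])
        if need["phi"]:
            gidx[_speed.G_PHI] = add("phi", 1, spec.priors["phi"])
        if need["eta"]:
            gidx[_speed.G_ETA] = add("eta", 3, spec.priors["eta"])

        t_u1 = np.full(T, -1, dtype=np.int64)
        t_u2 = np.full(T, -1, dtype=np.int64)
        t_u3 = np.full(T, -1, dtype=np.int64)
        t_v = np.full(T, -1, dtype=np.int64)
        t_mode1 = np.zeros(T, dtype=np.int64)
        t_mode2 = np.zeros(T, dtype=np.int64)
        t_mode3 = np.zeros(T, dtype=np.int64)
        t_modev = np.zeros(T, dtype=np.int64)
        for t, tid in enumerate(self.main_ids):
            if stratified:
                t_mode1[t] = MODE_DIRECT
                t_u1[t] = add(f"c_lambda[{tid}]", 1,
                              spec.trial_level_priors["log_lambda_control"])
                t_mode2[t] = MODE_DIRECT
                t_u2[t] = add(f"c_mu0[{tid}]", 1,
                              spec.trial_level_priors["log_mu_control"])
            else:
                t_mode1[t] = hier_mode
                t_u1[t] = add(f"c_lambda[{tid}]" if self.centered else f"u_lambda[{tid}]",
                              hier_kind, None)
                t_mode2[t] = hier_mode
                t_u2[t] = add(f"c_mu0[{tid}]" if self.centered else f"u_mu0[{tid}]",
                              hier_kind, None)
            t_mode3[t] = hier_mode
            t_u3[t] = add(f"c_mu1[{tid}]" if self.centered else f"u_mu1[{tid}]",
                          hier_kind, None)
            if re:
                t_modev[t] = hier_mode
                t_v[t] = add(f"c_phi[{tid}]" if self.centered else f"u_phi[{tid}]",
                             hier_kind, None)

        h_u1 = np.full(H, -1, dtype=np.int64)
        h_u2 = np.full(H, -1, dtype=np.int64)
        h_mode = np.full(H, hier_mode, dtype=np.int64)
        for h, hid in enumerate(self.hist_ids):
            h_u1[h] = add(f"c_lambda[{hid}]" if self.centered else f"u_lambda[{hid}]",
                          hier_kind, None)
            h_u2[h] = add(f"c_mu0[{hid}]" if self.centered else f"u_mu0[{hid}]",
                          hier_kind, None)

        # coordinate -> trial-block map and per-block coordinate lists
        c_trial = np.full(len(names), -1, dtype=np.int64)
        tc_idx: list[int] = []
        tc_off = np.zeros(T + H, dtype=np.int64)
        tc_cnt = np.zeros(T + H, dtype=np.int64)
        tcr_cnt = np.zeros(T + H, dtype=np.int64)
        for t in range(T):
            rate, other = [], []
            for idx, mode in ((t_u1[t], t_mode1[t]), (t_u2[t], t_mode2[t]),
                              (t_u3[t], t_mode3[t])):
                (rate if mode != MODE_NONCENTERED else other).append(int(idx))
            if re:
                other.append(int(t_v[t]))
            tc_off[t] = len(tc_idx)
            tc_cnt[t] = len(rate) + len(other)
            tcr_cnt[t] = len(rate)
            tc_idx.extend(rate + other)
            for idx in rate + other:
                c_trial[idx] = t
        for h in range(H):
            coords = [int(h_u1[h]), int(h_u2[h])]
            tc_off[T + h] = len(tc_idx)
            tc_cnt[T + h] = 2
            tcr_cnt[T + h] = 2 if h_mode[h] != MODE_NONCENTERED else 0
            tc_idx.extend(coords)
            for idx in coords:
                c_trial[idx] = T + h

        # arms per trial block
        ta_idx: list[int] = []
        ta_off = np.zeros(T + H, dtype=np.int64)
        ta_cnt = np.zeros(T + H, dtype=np.int64)

        # mixture tables
        moff = np.zeros(len(names), dtype=np.int64)
        mlen = np.zeros(len(names), dtype=np.int64)
        mfam: list[int] = []
        mlogw: list[float] = []
        mp1: list[float] = []
        mp2: list[float] = []
        for d, (k, prior) in enumerate(zip(kinds, prior_of)):
            if k in (0, 4):
                continue
            if prior is None:
                raise ValueError(f"coordinate {names[d]} needs a prior")
            comps = _components(prior)
            moff[d] = len(mfam)
            mlen[d] = len(comps)
            for w, c in comps:
                if c.family not in _KIND_ALLOWED[k]:
                    raise ValueError(
                        f"prior family {c.family!r} is not valid for parameter "
                        f"{names[d]!r} (support mismatch)")
                mfam.append(_FAMILY_CODE[c.family])
                mlogw.append(math.log(w) if w > 0 else -math.inf)
                if c.family == "half-normal":
                    mp1.append(c.params[0])
                    mp2.append(0.0)
                else:
                    mp1.append(c.params[0])
                    mp2.append(c.params[1])

        # arm data arrays
        A = len(self.arms)
        trial_pos = {tid: t for t, tid in enumerate(self.main_ids)}
        trial_pos.update({hid: T + h for h, hid in enumerate(self.hist_ids)})
        a_trial = np.zeros(A, dtype=np.int64)
        a_treat = np.zeros(A, dtype=np.int64)
        a_m = np.zeros(A, dtype=np.int64)
        a_ybase = np.zeros(A, dtype=np.int64)
        a_zbase = np.zeros(A, dtype=np.int64)
        a_nbase = np.zeros(A, dtype=np.int64)
        a_r1 = np.zeros(A, dtype=np.int64)
        a_r2 = np.zeros(A, dtype=np.int64)
        a_tau = np.zeros(A)
        a_coff = np.zeros(A, dtype=np.int64)
        coef: list[float] = []
        for i, arm in enumerate(self.arms):
            a_trial[i] = trial_pos[arm.trial_id]
            a_treat[i] = arm.arm
            a_m[i] = arm.m
            a_ybase[i] = arm.y - arm.m
            a_zbase[i] = arm.z - arm.m
            a_nbase[i] = arm.n - arm.y - arm.z + arm.m
            r1, r2 = feasible_w3_range(arm)
            a_r1[i], a_r2[i] = r1, r2
            a_tau[i] = arm.tau
            a_coff[i] = len(coef)
            base = gammaln(arm.n + 1) - gammaln(arm.m + 1)
            for r in range(r1, r2 + 1):
                coef.append(float(
                    base
                    - gammaln(arm.y - arm.m - r + 1)
                    - gammaln(r + 1)
                    - gammaln(arm.n - arm.y - arm.z + arm.m + r + 1)
                    - gammaln(arm.z - arm.m - r + 1)
                ))

        for tt in range(T + H):
            ta_off[tt] = len(ta_idx)
            for i in range(A):
                if a_trial[i] == tt:
                    ta_idx.append(i)
                    ta_cnt[tt] += 1

        self.names = names
        self._arrays = {
            "meta": np.array([T, H, 0 if spec.anchor == "control" else 1,
                              1 if re else 0, len(names)], dtype=np.int64),
            "gidx": gidx,
            "t_u1": t_u1, "t_u2": t_u2, "t_u3": t_u3, "t_v": t_v,
            "t_mode1": t_mode1, "t_mode2": t_mode2, "t_mode3": t_mode3,
            "t_modev": t_modev,
            "h_u1": h_u1, "h_u2": h_u2, "h_mode": h_mode,
            "kind": np.array(kinds, dtype=np.int64),
            "c_trial": c_trial,
            "tc_off": tc_off, "tc_cnt": tc_cnt,
            "tc_idx": np.array(tc_idx, dtype=np.int64),
            "tcr_cnt": tcr_cnt,
            "ta_off": ta_off, "ta_cnt": ta_cnt,
            "ta_idx": np.array(ta_idx, dtype=np.int64),
            "moff": moff, "mlen": mlen,
            "mfam": np.array(mfam, dtype=np.int64),
            "mlogw": np.array(mlogw, dtype=float),
            "mp1": np.array(mp1, dtype=float),
            "mp2": np.array(mp2, dtype=float),
            "a_trial": a_trial, "a_treat": a_treat, "a_m": a_m,
            "a_ybase": a_ybase, "a_zbase": a_zbase, "a_nbase": a_nbase,
            "a_r1": a_r1, "a_r2": a_r2, "a_tau": a_tau, "a_coff": a_coff,
            "coef": np.array(coef, dtype=float),
        }
        # Gibbs-rejuvenation levels: hyperparameter pairs whose members are
        # all centered (hence conditionally independent of the likelihood)
        lev_act = np.zeros(4, dtype=np.int64)
        lev_nu = np.full(4, -1, dtype=np.int64)
        lev_sig = np.full(4, -1, dtype=np.int64)
        lev_off = np.zeros(4, dtype=np.int64)
        lev_cnt = np.zeros(4, dtype=np.int64)
        memb: list[int] = []
        levels = [
            (_speed.G_NU1, _speed.G_SIG1,
             [t_u1[t] for t in range(T) if t_mode1[t] == MODE_CENTERED]
             + [h_u1[h] for h in range(H) if h_mode[h] == MODE_CENTERED],
             all(t_mode1[t] != MODE_NONCENTERED for t in range(T))
             and all(h_mode[h] != MODE_NONCENTERED for h in range(H))),
            (_speed.G_NU2, _speed.G_SIG2,
             [t_u2[t] for t in range(T) if t_mode2[t] == MODE_CENTERED]
             + [h_u2[h] for h in range(H) if h_mode[h] == MODE_CENTERED],
             all(t_mode2[t] != MODE_NONCENTERED for t in range(T))
             and all(h_mode[h] != MODE_NONCENTERED for h in range(H))),
            (_speed.G_NU3, _speed.G_SIG3,
             [t_u3[t] for t in range(T) if t_mode3[t] == MODE_CENTERED],
             all(t_mode3[t] != MODE_NONCENTERED for t in range(T))),
            (_speed.G_PHI, _speed.G_ETA,
             [t_v[t] for t in range(T) if re and t_modev[t] == MODE_CENTERED],
             re and all(t_modev[t] != MODE_NONCENTERED for t in range(T))),
        ]
        for L, (gnu, gsig, members, shielded) in enumerate(levels):
            if (shielded and members and gidx[gnu] >= 0 and gidx[gsig] >= 0):
                lev_act[L] = 1
                lev_nu[L] = gidx[gnu]
                lev_sig[L] = gidx[gsig]
                lev_off[L] = len(memb)
                lev_cnt[L] = len(members)
                memb.extend(int(m) for m in members)
        self._arrays.update({
            "lev_act": lev_act, "lev_nu": lev_nu, "lev_sig": lev_sig,
            "lev_off": lev_off, "lev_cnt": lev_cnt,
            "lev_memb": np.array(memb, dtype=np.int64),
        })
        self._prior_of = prior_of
        self._kinds = kinds

    # ------------------------------------------------------------------
    @property
    def dim(self) -> int:
        return len(self.names)

    def gibbs_args(self) -> tuple:
        a = self._arrays
        return (a["lev_act"], a["lev_nu"], a["lev_sig"], a["lev_off"],
                a["lev_cnt"], a["lev_memb"],
                a["tc_off"], a["tc_cnt"], a["tc_idx"], a["tc_off"],
                a["tcr_cnt"])

    def kernel_args(self) -> tuple:
        a = self._arrays
        return (a["meta"], a["gidx"], a["t_u1"], a["t_u2"], a["t_u3"], a["t_v"],
                a["t_mode1"], a["t_mode2"], a["t_mode3"], a["t_modev"],
                a["h_u1"], a["h_u2"], a["h_mode"],
                a["kind"], a["c_trial"], a["moff"], a["mlen"], a["mfam"],
                a["mlogw"], a["mp1"], a["mp2"],
                a["ta_off"], a["ta_cnt"], a["ta_idx"],
                a["a_treat"], a["a_m"], a["a_ybase"], a["a_zbase"],
                a["a_nbase"], a["a_r1"], a["a_r2"], a["a_tau"], a["a_coff"],
                a["coef"])

    def log_posterior(self, theta: np.ndarray) -> float:
        """Compiled unnormalized log posterior at a flat parameter vector."""
        return float(_speed._log_posterior(np.asarray(theta, dtype=float),
                                           *self.kernel_args()))

    # ------------------------------------------------------------------
    def derived(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Natural-scale named parameters for a draw matrix (ndraw, dim)."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        g = self._arrays["gidx"]
        out: dict[str, np.ndarray] = {}
        pairs = [("nu1", _speed.G_NU1), ("sigma1", _speed.G_SIG1),
                 ("nu2", _speed.G_NU2), ("sigma2", _speed.G_SIG2),
                 ("nu3", _speed.G_NU3), ("sigma3", _speed.G_SIG3),
                 ("phi", _speed.G_PHI), ("eta", _speed.G_ETA)]
        for name, slot in pairs:
            if g[slot] >= 0:
                out[name] = theta[:, g[slot]]
        if g[_speed.G_A0] >= 0:
            out["q0"] = expit(theta[:, g[_speed.G_A0]])
        if g[_speed.G_A1] >= 0:
            out["q1"] = expit(theta[:, g[_speed.G_A1]])

        a = self._arrays
        nu1 = out.get("nu1", 0.0)
        sig1 = out.get("sigma1", 0.0)
        nu2 = out.get("nu2", 0.0)
        sig2 = out.get("sigma2", 0.0)
        nu3 = out.get("nu3", 0.0)
        sig3 = out.get("sigma3", 0.0)
        phi = out.get("phi", 0.0)
        eta = out.get("eta", 0.0)
        for t, tid in enumerate(self.main_ids):
            anc = (nu1 + sig1 * theta[:, a["t_u1"][t]]
                   if a["t_mode1"][t] == MODE_NONCENTERED else theta[:, a["t_u1"][t]])
            lmu0 = (nu2 + sig2 * theta[:, a["t_u2"][t]]
                    if a["t_mode2"][t] == MODE_NONCENTERED else theta[:, a["t_u2"][t]])
            lmu1 = (nu3 + sig3 * theta[:, a["t_u3"][t]]
                    if a["t_mode3"][t] == MODE_NONCENTERED else theta[:, a["t_u3"][t]])
            if self.spec.random_effects:
                ph = (phi + eta * theta[:, a["t_v"][t]]
                      if a["t_modev"][t] == MODE_NONCENTERED
                      else theta[:, a["t_v"][t]])
                out[f"phi_i[{tid}]"] = ph
            else:
                ph = phi
            if self.spec.anchor == "control":
                out[f"log_lambda0[{tid}]"] = anc
                out[f"log_lambda1[{tid}]"] = anc + ph
            else:
                out[f"log_lambda1[{tid}]"] = anc
                out[f"log_lambda0[{tid}]"] = anc - ph
            out[f"log_mu0[{tid}]"] = lmu0
            out[f"log_mu1[{tid}]"] = lmu1
        for h, hid in enumerate(self.hist_ids):
            if a["h_mode"][h] == MODE_NONCENTERED:
                out[f"log_lambda0[{hid}]"] = nu1 + sig1 * theta[:, a["h_u1"][h]]
                out[f"log_mu0[{hid}]"] = nu2 + sig2 * theta[:, a["h_u2"][h]]
            else:
                out[f"log_lambda0[{hid}]"] = theta[:, a["h_u1"][h]]
                out[f"log_mu0[{hid}]"] = theta[:, a["h_u2"][h]]
        return out

    def unpack_state(self, theta: np.ndarray) -> ParameterState:
        """Explicit :class:`ParameterState` for a single flat vector."""
        d = self.derived(np.asarray(theta, dtype=float)[None, :])
        sc = {k: float(v[0]) for k, v in d.items() if "[" not in k}
        state = ParameterState(
            q0=sc.get("q0", 0.5), q1=sc.get("q1"),
            phi=sc.get("phi"), eta=sc.get("eta"),
            nu1=sc.get("nu1"), sigma1=sc.get("sigma1"),
            nu2=sc.get("nu2"), sigma2=sc.get("sigma2"),
            nu3=sc.get("nu3"), sigma3=sc.get("sigma3"),
        )
        for tid in self.main_ids:
            if self.spec.anchor == "control":
                anchor = float(d[f"log_lambda0[{tid}]"][0])
            else:
                anchor = float(d[f"log_lambda1[{tid}]"][0])
            state.trials[tid] = TrialParams(
                log_lambda_anchor=anchor,
                log_mu0=float(d[f"log_mu0[{tid}]"][0]),
                log_mu1=float(d[f"log_mu1[{tid}]"][0]),
                phi_i=(float(d[f"phi_i[{tid}]"][0])
                       if self.spec.random_effects else sc.get("phi")),
            )
        for hid in self.hist_ids:
            state.historical[hid] = HistoricalParams(
                log_lambda0=float(d[f"log_lambda0[{hid}]"][0]),
                log_mu0=float(d[f"log_mu0[{hid}]"][0]),
            )
        return state

    def noncentering_jacobian(self, theta: np.ndarray) -> float:
        """log |d(natural)/d(sampled)| between the sampled coordinates and
        the centered natural-scale state (used when comparing the compiled
        density with the centered reference density)."""
        theta = np.asarray(theta, dtype=float)
        a = self._arrays
        g = self._arrays["gidx"]
        jac = 0.0
        T, H = len(self.main_ids), len(self.hist_ids)

        def sig(slot):
            return theta[g[slot]] if g[slot] >= 0 else 0.0

        for t in range(T):
            if a["t_mode1"][t] == MODE_NONCENTERED:
                jac += math.log(abs(sig(_speed.G_SIG1)))
            if a["t_mode2"][t] == MODE_NONCENTERED:
                jac += math.log(abs(sig(_speed.G_SIG2)))
            if a["t_mode3"][t] == MODE_NONCENTERED:
                jac += math.log(abs(sig(_speed.G_SIG3)))
            if self.spec.random_effects and a["t_modev"][t] == MODE_NONCENTERED:
                jac += math.log(abs(sig(_speed.G_ETA)))
        for h in range(H):
            if a["h_mode"][h] == MODE_NONCENTERED:
                jac += math.log(abs(sig(_speed.G_SIG1)))
                jac += math.log(abs(sig(_speed.G_SIG2)))
        for slot in (_speed.G_A0, _speed.G_A1):
            if g[slot] >= 0:
                q = expit(theta[g[slot]])
                jac += math.log(q) + math.log1p(-q)
        return jac

    # ------------------------------------------------------------------
    def initial_walkers(self, rng: np.random.Generator, nwalkers: int,
                        max_tries: int = 200) -> np.ndarray:
        """Overdispersed starting ensemble with finite posterior density."""
        center = self._center_guess(rng)
        W = nwalkers
        D = self.dim
        x = np.empty((W, D))
        for w in range(W):
            x[w] = self._jitter(center, rng)
        for w in range(W):
            tries = 0
            while not np.isfinite(self.log_posterior(x[w])):
                x[w] = self._jitter(center, rng)
                tries += 1
                if tries > max_tries:
                    raise RuntimeError(
                        "could not find a finite-density starting point; "
                        "check data/prior consistency")
        return x

    def _center_guess(self, rng: np.random.Generator) -> np.ndarray:
        a = self._arrays
        g = a["gidx"]
        center = np.zeros(self.dim)
        lam_hat = {}
        mu_hat = {}
        for arm in self.arms:
            n = max(arm.n, 1)
            lam_hat[(arm.trial_id, arm.arm)] = (arm.y + 0.5) / (n * arm.tau)
            mu_hat[(arm.trial_id, arm.arm)] = (arm.z + 0.5) / (n * arm.tau)
        anchor_arm = 0 if self.spec.anchor == "control" else 1
        anchor_logs = [math.log(lam_hat[(tid, anchor_arm)])
                       for tid in self.main_ids if (tid, anchor_arm) in lam_hat]
        anchor_logs += [math.log(lam_hat[(hid, 0)]) for hid in self.hist_ids]
        mu0_logs = [math.log(v) for (tid, j), v in mu_hat.items() if j == 0]
        mu1_logs = [math.log(v) for (tid, j), v in mu_hat.items() if j == 1]
        nu1c = float(np.mean(anchor_logs)) if anchor_logs else -1.0
        nu2c = float(np.mean(mu0_logs)) if mu0_logs else -1.0
        nu3c = float(np.mean(mu1_logs)) if mu1_logs else -1.0
        phis = []
        for tid in self.main_ids:
            if (tid, 0) in lam_hat and (tid, 1) in lam_hat:
                phis.append(math.log(lam_hat[(tid, 1)]) - math.log(lam_hat[(tid, 0)]))
        phic = float(np.mean(phis)) if phis else 0.0
        my = sum(arm.m for arm in self.arms)
        yy = sum(arm.y for arm in self.arms)
        qc = logit(min(max((my + 0.5) / (yy + 1.0), 1e-3), 1 - 1e-3))

        def setg(slot, val):
            if g[slot] >= 0:
                center[g[slot]] = val

        setg(_speed.G_NU1, nu1c)
        setg(_speed.G_SIG1, 0.4)
        setg(_speed.G_NU2, nu2c)
        setg(_speed.G_SIG2, 0.4)
        setg(_speed.G_NU3, nu3c)
        setg(_speed.G_SIG3, 0.4)
        setg(_speed.G_A0, qc)
        setg(_speed.G_A1, qc)
        setg(_speed.G_PHI, phic)
        setg(_speed.G_ETA, 0.2)

        def tl_center(mode, crude_log, hyper_center):
            if mode == MODE_NONCENTERED:
                return float(np.clip((crude_log - hyper_center) / 0.4, -2.5, 2.5))
            return crude_log

        for t, tid in enumerate(self.main_ids):
            crude = math.log(lam_hat.get((tid, anchor_arm), math.exp(nu1c)))
            center[a["t_u1"][t]] = tl_center(a["t_mode1"][t], crude, nu1c)
            crude = math.log(mu_hat.get((tid, 0), math.exp(nu2c)))
            center[a["t_u2"][t]] = tl_center(a["t_mode2"][t], crude, nu2c)
            crude = math.log(mu_hat.get((tid, 1), math.exp(nu3c)))
            center[a["t_u3"][t]] = tl_center(a["t_mode3"][t], crude, nu3c)
            if self.spec.random_effects:
                center[a["t_v"][t]] = (0.0 if a["t_modev"][t] == MODE_NONCENTERED
                                       else phic)
        for h, hid in enumerate(self.hist_ids):
            crude = math.log(lam_hat.get((hid, 0), math.exp(nu1c)))
            center[a["h_u1"][h]] = tl_center(a["h_mode"][h], crude, nu1c)
            crude = math.log(mu_hat.get((hid, 0), math.exp(nu2c)))
            center[a["h_u2"][h]] = tl_center(a["h_mode"][h], crude, nu2c)

        # prior-only coordinates: start near a draw from the prior
        if not self.arms:
            for d, (k, prior) in enumerate(zip(self._kinds, self._prior_of)):
                if prior is None:
                    continue
                draw = float(prior.rvs(rng, 1)[0])
                if k == 2:
                    draw = float(logit(min(max(draw, 1e-4), 1 - 1e-4)))
                elif k == 3:
                    draw = abs(draw)
                center[d] = draw
        return center

    def _jitter(self, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = center + 0.1 * rng.standard_normal(center.shape)
        for d, k in enumerate(self._kinds):
            if k == 3:
                x[d] = abs(x[d]) + 1e-4
        return x
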