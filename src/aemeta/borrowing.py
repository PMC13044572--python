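"""Meta-analytic-predictive (MAP) borrowing from historical control arms.

Workflow: fit the control-only hierarchical model to the historical trials
(:func:`fit_historical`), form the predictive quantities
(:func:`map_predictive`) — either the hyperparameter posterior itself
(*non-stratified*, allowing cross-trial shrinkage in the main analysis) or
the marginal new-trial predictive for the trial-level control parameters
(*stratified*) — approximate each margin by a small parametric mixture
(:func:`fit_mixture`), optionally mix in a vague component
(:func:`robustify`, weights 50/80/100% of the informative part), and inject
the result into a :class:`~aemeta.hierarchy.ModelSpec` via
:func:`with_borrowing`.

By default the joint hyperparameter posterior is approximated by
*independent* univariate mixtures (standard MAP practice);
:func:`map_predictive` also exposes the raw joint draws for sensitivity
analyses that wish to preserve correlations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .hierarchy import ModelSpec
from .inference import McmcConfig, PosteriorSamples, sample_posterior
from .priors import PriorSpec, vague_prior

__all__ = [
    "MixtureApprox",
    "fit_historical",
    "map_predictive",
    "fit_mixture",
    "robustify",
    "derive_map_priors",
    "with_borrowing",
]

#: hyperparameters informed by historical control data
MAP_PARAMETERS = ("nu1", "sigma1", "nu2", "sigma2", "q0")

_SUPPORTS = {"real", "positive", "unit"}


@dataclass(frozen=True)
class MixtureApprox:
    """Parametric mixture approximation of a posterior/predictive margin."""

    parameter: str
    prior: PriorSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prior.family != "mixture":
            object.__setattr__(
                self, "prior",
                PriorSpec.mixture([self.prior], [1.0]))

    @property
    def components(self):
        return self.prior.components

    @property
    def weights(self):
        return self.prior.weights

    def logpdf(self, x):
        return self.prior.logpdf(x)

    def pdf(self, x):
        return self.prior.pdf(x)

    def cdf(self, x):
        return self.prior.cdf(x)

    def rvs(self, rng, size=1):
        return self.prior.rvs(rng, size)

    def to_json(self) -> str:
        return json.dumps({"parameter": self.parameter,
                           "prior": self.prior.to_dict(),
                           "provenance": self.provenance})

    @classmethod
    def from_json(cls, s: str) -> "MixtureApprox":
        d = json.loads(s)
        return cls(d["parameter"], PriorSpec.from_dict(d["prior"]),
                   d.get("provenance", {}))


def fit_historical(dataset, config: McmcConfig,
                   spec: ModelSpec | None = None) -> PosteriorSamples:
    """Posterior of (nu1, sigma1, nu2, sigma2, q0) from historical controls.

    ``dataset`` may contain main-trial arms; only historical arms are used.
    At least two historical trials are required for the hierarchy to be
    identifiable.
    """
    hist = [a for a in dataset if a.historical]
    if len({a.trial_id for a in hist}) < 2:
        raise ValueError("MAP derivation needs at least 2 historical trials")
    if spec is None:
        spec = ModelSpec.vague("common", anchor="control")
    return sample_posterior(hist, spec, config)


def map_predictive(samples: PosteriorSamples, mode: str = "non-stratified",
                   rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Predictive draws for borrowing into the main analysis.

    non-stratified
        The hyperparameter posterior draws themselves
        (``nu1, sigma1, nu2, sigma2, q0``).
    stratified
        New-trial predictive draws ``log_lambda0_new = nu1 + sigma1 * N(0,1)``
        and ``log_mu0_new = nu2 + sigma2 * N(0,1)`` integrated over the
        hyperparameter posterior, plus ``q0``.
    """
    if mode not in ("stratified", "non-stratified"):
        raise ValueError(f"unknown MAP mode {mode!r}")
    pooled = {p: samples.pooled(p) for p in MAP_PARAMETERS}
    if mode == "non-stratified":
        return pooled
    rng = rng or np.random.default_rng(0)
    n = len(pooled["nu1"])
    return {
        "log_lambda0_new": pooled["nu1"] + pooled["sigma1"] * rng.standard_normal(n),
        "log_mu0_new": pooled["nu2"] + pooled["sigma2"] * rng.standard_normal(n),
        "q0": pooled["q0"],
    }


# ---------------------------------------------------------------------------
# mixture approximation


def _beta_from_moments(mean: float, var: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    var = min(max(var, 1e-12), mean * (1 - mean) * 0.999)
    nu = mean * (1 - mean) / var - 1.0
    return max(mean * nu, 1e-3), max((1 - mean) * nu, 1e-3)


def _fit_beta_mixture(x: np.ndarray, max_components: int, seed: int = 0):
    """Small EM for a beta mixture with moment-matching M-step; BIC selection."""
    x = np.clip(x, 1e-9, 1 - 1e-9)
    n = len(x)
    best = None
    rng = np.random.default_rng(seed)
    for k in range(1, max_components + 1):
        # init from quantile bins
        qs = np.quantile(x, np.linspace(0, 1, k + 1))
        params = []
        weights = np.full(k, 1.0 / k)
        for j in range(k):
            sel = x[(x >= qs[j]) & (x <= qs[j + 1])]
            if len(sel) < 2:
                sel = x
            params.append(_beta_from_moments(sel.mean(), max(sel.var(), 1e-10)))
        ll = -np.inf
        for _ in range(200):
            logp = np.array([math.log(max(w, 1e-300))
                             + stats.beta.logpdf(x, a, b)
                             for w, (a, b) in zip(weights, params)])
            mx = logp.max(axis=0)
            lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
            new_ll = lse.sum()
            resp = np.exp(logp - lse)
            weights = resp.mean(axis=1)
            params = []
            for j in range(k):
                r = resp[j]
                tot = r.sum()
                mean = float((r * x).sum() / tot)
                var = float((r * (x - mean) ** 2).sum() / tot)
                params.append(_beta_from_moments(mean, var))
            if new_ll - ll < 1e-8 * n:
                ll = new_ll
                break
            ll = new_ll
        bic = -2 * ll + (3 * k - 1) * math.log(n)
        if best is None or bic < best[0]:
            best = (bic, weights.copy(), list(params), ll)
    bic, weights, params, ll = best
    comps = [PriorSpec.beta(a, b) for a, b in params]
    return comps, weights / weights.sum(), bic


def fit_mixture(draws: np.ndarray, support: str = "real",
                max_components: int = 3, seed: int = 0,
                parameter: str = "") -> MixtureApprox:
    """Approximate a sample by a small mixture on the appropriate scale.

    ``support``: "real" -> normal components; "positive" -> normal
    components truncated at 0; "unit" -> beta components.  Component count
    up to ``max_components`` is selected by BIC; the Kolmogorov-Smirnov
    distance between the draws and the fitted mixture CDF is recorded in
    the provenance.
    """
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if len(draws) < 1000:
        raise ValueError(f"need >= 1000 draws to fit a MAP mixture, got {len(draws)}")
    if support not in _SUPPORTS:
        raise ValueError(f"support must be one of {sorted(_SUPPORTS)}")

    sd = draws.std()
    prov: dict = {"n_draws": int(len(draws)), "support": support}
    if sd < 1e-8:
        prov["warning"] = "degenerate draws; point-like single component"
        if support == "unit":
            comp = PriorSpec.beta(*_beta_from_moments(float(draws.mean()), 1e-10))
        elif support == "positive":
            comp = PriorSpec("trunc-normal", (float(draws.mean()), max(sd, 1e-6)))
        else:
            comp = PriorSpec.normal(float(draws.mean()), max(sd, 1e-6))
        prov["n_components"] = 1
        return MixtureApprox(parameter, PriorSpec.mixture([comp], [1.0]), prov)

    if support == "unit":
        comps, weights, bic = _fit_beta_mixture(draws, max_components, seed)
    else:
        best = None
        for k in range(1, max_components + 1):
            gm = GaussianMixture(n_components=k, random_state=seed, n_init=2)
            gm.fit(draws[:, None])
            bic = gm.bic(draws[:, None])
            if best is None or bic < best[0]:
                best = (bic, gm)
        bic, gm = best
        fam = "normal" if support == "real" else "trunc-normal"
        comps = [PriorSpec(fam, (float(m), float(max(math.sqrt(v), 1e-8))))
                 for m, v in zip(gm.means_.ravel(), gm.covariances_.ravel())]
        weights = gm.weights_
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    mix = PriorSpec.mixture(comps, weights)
    approx = MixtureApprox(parameter, mix, prov)
    ks = stats.kstest(draws, approx.cdf).statistic
    prov.update({"n_components": len(comps), "bic": float(bic), "ks": float(ks)})
    return approx


def robustify(map_approx: MixtureApprox, weight: float,
              vague: PriorSpec | None = None) -> MixtureApprox:
    """Mix the informative MAP with a vague component:
    ``weight * MAP + (1 - weight) * vague``; ``weight = 1`` is a no-op."""
    if not 0.0 < weight <= 1.0:
        raise ValueError(f"robustification weight must lie in (0, 1], got {weight}")
    if weight == 1.0:
        return map_approx
    if vague is None:
        sup = map_approx.provenance.get("support", "real")
        vague = vague_prior({"real": "location", "positive": "scale",
                             "unit": "proportion"}[sup])
    comps = list(map_approx.components) + [vague]
    weights = [w * weight for w in map_approx.weights] + [1.0 - weight]
    prov = dict(map_approx.provenance)
    prov["robust_weight"] = weight
    return MixtureApprox(map_approx.parameter,
                         PriorSpec.mixture(comps, weights), prov)


# ---------------------------------------------------------------------------
# end-to-end derivation


_PARAM_SUPPORT = {"nu1": "real", "sigma1": "positive", "nu2": "real",
                  "sigma2": "positive", "q0": "unit",
                  "log_lambda0_new": "real", "log_mu0_new": "real"}


def derive_map_priors(dataset, config: McmcConfig, mode: str = "non-stratified",
                      weight: float = 1.0, max_components: int = 3,
                      seed: int = 0) -> dict[str, MixtureApprox]:
    """Historical fit -> predictive -> mixture fit -> robustification."""
    samples = fit_historical(dataset, config)
    pred = map_predictive(samples, mode, rng=np.random.default_rng(seed + 1))
    out = {}
    for name, draws in pred.items():
        approx = fit_mixture(draws, _PARAM_SUPPORT[name], max_components,
                             seed=seed, parameter=name)
        out[name] = robustify(approx, weight)
    return out


def with_borrowing(spec: ModelSpec, mixtures: dict[str, MixtureApprox],
                   mode: str = "non-stratified") -> ModelSpec:
    """Inject MAP mixtures into a model specification.

    Non-stratified: replaces the hyperpriors for nu1, sigma1, nu2, sigma2
    and q0.  Stratified: sets direct trial-level priors for the per-trial
    control parameters (no cross-trial shrinkage) and the q0 prior.
    """
    if mode == "non-stratified":
        updates = {k: m.prior for k, m in mixtures.items() if k in MAP_PARAMETERS}
        return replace(spec, borrowing="non-stratified",
                       priors={**spec.priors, **updates})
    if mode == "stratified":
        tlp = {"log_lambda_control": mixtures["log_lambda0_new"].prior,
               "log_mu_control": mixtures["log_mu0_new"].prior}
        priors = dict(spec.priors)
        if "q0" in mixtures:
            priors["q0"] = mixtures["q0"].prior
        return replace(spec, borrowing="stratified", priors=priors,
                       trial_level_priors=tlp)
    raise ValueError(f"unknown MAP mode {mode!r}")
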