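"""Hierarchical common-effect (CE) and random-effects (RE) models over trials.

The meta-analysis comprises ``I`` two-armed trials (control arm ``j=0``,
treatment arm ``j=1``) and optionally ``H`` single-arm historical control
trials.  Trial-level nuisance parameters are exchangeable on the log scale::

    log(lambda_anchor_i) ~ Normal(nu1, sigma1^2)
    log(mu_i0)           ~ Normal(nu2, sigma2^2)
    log(mu_i1)           ~ Normal(nu3, sigma3^2)

where the *anchor* arm is the control arm (``log lambda_i1 = log lambda_i0
+ phi_i``) or, for heterogeneous-control settings such as the oncology
example, the treatment arm (``log lambda_i0 = log lambda_i1 - phi_i``).
Under the CE model the log hazard ratio is shared, ``phi_i = phi``; the RE
extension draws ``phi_i ~ Normal(phi, eta^2)`` with between-trial
heterogeneity SD ``eta``, reducing to CE at ``eta = 0``.  Fatality
probabilities ``q0, q1`` are global across trials.

This module provides the declarative :class:`ModelSpec`, the explicit
:class:`ParameterState`, and straightforward (scipy-based) evaluations of
the joint log prior / likelihood / posterior.  The MCMC backend uses an
equivalent compiled evaluation (see ``aemeta._compile``); agreement of the
two routes is asserted in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import ArmAggregate, ArmRates, arm_log_likelihood, category_probabilities
from .priors import PriorSpec, named_prior, vague_prior

__all__ = [
    "ModelSpec",
    "ParameterState",
    "TrialParams",
    "HistoricalParams",
    "GLOBAL_PARAMETERS",
    "log_prior",
    "log_likelihood",
    "log_posterior_unnormalized",
]

GLOBAL_PARAMETERS = ("nu1", "sigma1", "nu2", "sigma2", "nu3", "sigma3",
                     "q0", "q1", "phi", "eta")


def _resolve_prior(p: PriorSpec | str) -> PriorSpec:
    return named_prior(p) if isinstance(p, str) else p


@dataclass(frozen=True)
class ModelSpec:
    """Full model configuration: effect type, anchoring, borrowing and priors.

    ``priors`` maps global parameter names (``nu1 .. sigma3``, ``q0``,
    ``q1``, ``phi``, ``eta``) to :class:`PriorSpec`; preset names such as
    ``"cauchy-0.37"`` are accepted.  ``trial_level_priors`` is only used
    under *stratified* borrowing and holds direct priors for the per-trial
    control parameters (keys ``log_lambda_control`` and ``log_mu_control``),
    replacing the corresponding hierarchical level.
    """

    effect_type: str = "common"
    anchor: str = "control"
    borrowing: str = "none"
    priors: dict[str, PriorSpec] = field(default_factory=dict)
    trial_level_priors: dict[str, PriorSpec] | None = None

    def __post_init__(self) -> None:
        if self.effect_type not in ("common", "random"):
            raise ValueError(f"effect_type must be 'common' or 'random', got {self.effect_type!r}")
        if self.anchor not in ("control", "treatment"):
            raise ValueError(f"anchor must be 'control' or 'treatment', got {self.anchor!r}")
        if self.borrowing not in ("none", "non-stratified", "stratified"):
            raise ValueError(f"unknown borrowing mode {self.borrowing!r}")
        pr = {k: _resolve_prior(v) for k, v in self.priors.items()}
        unknown = set(pr) - set(GLOBAL_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown prior keys: {sorted(unknown)}")
        defaults = {
            "nu1": vague_prior("location"), "sigma1": vague_prior("scale"),
            "nu2": vague_prior("location"), "sigma2": vague_prior("scale"),
            "nu3": vague_prior("location"), "sigma3": vague_prior("scale"),
            "q0": vague_prior("proportion"), "q1": vague_prior("proportion"),
            "phi": named_prior("cauchy-2.5"), "eta": named_prior("hn-100"),
        }
        for k, v in defaults.items():
            pr.setdefault(k, v)
        if self.effect_type == "common":
            pr.pop("eta", None)
        object.__setattr__(self, "priors", pr)
        if self.trial_level_priors is not None:
            tlp = {k: _resolve_prior(v) for k, v in self.trial_level_priors.items()}
            bad = set(tlp) - {"log_lambda_control", "log_mu_control"}
            if bad:
                raise ValueError(f"unknown trial-level prior keys: {sorted(bad)}")
            object.__setattr__(self, "trial_level_priors", tlp)
        if self.borrowing == "stratified":
            if self.anchor != "control":
                raise ValueError("stratified borrowing requires control anchoring "
                                 "(historical data inform control-arm parameters)")
            if not self.trial_level_priors:
                raise ValueError("stratified borrowing needs trial_level_priors")

    @property
    def random_effects(self) -> bool:
        return self.effect_type == "random"

    @classmethod
    def vague(cls, effect_type: str = "common", anchor: str = "control",
              phi_prior: PriorSpec | str = "cauchy-2.5",
              eta_prior: PriorSpec | str = "hn-100") -> "ModelSpec":
        """Vague prior settings for all hyperparameters."""
        return cls(effect_type=effect_type, anchor=anchor,
                   priors={"phi": phi_prior, "eta": eta_prior})

    @classmethod
    def rosiglitazone_weakly_informative(cls, effect_type: str = "common",
                                         phi_prior: PriorSpec | str = "cauchy-0.37",
                                         eta_prior: PriorSpec | str = "hn-0.5") -> "ModelSpec":
        """The weakly informative menu used for the type-2-diabetes data:
        nu1 ~ Normal(-4.27, log(10)^2), nu2, nu3 ~ Normal(log 0.22, log(10)^2),
        all scales Halfnormal(log 10)."""
        pr = {
            "nu1": named_prior("rosi-lambda-location"),
            "sigma1": named_prior("rosi-scale"),
            "nu2": named_prior("rosi-mu-location"),
            "sigma2": named_prior("rosi-scale"),
            "nu3": named_prior("rosi-mu-location"),
            "sigma3": named_prior("rosi-scale"),
            "phi": phi_prior, "eta": eta_prior,
        }
        return cls(effect_type=effect_type, anchor="control", priors=pr)

    def with_priors(self, **updates: PriorSpec | str) -> "ModelSpec":
        pr = dict(self.priors)
        pr.update({k: _resolve_prior(v) for k, v in updates.items()})
        return replace(self, priors=pr)


@dataclass
class TrialParams:
    """Parameters of one two-armed trial: the anchor-arm log event hazard,
    the two log drop-out hazards, and (RE) the trial-specific log-HR."""

    log_lambda_anchor: float
    log_mu0: float
    log_mu1: float
    phi_i: float | None = None


@dataclass
class HistoricalParams:
    log_lambda0: float
    log_mu0: float


@dataclass
class ParameterState:
    """An explicit point in parameter space for a given dataset + spec."""

    q0: float
    q1: float | None = None
    phi: float | None = None
    eta: float | None = None
    nu1: float | None = None
    sigma1: float | None = None
    nu2: float | None = None
    sigma2: float | None = None
    nu3: float | None = None
    sigma3: float | None = None
    trials: dict[str, TrialParams] = field(default_factory=dict)
    historical: dict[str, HistoricalParams] = field(default_factory=dict)


def _norm_logpdf(x: float, loc: float, scale: float) -> float:
    if scale == 0.0:
        return 0.0 if x == loc else -math.inf
    return float(stats.norm.logpdf(x, loc, scale))


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior: hyperpriors plus all hierarchical levels.

    Includes the exchangeability densities of the trial-level parameters
    (evaluated on their natural, centered scale) and, under the RE model,
    the Normal(phi, eta^2) level for the trial-specific log hazard ratios.
    Returns ``-inf`` outside the support (e.g. negative scales).
    """
    lp = 0.0
    for name in GLOBAL_PARAMETERS:
        val = getattr(state, name)
        if val is None:
            continue
        if name == "eta" and spec.effect_type == "common":
            continue
        prior = spec.priors.get(name)
        if prior is None:
            continue
        lp += float(prior.logpdf(val))
        if not np.isfinite(lp):
            return -math.inf

    stratified = spec.borrowing == "stratified"
    for tid, tp in state.trials.items():
        if stratified:
            lp += float(spec.trial_level_priors["log_lambda_control"].logpdf(tp.log_lambda_anchor))
            lp += float(spec.trial_level_priors["log_mu_control"].logpdf(tp.log_mu0))
        else:
            lp += _norm_logpdf(tp.log_lambda_anchor, state.nu1, state.sigma1)
            lp += _norm_logpdf(tp.log_mu0, state.nu2, state.sigma2)
        lp += _norm_logpdf(tp.log_mu1, state.nu3, state.sigma3)
        if spec.random_effects:
            if tp.phi_i is None:
                raise ValueError(f"trial {tid!r}: phi_i required under the RE model")
            lp += _norm_logpdf(tp.phi_i, state.phi, state.eta)
        if not np.isfinite(lp):
            return -math.inf
    for hid, hp in state.historical.items():
        lp += _norm_logpdf(hp.log_lambda0, state.nu1, state.sigma1)
        lp += _norm_logpdf(hp.log_mu0, state.nu2, state.sigma2)
        if not np.isfinite(lp):
            return -math.inf
    return float(lp)


def resolve_arm_rates(state: ParameterState, arm: ArmAggregate, spec: ModelSpec) -> ArmRates:
    """Map an arm to its (lambda, mu, q, tau) under the given state."""
    if arm.historical:
        try:
            hp = state.historical[arm.trial_id]
        except KeyError:
            raise KeyError(f"historical arm references unknown trial {arm.trial_id!r}") from None
        return ArmRates(math.exp(hp.log_lambda0), math.exp(hp.log_mu0), state.q0, arm.tau)
    try:
        tp = state.trials[arm.trial_id]
    except KeyError:
        raise KeyError(f"arm references unknown trial {arm.trial_id!r}") from None
    phi_i = tp.phi_i if spec.random_effects else state.phi
    if phi_i is None:
        raise ValueError("phi (or phi_i) must be set for two-armed trials")
    if spec.anchor == "control":
        log_l0 = tp.log_lambda_anchor
        log_l1 = tp.log_lambda_anchor + phi_i
    else:
        log_l1 = tp.log_lambda_anchor
        log_l0 = tp.log_lambda_anchor - phi_i
    if arm.arm == 1:
        return ArmRates(math.exp(log_l1), math.exp(tp.log_mu1), state.q1, arm.tau)
    return ArmRates(math.exp(log_l0), math.exp(tp.log_mu0), state.q0, arm.tau)


def log_likelihood(state: ParameterState, dataset, spec: ModelSpec) -> float:
    """Sum of the marginalized aggregate-data log likelihood over all arms.

    Trials are independent; historical arms contribute control parameters
    only.  ``dataset`` is any iterable of :class:`~aemeta.core.ArmAggregate`.
    """
    total = 0.0
    for arm in dataset:
        rates = resolve_arm_rates(state, arm, spec)
        total += arm_log_likelihood(arm, category_probabilities(rates))
        if total == -math.inf:
            return -math.inf
    return float(total)


def log_posterior_unnormalized(state: ParameterState, dataset, spec: ModelSpec) -> float:
    lp = log_prior(state, spec)
    if lp == -math.inf:
        return -math.inf
    return lp + log_likelihood(state, dataset, spec)
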