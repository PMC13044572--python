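"""Arm-level probability model and aggregate-data likelihood.

A patient in a trial arm is characterised by three independent latent
quantities: the time to first adverse event of interest ``X ~ Exponential(lam)``,
the time to early discontinuation ``C ~ Exponential(mu)``, and a fatality
indicator ``M ~ Bernoulli(q)`` attached to the event.  Over a maximum
follow-up ``tau`` each patient falls into exactly one of five timeline
categories:

1. fatal event of interest during follow-up,
2. nonfatal event, trial completed,
3. nonfatal event followed by drop-out before ``tau``,
4. administratively censored (no event, no drop-out by ``tau``),
5. drop-out before any event.

Published aggregate data (AD) report, per arm, the sample size ``n``, the
number of patients with at least one event ``y = w1+w2+w3``, the number of
early discontinuations ``z = w1+w3+w5``, the number of fatal events
``m = w1``, and ``tau``.  Only the marginal counts are observed; the
category count ``w3`` is latent and is marginalized by summing the
multinomial likelihood over its feasible range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ArmAggregate",
    "ArmRates",
    "CategoryProbabilities",
    "LatentCounts",
    "InconsistentDataError",
    "category_probabilities",
    "feasible_w3_range",
    "latent_counts",
    "arm_log_likelihood",
]


class InconsistentDataError(ValueError):
    """Raised when an aggregate-data row admits no valid latent configuration."""


@dataclass(frozen=True)
class ArmAggregate:
    """One trial arm's published aggregate summary.

    Parameters
    ----------
    trial_id : str
        Trial identifier; arms sharing it belong to the same trial.
    arm : int
        0 for control, 1 for treatment.
    n, y, z, m : int
        Sample size, patients with >=1 event, early discontinuations
        (fatal events count as discontinuations), fatal events.
    tau : float
        Maximum follow-up duration, in the dataset's time unit.
    historical : bool
        True for single-arm control-only historical trials.
    """

    trial_id: str
    arm: int
    n: int
    y: int
    z: int
    m: int
    tau: float
    historical: bool = False

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise ValueError(f"arm must be 0 or 1, got {self.arm!r}")
        if self.historical and self.arm != 0:
            raise ValueError(f"historical arm of trial {self.trial_id!r} must have arm=0")
        for name in ("n", "y", "z", "m"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if not (self.m <= self.y <= self.n):
            raise InconsistentDataError(
                f"trial {self.trial_id!r} arm {self.arm}: need m <= y <= n, "
                f"got m={self.m}, y={self.y}, n={self.n}"
            )
        if not (self.m <= self.z <= self.n):
            raise InconsistentDataError(
                f"trial {self.trial_id!r} arm {self.arm}: need m <= z <= n, "
                f"got m={self.m}, z={self.z}, n={self.n}"
            )
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")
        r1 = max(0, self.y + self.z - self.m - self.n)
        r2 = min(self.y - self.m, self.z - self.m)
        if r1 > r2:
            raise InconsistentDataError(
                f"trial {self.trial_id!r} arm {self.arm}: aggregate counts "
                f"(n={self.n}, y={self.y}, z={self.z}, m={self.m}) admit no "
                f"latent category configuration (feasible w3 range empty)"
            )


@dataclass(frozen=True)
class ArmRates:
    """Per-arm rates: event hazard ``lam``, drop-out hazard ``mu`` (both per
    time unit), fatality probability ``q`` and follow-up ``tau``."""

    lam: float
    mu: float
    q: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"event hazard must be positive and finite, got {self.lam}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"drop-out hazard must be positive and finite, got {self.mu}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"fatality probability must lie in [0, 1], got {self.q}")
        if not (self.tau > 0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")


@dataclass(frozen=True)
class CategoryProbabilities:
    """Probabilities of the five patient-timeline categories (sum to 1)."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5])

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"category probabilities outside [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"category probabilities sum to {arr.sum()}, not 1")


@dataclass(frozen=True)
class LatentCounts:
    """Per-category patient counts ``w1..w5`` for one arm; sums to ``n``."""

    w1: int
    w2: int
    w3: int
    w4: int
    w5: int

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5])

    @property
    def n(self) -> int:
        return int(self.as_array().sum())

    @property
    def y(self) -> int:
        return self.w1 + self.w2 + self.w3

    @property
    def z(self) -> int:
        return self.w1 + self.w3 + self.w5

    @property
    def m(self) -> int:
        return self.w1


def _one_minus_exp_over(s: float, tau: float) -> float:
    """(1 - exp(-s*tau)) / s, stable as s -> 0 (limit: tau)."""
    x = s * tau
    if x < 1e-8:
        # series: tau * (1 - x/2 + x^2/6)
        return tau * (1.0 - x / 2.0 + x * x / 6.0)
    return -math.expm1(-x) / s


def category_probabilities(rates: ArmRates) -> CategoryProbabilities:
    """Closed-form probabilities of the five timeline categories.

    With ``s = lam + mu`` and ``f = (1 - e^{-s tau}) / s``:

    * ``p1 = q * lam * f``                (fatal event before min(C, tau))
    * ``p2 = (1-q) (1 - e^{-lam tau}) e^{-mu tau}``  (nonfatal event, completes)
    * ``p3 = (1-q) (1 - e^{-mu tau} - mu f)``        (nonfatal event, then drop-out)
    * ``p4 = e^{-s tau}``                 (administratively censored)
    * ``p5 = mu * f``                     (drop-out before any event)

    The ``p3`` expression is rearranged against catastrophic cancellation when
    ``s * tau`` is tiny.
    """
    lam, mu, q, tau = rates.lam, rates.mu, rates.q, rates.tau
    s = lam + mu
    f = _one_minus_exp_over(s, tau)
    p1 = q * lam * f
    p2 = (1.0 - q) * (-math.expm1(-lam * tau)) * math.exp(-mu * tau)
    p3 = (1.0 - q) * (-math.expm1(-mu * tau) - mu * f)
    p4 = math.exp(-s * tau)
    p5 = mu * f
    p3 = max(p3, 0.0)  # cancellation can leave a tiny negative residue
    return CategoryProbabilities(p1, p2, p3, p4, p5)


def feasible_w3_range(arm: ArmAggregate) -> tuple[int, int]:
    """Bounds ``(r1, r2)`` of the latent nonfatal-event-then-drop-out count.

    ``r1 = max(0, y + z - m - n)`` and ``r2 = min(y - m, z - m)``.
    ``ArmAggregate`` construction already guarantees ``r1 <= r2``.
    """
    r1 = max(0, arm.y + arm.z - arm.m - arm.n)
    r2 = min(arm.y - arm.m, arm.z - arm.m)
    return r1, r2


def latent_counts(arm: ArmAggregate, w3: int) -> LatentCounts:
    """Reconstruct the full category counts from the aggregate row and ``w3``."""
    r1, r2 = feasible_w3_range(arm)
    if not r1 <= w3 <= r2:
        raise ValueError(
            f"w3={w3} outside feasible range [{r1}, {r2}] for trial "
            f"{arm.trial_id!r} arm {arm.arm}"
        )
    w1 = arm.m
    w2 = arm.y - w1 - w3
    w5 = arm.z - w1 - w3
    w4 = arm.n - w1 - w2 - w3 - w5
    return LatentCounts(w1, w2, w3, w4, w5)


def _xlogp(k: int, p: float) -> float:
    """k * log(p) with the convention 0 * log(0) = 0; -inf when k>0, p<=0."""
    if k == 0:
        return 0.0
    if p <= 0.0:
        return -math.inf
    return k * math.log(p)


def arm_log_likelihood(arm: ArmAggregate, probs: CategoryProbabilities) -> float:
    """Log-probability of one arm's aggregate counts under the category model.

    The multinomial likelihood is marginalized over the latent count ``w3``
    by log-sum-exp over its feasible range; factorials are handled via
    ``gammaln``.  Returns ``-inf`` (never raises) when every term in the sum
    has zero probability, e.g. ``m > 0`` with ``p1 = 0``.
    """
    if arm.n == 0:
        return 0.0
    p = probs.as_array()
    r1, r2 = feasible_w3_range(arm)
    base = gammaln(arm.n + 1) - gammaln(arm.m + 1) + _xlogp(arm.m, p[0])
    if base == -math.inf:
        return -math.inf
    terms = []
    for r in range(r1, r2 + 1):
        w = latent_counts(arm, r)
        t = (
            _xlogp(w.w2, p[1])
            + _xlogp(w.w3, p[2])
            + _xlogp(w.w4, p[3])
            + _xlogp(w.w5, p[4])
            - gammaln(w.w2 + 1)
            - gammaln(w.w3 + 1)
            - gammaln(w.w4 + 1)
            - gammaln(w.w5 + 1)
        )
        terms.append(t)
    total = logsumexp(terms)
    if total == -math.inf:
        return -math.inf
    return float(base + total)
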