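"""Prior distribution specifications and the standard prior menus.

Priors are declarative: a :class:`PriorSpec` names a family and its
parameters, and can be evaluated (``logpdf``), sampled (``rvs``) and
serialized to/from plain JSON-compatible dictionaries.  Mixtures of these
families represent meta-analytic-predictive (MAP) priors and their
robustified variants.

Supported families
------------------
``normal(loc, scale)``
    Gaussian, used for location hyperparameters (default vague scale 100).
``half-normal(scale)``
    |Normal(0, scale^2)|, the standard weakly informative / vague choice for
    between-trial standard deviations.
``trunc-normal(loc, scale)``
    Normal truncated to [0, inf); appears as a MAP mixture component for
    scale parameters.
``cauchy(loc, scale)``
    For the log hazard ratio; the menu offers Cauchy(0, 2.5) and
    Cauchy(0, 0.37) (the latter puts 90% of its mass inside
    [-log 10, log 10]).
``beta(a, b)``
    For fatality probabilities; Jeffreys Beta(0.5, 0.5) is the vague choice.
``point-mass(loc)``
    Degenerate; useful for fixing parameters in tests and sensitivity runs.
``mixture``
    Weighted combination of the above (weights sum to 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

__all__ = ["PriorSpec", "vague_prior", "named_prior", "PRIOR_PRESETS"]

_FAMILIES = {"normal", "half-normal", "trunc-normal", "cauchy", "beta", "point-mass", "mixture"}


@dataclass(frozen=True)
class PriorSpec:
    family: str
    params: tuple[float, ...] = ()
    components: tuple["PriorSpec", ...] | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family == "mixture":
            if not self.components:
                raise ValueError("mixture prior needs at least one component")
            object.__setattr__(self, "components", tuple(self.components))
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 1 or len(w) != len(self.components):
                raise ValueError("mixture needs one weight per component")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must be nonnegative and sum to 1")
            object.__setattr__(self, "weights", tuple(float(x) for x in w))
            if any(c.family == "mixture" for c in self.components):
                raise ValueError("nested mixtures are not supported")
        else:
            n_expected = {"normal": 2, "half-normal": 1, "trunc-normal": 2,
                          "cauchy": 2, "beta": 2, "point-mass": 1}[self.family]
            if len(self.params) != n_expected:
                raise ValueError(
                    f"{self.family} prior takes {n_expected} parameter(s), got {self.params}"
                )
            scale_pos = {"normal": 1, "half-normal": 0, "trunc-normal": 1, "cauchy": 1}
            if self.family in scale_pos and self.params[scale_pos[self.family]] <= 0:
                raise ValueError(f"{self.family} scale must be positive, got {self.params}")
            if self.family == "beta" and (self.params[0] <= 0 or self.params[1] <= 0):
                raise ValueError(f"beta shapes must be positive, got {self.params}")

    # -- evaluation ---------------------------------------------------------

    def _frozen(self):
        f, p = self.family, self.params
        if f == "normal":
            return stats.norm(p[0], p[1])
        if f == "half-normal":
            return stats.halfnorm(0.0, p[0])
        if f == "trunc-normal":
            a = (0.0 - p[0]) / p[1]
            return stats.truncnorm(a, np.inf, loc=p[0], scale=p[1])
        if f == "cauchy":
            return stats.cauchy(p[0], p[1])
        if f == "beta":
            return stats.beta(p[0], p[1])
        raise ValueError(f"no frozen form for family {f!r}")

    def logpdf(self, x: float | np.ndarray) -> float | np.ndarray:
        if self.family == "point-mass":
            x = np.asarray(x, dtype=float)
            out = np.where(x == self.params[0], 0.0, -np.inf)
            return float(out) if out.ndim == 0 else out
        if self.family == "mixture":
            parts = np.array([np.log(w) + np.asarray(c.logpdf(x), dtype=float)
                              if w > 0 else np.full(np.shape(np.asarray(x)), -np.inf)
                              for w, c in zip(self.weights, self.components)])
            from scipy.special import logsumexp
            out = logsumexp(parts, axis=0)
            return float(out) if np.ndim(out) == 0 else out
        return self._frozen().logpdf(x)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        if self.family == "point-mass":
            return np.where(np.asarray(x, dtype=float) >= self.params[0], 1.0, 0.0)
        if self.family == "mixture":
            return sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))
        return self._frozen().cdf(x)

    def rvs(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        if self.family == "point-mass":
            return np.full(size, self.params[0])
        if self.family == "mixture":
            idx = rng.choice(len(self.components), size=size, p=np.asarray(self.weights))
            out = np.empty(size)
            for k, c in enumerate(self.components):
                mask = idx == k
                if mask.any():
                    out[mask] = c.rvs(rng, int(mask.sum()))
            return out
        return self._frozen().rvs(size=size, random_state=rng)

    @property
    def support(self) -> tuple[float, float]:
        if self.family in ("normal", "cauchy"):
            return (-math.inf, math.inf)
        if self.family in ("half-normal", "trunc-normal"):
            return (0.0, math.inf)
        if self.family == "beta":
            return (0.0, 1.0)
        if self.family == "point-mass":
            return (self.params[0], self.params[0])
        lo = min(c.support[0] for c in self.components)
        hi = max(c.support[1] for c in self.components)
        return (lo, hi)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"family": self.family}
        if self.family == "mixture":
            d["components"] = [c.to_dict() for c in self.components]
            d["weights"] = list(self.weights)
        else:
            d["params"] = list(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PriorSpec":
        if d["family"] == "mixture":
            return cls(
                "mixture",
                components=tuple(cls.from_dict(c) for c in d["components"]),
                weights=tuple(d["weights"]),
            )
        return cls(d["family"], tuple(d.get("params", ())))

    # -- constructors -------------------------------------------------------

    @classmethod
    def normal(cls, loc: float, scale: float) -> "PriorSpec":
        return cls("normal", (loc, scale))

    @classmethod
    def half_normal(cls, scale: float) -> "PriorSpec":
        return cls("half-normal", (scale,))

    @classmethod
    def cauchy(cls, loc: float, scale: float) -> "PriorSpec":
        return cls("cauchy", (loc, scale))

    @classmethod
    def beta(cls, a: float, b: float) -> "PriorSpec":
        return cls("beta", (a, b))

    @classmethod
    def point_mass(cls, loc: float) -> "PriorSpec":
        return cls("point-mass", (loc,))

    @classmethod
    def mixture(cls, components: Sequence["PriorSpec"], weights: Sequence[float]) -> "PriorSpec":
        return cls("mixture", components=tuple(components), weights=tuple(weights))


def vague_prior(kind: str) -> PriorSpec:
    """The vague menu: Normal(0, 100^2) locations, Halfnormal(100) scales,
    Jeffreys Beta(0.5, 0.5) proportions."""
    if kind == "location":
        return PriorSpec.normal(0.0, 100.0)
    if kind == "scale":
        return PriorSpec.half_normal(100.0)
    if kind == "proportion":
        return PriorSpec.beta(0.5, 0.5)
    raise ValueError(f"unknown vague prior kind {kind!r}")


PRIOR_PRESETS: dict[str, PriorSpec] = {
    "vague-location": vague_prior("location"),
    "vague-scale": vague_prior("scale"),
    "vague-proportion": vague_prior("proportion"),
    "cauchy-2.5": PriorSpec.cauchy(0.0, 2.5),
    "cauchy-0.37": PriorSpec.cauchy(0.0, 0.37),
    "hn-0.1": PriorSpec.half_normal(0.1),
    "hn-0.25": PriorSpec.half_normal(0.25),
    "hn-0.5": PriorSpec.half_normal(0.5),
    "hn-log10": PriorSpec.half_normal(math.log(10.0)),
    "hn-100": PriorSpec.half_normal(100.0),
    # weakly informative menu for type-2-diabetes-like settings
    "rosi-lambda-location": PriorSpec.normal(-4.27, math.log(10.0)),
    "rosi-mu-location": PriorSpec.normal(math.log(0.22), math.log(10.0)),
    "rosi-scale": PriorSpec.half_normal(math.log(10.0)),
}


def named_prior(name: str) -> PriorSpec:
    """Look up a preset prior by its menu name (e.g. ``"cauchy-0.37"``)."""
    try:
        return PRIOR_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown prior preset {name!r}; available: {sorted(PRIOR_PRESETS)}"
        ) from None
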