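"""Posterior sampling, convergence diagnostics, and interval summaries.

The sampler is an affine-invariant ensemble ("stretch move") MCMC run on
the non-centered flat encoding of the model (see ``aemeta._compile``).
Each requested chain is an independent ensemble of walkers started from an
overdispersed data-informed initialization; draws are pooled over walkers.
Convergence is monitored with the rank-normalized split R-hat and bulk
effective sample size for every reported parameter.

The default protocol mirrors standard practice for this model class:
5 chains, 10 000 burn-in sweeps per chain, thinning by 5, and roughly
10 000 retained draws; all of it is configurable, and the
operating-characteristics engine uses a documented reduced protocol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import arviz as az
import numpy as np
import pandas as pd

from . import _speed
from ._compile import CompiledModel
from .hierarchy import ModelSpec

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "SamplingError",
    "sample_posterior",
    "summarize",
    "ci_excludes_null",
    "rhat",
    "ess",
    "CredibleInterval",
]

RHAT_WARN = 1.01


class SamplingError(RuntimeError):
    """Sampling failed; carries the partial diagnostics that triggered it."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class McmcConfig:
    """MCMC protocol.

    ``burn_in`` and ``thin`` are in ensemble sweeps per chain (one sweep
    updates every walker once); ``kept`` is the target total number of
    retained draws pooled over chains and walkers.  ``walkers=None`` picks
    an even count of at least ``2 * (dim + 1)`` (minimum 48), enabling the
    global affine-invariant moves; smaller explicit ensembles (minimum 6)
    are allowed and rely on the kernel's local and collective moves.
    """

    chains: int = 5
    burn_in: int = 10000
    thin: int = 5
    kept: int = 10000
    walkers: int | None = None
    stretch: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chains", "burn_in", "thin", "kept"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.stretch <= 1.0:
            raise ValueError("stretch parameter must exceed 1")

    def resolve_walkers(self, dim: int) -> int:
        w = self.walkers if self.walkers is not None else max(48, 2 * (dim + 1))
        if w < 6:
            raise ValueError("need at least 6 walkers")
        return w + (w % 2)


@dataclass
class PosteriorSamples:
    """Named posterior draws with per-parameter diagnostics.

    ``draws[name]`` has shape (chains, draws-per-chain); draws within a
    chain are ordered sweep-major over the walker ensemble.
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    ess: dict[str, float]
    spec: ModelSpec
    config: McmcConfig
    accept_fraction: float = math.nan
    convergence_warning: bool = False

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def pooled(self, parameter: str) -> np.ndarray:
        try:
            return self.draws[parameter].reshape(-1)
        except KeyError:
            raise KeyError(
                f"parameter {parameter!r} was not sampled; available: "
                f"{sorted(self.draws)}") from None

    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else math.nan

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        for name, arr in self.draws.items():
            c, n = arr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(c), n),
                "iteration": np.tile(np.arange(n), c),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            point, lo, hi = summarize(self, name)
            rows.append({"parameter": name, "median": point,
                         "lower95": lo, "upper95": hi,
                         "rhat": self.rhat.get(name, math.nan),
                         "ess": self.ess.get(name, math.nan)})
        return pd.DataFrame(rows)


class CredibleInterval(NamedTuple):
    point: float
    lower95: float
    upper95: float


def _diag_matrix(arr: np.ndarray) -> np.ndarray:
    """Reshape draws to >=2 pseudo-chains for split diagnostics."""
    if arr.shape[0] >= 2:
        return arr
    n = arr.shape[1]
    return arr[0, : 2 * (n // 2)].reshape(2, n // 2)


def rhat(chain_draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of a (chains, draws) matrix."""
    chain_draws = np.asarray(chain_draws, dtype=float)
    if chain_draws.ndim != 2 or chain_draws.shape[0] < 2:
        raise ValueError("rhat needs a 2-D (chains, draws) matrix with >= 2 chains")
    return float(az.rhat(chain_draws, method="rank"))


def ess(chain_draws: np.ndarray) -> float:
    """Bulk effective sample size of a (chains, draws) matrix."""
    chain_draws = np.asarray(chain_draws, dtype=float)
    if chain_draws.ndim != 2:
        raise ValueError("ess needs a 2-D (chains, draws) matrix")
    return float(az.ess(chain_draws, method="bulk"))


def sample_posterior(dataset, spec: ModelSpec, config: McmcConfig) -> PosteriorSamples:
    """Draw from the joint posterior of the hierarchical model.

    Deterministic given ``config.seed``.  Sets ``convergence_warning`` when
    any parameter's rank-based split R-hat exceeds 1.01; raises
    :class:`SamplingError` (carrying diagnostics) when the ensemble fails to
    move at all.
    """
    model = CompiledModel.build(dataset, spec)
    D = model.dim
    W = config.resolve_walkers(D)
    ksteps = max(1, math.ceil(config.kept / (config.chains * W)))
    nsteps = config.burn_in + (ksteps - 1) * config.thin + 1

    ss = np.random.SeedSequence(config.seed)
    kernel_seeds = ss.generate_state(config.chains).astype(np.int64) & 0x7FFFFFFF
    init_rngs = [np.random.default_rng(s) for s in ss.spawn(config.chains)]

    args = model.kernel_args()
    per_chain: list[np.ndarray] = []
    acc_total = 0
    nmoves = 0
    for c in range(config.chains):
        x0 = model.initial_walkers(init_rngs[c], W)
        draws, logp, nacc = _speed._run_ensemble(
            x0, nsteps, config.burn_in, config.thin, config.stretch,
            int(kernel_seeds[c]), *model.gibbs_args(), *args)
        per_chain.append(draws.reshape(-1, D))  # sweep-major over walkers
        acc_total += nacc
        if W >= 2 * (D + 1):  # global moves active
            nmoves += nsteps * W
    accept_fraction = acc_total / nmoves if nmoves else math.nan

    if nmoves and accept_fraction < 0.005:
        raise SamplingError(
            f"ensemble sampler failed to move (acceptance {accept_fraction:.4f}); "
            "the posterior may be degenerate",
            {"accept_fraction": accept_fraction, "dim": D, "walkers": W})

    named: dict[str, np.ndarray] = {}
    for c, flat in enumerate(per_chain):
        d = model.derived(flat)
        for k, v in d.items():
            named.setdefault(k, []).append(v)
    draws = {k: np.stack(v) for k, v in named.items()}

    rhats: dict[str, float] = {}
    esss: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, arr in draws.items():
            m = _diag_matrix(arr)
            if m.shape[1] < 4 or np.allclose(arr, arr.reshape(-1)[0]):
                rhats[k] = math.nan
                esss[k] = math.nan
                continue
            rhats[k] = float(az.rhat(m, method="rank"))
            esss[k] = float(az.ess(m, method="bulk"))

    warn = any(np.isfinite(v) and v > RHAT_WARN for v in rhats.values())
    return PosteriorSamples(draws=draws, rhat=rhats, ess=esss, spec=spec,
                            config=config, accept_fraction=accept_fraction,
                            convergence_warning=warn)


def summarize(samples: PosteriorSamples, parameter: str) -> CredibleInterval:
    """Posterior median and 95% equal-tailed credible interval (pooled chains)."""
    x = samples.pooled(parameter)
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return CredibleInterval(float(med), float(lo), float(hi))


def ci_excludes_null(samples: PosteriorSamples, parameter: str = "phi") -> bool:
    """True iff the 95% equal-tailed CI for the (log-scale) effect excludes 0."""
    _, lo, hi = summarize(samples, parameter)
    return not (lo <= 0.0 <= hi)
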