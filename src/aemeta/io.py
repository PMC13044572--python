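"""Readers/writers for the arm-level aggregate-data CSV schema and configs.

The AD schema is one row per trial arm with columns
``trial,arm,n,y,z,m,tau,historical`` (``historical`` optional, default
false).  Real published data sometimes mix analysis sets (e.g. ``z``
reported on the full analysis set while ``n`` and ``y`` follow the safety
set); rows are accepted as long as the arithmetic invariants hold, and
rejected with a row-identifying message otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ArmAggregate
from .hierarchy import ModelSpec
from .priors import PriorSpec
from .simulator import ScenarioConfig

__all__ = ["Dataset", "read_ad_csv", "write_ad_csv",
           "model_spec_from_dict", "load_model_config", "load_scenario_config"]

_REQUIRED = ["trial", "arm", "n", "y", "z", "m", "tau"]


class AdParseError(ValueError):
    """A malformed aggregate-data table row or header."""


@dataclass(frozen=True)
class Dataset:
    """A validated collection of trial arms.

    Main trials have exactly one control (0) and one treatment (1) arm;
    historical trials exactly one control arm.
    """

    arms: tuple[ArmAggregate, ...]
    time_unit: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        seen = set()
        by_trial: dict[str, list[ArmAggregate]] = {}
        for a in self.arms:
            key = (a.trial_id, a.arm)
            if key in seen:
                raise AdParseError(f"duplicate (trial, arm) pair {key}")
            seen.add(key)
            by_trial.setdefault(a.trial_id, []).append(a)
        for tid, group in by_trial.items():
            if any(g.historical for g in group):
                if len(group) != 1 or not all(g.historical for g in group):
                    raise AdParseError(
                        f"historical trial {tid!r} must consist of exactly one control arm")
            else:
                if sorted(g.arm for g in group) != [0, 1]:
                    raise AdParseError(
                        f"trial {tid!r} must have exactly one control and one treatment arm")

    def __iter__(self):
        return iter(self.arms)

    def __len__(self) -> int:
        return len(self.arms)

    @property
    def main_arms(self) -> tuple[ArmAggregate, ...]:
        return tuple(a for a in self.arms if not a.historical)

    @property
    def historical_arms(self) -> tuple[ArmAggregate, ...]:
        return tuple(a for a in self.arms if a.historical)

    @property
    def main_trials(self) -> list[str]:
        out: list[str] = []
        for a in self.main_arms:
            if a.trial_id not in out:
                out.append(a.trial_id)
        return out

    @property
    def historical_trials(self) -> list[str]:
        out: list[str] = []
        for a in self.historical_arms:
            if a.trial_id not in out:
                out.append(a.trial_id)
        return out


def _parse_bool(v, row: int):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", "", "nan"):
        return False
    raise AdParseError(f"row {row}: cannot interpret historical flag {v!r}")


def read_ad_csv(path: str | Path, time_unit: str = "") -> Dataset:
    """Read and validate an aggregate-data table.

    Error messages reference the offending data row (header = row 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise AdParseError(f"{path.name}: missing required column(s) {missing}")
    arms = []
    for i, rec in df.iterrows():
        row = i + 2  # header line is row 1
        vals = {}
        for cname in ("arm", "n", "y", "z", "m"):
            v = rec[cname]
            fv = float(v)
            if not float(fv).is_integer():
                raise AdParseError(f"{path.name} row {row}: column {cname!r} "
                                   f"must be an integer, got {v!r}")
            vals[cname] = int(fv)
        hist = _parse_bool(rec.get("historical", False), row)
        try:
            arms.append(ArmAggregate(
                trial_id=str(rec["trial"]), arm=vals["arm"], n=vals["n"],
                y=vals["y"], z=vals["z"], m=vals["m"], tau=float(rec["tau"]),
                historical=hist))
        except (ValueError, TypeError) as exc:
            raise AdParseError(f"{path.name} row {row}: {exc}") from exc
    try:
        return Dataset(tuple(arms), time_unit=time_unit, source=str(path))
    except AdParseError as exc:
        raise AdParseError(f"{path.name}: {exc}") from exc


def write_ad_csv(dataset: Dataset | list, path: str | Path) -> None:
    """Write the AD schema; ``read_ad_csv(write_ad_csv(d))`` round-trips exactly."""
    arms = list(dataset)
    df = pd.DataFrame({
        "trial": [a.trial_id for a in arms],
        "arm": [a.arm for a in arms],
        "n": [a.n for a in arms],
        "y": [a.y for a in arms],
        "z": [a.z for a in arms],
        "m": [a.m for a in arms],
        # repr round-trips the exact binary double; pandas' default float
        # formatting may drop the last digit
        "tau": [repr(float(a.tau)) for a in arms],
        "historical": [a.historical for a in arms],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration files


def _prior_from_config(v) -> PriorSpec | str:
    if isinstance(v, str):
        return v
    if isinstance(v, dict):
        return PriorSpec.from_dict(v)
    raise ValueError(f"cannot interpret prior config {v!r}")


def model_spec_from_dict(d: dict) -> ModelSpec:
    priors = {k: _prior_from_config(v) for k, v in (d.get("priors") or {}).items()}
    tlp = d.get("trial_level_priors")
    if tlp is not None:
        tlp = {k: _prior_from_config(v) for k, v in tlp.items()}
    return ModelSpec(
        effect_type=d.get("effect_type", "common"),
        anchor=d.get("anchor", "control"),
        borrowing=d.get("borrowing", "none"),
        priors=priors,
        trial_level_priors=tlp,
    )


def load_model_config(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        return model_spec_from_dict(yaml.safe_load(fh) or {})


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def save_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
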