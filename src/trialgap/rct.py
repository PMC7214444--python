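"""Per-arm RCT baseline characteristics and arm pooling.

A trial's published baseline table gives one column per arm. Pooling
collapses the two arms into the single value the comparison runs against:
discrete rows are summed across arms and expressed as a percent of the
combined n; continuous rows are averaged with weights proportional to arm
size. Characteristics published as medians are pooled by the same weighted
average of arm medians — an average of medians is not itself a median, so
the result is flagged ``median_average``.

The packaged transcriptions of the four source trials live under
``trialgap/data/trials`` and record, per characteristic: the two arm
values, the trial-level standard deviation where printed, the printed
pooled cell (kept verbatim, with a flag saying whether it is derivable
from the arm values at printed precision), and the printed observational
cohort columns with their discrepancy cells.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

TRIAL_IDS = ("sitagliptin_glimepiride", "prove_it", "renaal", "accomplish")

RowKind = Literal["discrete", "continuous", "median"]


class TrialSpecError(ValueError):
    """Raised when a trial transcription violates the schema."""


class ArmSummary(BaseModel):
    arm_name: str
    n: int = Field(ge=1)
    discrete: dict[str, float] = Field(default_factory=dict)   # counts
    continuous: dict[str, float] = Field(default_factory=dict)  # means (or medians)

    @model_validator(mode="after")
    def _check(self):
        for name, count in self.discrete.items():
            if count < 0 or count > self.n:
                raise ValueError(f"count for {name!r} outside [0, n={self.n}]")
        return self


class ReportedColumn(BaseModel):
    """One printed observational-cohort column (value, Δ, NED, audit flags)."""

    value: Optional[float] = None
    delta: Optional[float] = None
    ned: bool = False
    delta_consistency: Optional[Literal["exact", "edge", "inconsistent"]] = None


class TrialSummary(BaseModel):
    trial_id: str
    label: str = ""
    arms: list[ArmSummary]
    sigma: dict[str, float] = Field(default_factory=dict)
    median_flags: list[str] = Field(default_factory=list)
    characteristics: list[tuple[str, RowKind]] = Field(default_factory=list)
    pooled_printed: dict[str, str] = Field(default_factory=dict)
    pooled_derivable: dict[str, bool] = Field(default_factory=dict)
    reported_cohorts: dict[str, dict] = Field(default_factory=dict)
    cohort_ns: dict[str, int] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        if len(self.arms) != 2:
            raise ValueError(f"a trial summary holds exactly two arms, got {len(self.arms)}")
        for name, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"sigma for {name!r} must be >= 0")
        return self

    def kind_of(self, name: str) -> RowKind:
        for n, k in self.characteristics:
            if n == name:
                return k
        raise KeyError(name)

    def reported(self, cohort: str) -> "ReportedCohort":
        raw = self.reported_cohorts[cohort]
        return ReportedCohort(
            n=self.cohort_ns[cohort],
            values={k: v["value"] for k, v in raw.items()},
            deltas={k: v["delta"] for k, v in raw.items()},
            ned=frozenset(k for k, v in raw.items() if v["ned"]),
            delta_consistency={k: v.get("delta_consistency") for k, v in raw.items()},
        )


@dataclasses.dataclass(frozen=True)
class ReportedCohort:
    """Printed cohort column of a trial table, keyed by characteristic."""

    n: int
    values: dict[str, Optional[float]]
    deltas: dict[str, Optional[float]]
    ned: frozenset[str]
    delta_consistency: dict[str, Optional[str]]


@dataclasses.dataclass(frozen=True)
class PooledValue:
    characteristic: str
    value: float
    value_kind: Literal["percent", "mean", "median_average"]


def pool_discrete(count_arm1: float, count_arm2: float, n_arm1: int, n_arm2: int,
                  characteristic: str = "") -> PooledValue:
    """Sum counts across arms; report as a percent of the combined n."""
    if n_arm1 + n_arm2 <= 0:
        raise ValueError("pooled percent undefined for empty arms")
    if count_arm1 > n_arm1 or count_arm2 > n_arm2 or count_arm1 < 0 or count_arm2 < 0:
        raise ValueError("counts must lie in [0, arm n]")
    pct = 100.0 * (count_arm1 + count_arm2) / (n_arm1 + n_arm2)
    return PooledValue(characteristic, pct, "percent")


def pool_continuous(mean_arm1: float, mean_arm2: float, n_arm1: int, n_arm2: int,
                    characteristic: str = "", median: bool = False) -> PooledValue:
    """Average the arm means weighted by arm size."""
    if n_arm1 < 1 or n_arm2 < 1:
        raise ValueError("arm sizes must be >= 1")
    value = (n_arm1 * mean_arm1 + n_arm2 * mean_arm2) / (n_arm1 + n_arm2)
    return PooledValue(characteristic, value, "median_average" if median else "mean")


def pooled_value(trial: TrialSummary, name: str) -> PooledValue:
    """Pool one characteristic of a trial from its two arms."""
    kind = trial.kind_of(name)
    a1, a2 = trial.arms
    if kind == "discrete":
        return pool_discrete(a1.discrete[name], a2.discrete[name], a1.n, a2.n, name)
    return pool_continuous(a1.continuous[name], a2.continuous[name], a1.n, a2.n,
                           name, median=kind == "median")


def pooled_table(trial: TrialSummary) -> pd.DataFrame:
    """All pooled cells of a trial, with the printed value alongside."""
    rows = []
    for name, kind in trial.characteristics:
        pv = pooled_value(trial, name)
        rows.append({
            "characteristic": name,
            "kind": kind,
            "pooled": pv.value,
            "value_kind": pv.value_kind,
            "pooled_printed": trial.pooled_printed.get(name),
            "pooled_derivable": trial.pooled_derivable.get(name, False),
        })
    return pd.DataFrame(rows)


def _percent_to_count(percent: float, n: int) -> float:
    # lossy: printed percents imply a count only up to rounding
    return round(percent * n / 100.0)


def load_trial_spec(path: str | Path) -> TrialSummary:
    """Parse a packaged trial transcription (row-oriented JSON) losslessly."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        arm_names = doc["arm_names"]
        arm_ns = doc["arm_ns"]
        rows = doc["rows"]
    except KeyError as exc:
        raise TrialSpecError(f"missing field {exc} in {path}") from exc
    if len(arm_names) != 2 or len(arm_ns) != 2:
        raise TrialSpecError(f"{path}: a trial summary holds exactly two arms")
    discrete: list[dict[str, float]] = [{}, {}]
    continuous: list[dict[str, float]] = [{}, {}]
    sigma: dict[str, float] = {}
    median_flags: list[str] = []
    characteristics: list[tuple[str, RowKind]] = []
    pooled_printed: dict[str, str] = {}
    pooled_derivable: dict[str, bool] = {}
    reported: dict[str, dict] = {"indication_only": {}, "with_criteria": {}}
    for row in rows:
        name, kind = row["name"], row["kind"]
        characteristics.append((name, kind))
        pooled_printed[name] = row["pooled_printed"]
        pooled_derivable[name] = bool(row.get("pooled_derivable", False))
        a1, a2 = row["arm_values"]
        if kind == "discrete":
            if isinstance(a1, dict):  # percent-only transcription
                a1 = _percent_to_count(a1["percent"], arm_ns[0])
                a2 = _percent_to_count(a2["percent"], arm_ns[1])
            discrete[0][name], discrete[1][name] = a1, a2
        else:
            continuous[0][name], continuous[1][name] = a1, a2
            if kind == "median":
                median_flags.append(name)
        if row.get("sigma") is not None:
            sigma[name] = row["sigma"]
        for side in ("indication_only", "with_criteria"):
            reported[side][name] = row[side]
    try:
        return TrialSummary(
            trial_id=doc["trial_id"], label=doc.get("label", ""),
            arms=[ArmSummary(arm_name=arm_names[i], n=arm_ns[i],
                             discrete=discrete[i], continuous=continuous[i])
                  for i in range(2)],
            sigma=sigma, median_flags=median_flags,
            characteristics=characteristics,
            pooled_printed=pooled_printed, pooled_derivable=pooled_derivable,
            reported_cohorts=reported, cohort_ns=doc["cohort_ns"],
        )
    except (ValueError, KeyError) as exc:
        raise TrialSpecError(f"{path}: {exc}") from exc


def packaged_trial_path(trial_id: str) -> Path:
    if trial_id not in TRIAL_IDS:
        raise KeyError(f"unknown trial id {trial_id!r}; expected one of {TRIAL_IDS}")
    return Path(resources.files("trialgap").joinpath("data", "trials", f"{trial_id}.json"))


def load_packaged_trial(trial_id: str) -> TrialSummary:
    """Load one of the four packaged source-trial transcriptions."""
    return load_trial_spec(packaged_trial_path(trial_id))
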