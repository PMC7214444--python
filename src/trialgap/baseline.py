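"""Observational-cohort baseline characteristics aligned to a trial's table rows.

Each characteristic spec says how one (or one family of) table row(s) is
computed from the patient database at each member's index date:

* ``demographic_category`` — distribution of a person-level demographic
  field over labelled categories (explicit Unknown included);
* ``event_flag`` — percent of members with at least one in-window event
  from a concept set (conditions, drugs, procedures);
* ``event_count_category`` — members binned by the number of distinct
  concepts from a set with in-window events (e.g. antihypertensive drug
  classes used);
* ``measurement`` — mean/median/min/max of the per-person baseline value
  of a measurement concept (the in-window value closest to, and preferably
  not after, the index date);
* ``measurement_category`` — members binned by thresholds on that baseline
  value, with missing values reported as an explicit Unknown row;
* ``age`` / ``age_flag`` — age at index (index year minus birth year) as a
  mean, or as the percent at or above a cutoff;
* ``time_since_first_event`` — years from the earliest event of a concept
  set anywhere in the record to the index date.

Continuous rows whose number of recorded members falls below
``ned_threshold`` are reported as NED ("not enough data") instead of a
value. Members without a measurement are excluded from a continuous mean's
denominator but appear in the Unknown level of the matching discrete
breakdown, where the trial table prints one.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .criteria import Cohort, ConceptSet, resolve, select_measurement
from .model import PatientDatabase

log = logging.getLogger("trialgap.baseline")

DEFAULT_NED_THRESHOLD = 10

SpecKind = Literal[
    "demographic_category", "event_flag", "event_count_category",
    "measurement", "measurement_category", "age", "age_flag",
    "time_since_first_event",
]


class Bin(BaseModel):
    name: str
    op: Optional[Literal["lt", "le", "gt", "ge", "between"]] = None
    low: Optional[float] = None
    high: Optional[float] = None
    min_count: Optional[int] = None
    max_count: Optional[int] = None


class CharacteristicSpec(BaseModel):
    name: str
    kind: SpecKind
    field: Optional[Literal["gender", "race", "ethnicity"]] = None
    categories: Optional[dict[str, str]] = None  # concept_id -> row name
    concept_set: Optional[ConceptSet] = None
    days_before: int = Field(default=0, ge=0)
    days_after: int = Field(default=0, ge=0)
    aggregate: Literal["mean", "median", "min", "max"] = "mean"
    bins: Optional[list[Bin]] = None
    unknown_name: Optional[str] = None
    bound: Optional[float] = None  # age_flag cutoff

    @model_validator(mode="after")
    def _check(self):
        needs_set = ("event_flag", "event_count_category", "measurement",
                     "measurement_category", "time_since_first_event")
        if self.kind in needs_set and self.concept_set is None:
            raise ValueError(f"{self.kind} spec {self.name!r} requires concept_set")
        if self.kind == "demographic_category" and (self.field is None or not self.categories):
            raise ValueError(f"demographic_category spec {self.name!r} requires field+categories")
        if self.kind in ("event_count_category", "measurement_category") and not self.bins:
            raise ValueError(f"{self.kind} spec {self.name!r} requires bins")
        if self.kind == "age_flag" and self.bound is None:
            raise ValueError(f"age_flag spec {self.name!r} requires bound")
        return self


def load_characteristic_specs(path: str | Path) -> list[CharacteristicSpec]:
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    return [CharacteristicSpec.model_validate(d) for d in docs]


@dataclasses.dataclass
class SummaryRow:
    name: str
    data_type: Literal["discrete", "continuous"]
    value: Optional[float]      # percent for discrete, mean/median/... otherwise
    n_recorded: int
    ned: bool = False
    sd: Optional[float] = None  # cohort SD of the per-person values (continuous)


@dataclasses.dataclass
class CohortSummary:
    n: int
    rows: list[SummaryRow]

    def value(self, name: str) -> Optional[float]:
        for r in self.rows:
            if r.name == name:
                return r.value
        raise KeyError(name)

    def row(self, name: str) -> SummaryRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rows]

    def sds(self) -> dict[str, float]:
        return {r.name: r.sd for r in self.rows
                if r.data_type == "continuous" and r.sd is not None}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-person reduction (reference path; summarize() is vectorised)
# ---------------------------------------------------------------------------

def baseline_value(db: PatientDatabase, person_id: str, spec: CharacteristicSpec,
                   index_date: pd.Timestamp):
    """Per-person baseline reduction behind :func:`summarize`.

    Returns a category name (demographic), bool (event flag), count
    (event_count_category), float, or None when nothing is recorded.
    """
    person = db.person(person_id)
    if spec.kind == "demographic_category":
        return spec.categories.get(str(person[f"{spec.field}_concept"]))
    if spec.kind in ("age", "age_flag"):
        age = index_date.year - int(person["birth_year"])
        return age if spec.kind == "age" else age >= spec.bound
    ids = resolve(spec.concept_set, db.vocabulary)
    ev = db.events_for(person_id)
    ev = ev[ev["concept_id"].isin(ids)]
    if spec.kind == "time_since_first_event":
        if ev.empty:
            return None
        return (index_date - ev["event_date"].min()).days / 365.25
    days = (ev["event_date"] - index_date).dt.days
    in_window = ev[(days >= -spec.days_before) & (days <= spec.days_after)]
    if spec.kind == "event_flag":
        return not in_window.empty
    if spec.kind == "event_count_category":
        return in_window["concept_id"].nunique()
    return select_measurement(in_window[in_window["domain"] == "measurement"],
                              index_date, spec.days_before, spec.days_after)


# ---------------------------------------------------------------------------
# vectorised summarisation
# ---------------------------------------------------------------------------

def _in_window_events(db: PatientDatabase, members: pd.DataFrame, spec) -> pd.DataFrame:
    ids = resolve(spec.concept_set, db.vocabulary)
    ev = db.events[db.events["concept_id"].isin(ids)]
    merged = ev.merge(members, on="person_id", how="inner")
    merged["days"] = (merged["event_date"] - merged["index_date"]).dt.days
    return merged[(merged["days"] >= -spec.days_before) & (merged["days"] <= spec.days_after)]


def _baseline_measurements(db: PatientDatabase, members: pd.DataFrame,
                           spec) -> pd.Series:
    """person_id -> baseline value for every member with one recorded."""
    meas = _in_window_events(db, members, spec)
    meas = meas[(meas["domain"] == "measurement") & meas["value"].notna()].copy()
    if meas.empty:
        return pd.Series(dtype=float)
    meas["after"] = (meas["days"] > 0).astype(int)
    meas["dist"] = meas["days"].abs()
    meas = meas.sort_values(["after", "dist"], kind="stable")
    chosen = meas.drop_duplicates("person_id", keep="first")
    return chosen.set_index("person_id")["value"].astype(float)


def _bin_ok(value: float, b: Bin) -> bool:
    if b.op == "lt":
        return value < b.high
    if b.op == "le":
        return value <= b.high
    if b.op == "gt":
        return value > b.low
    if b.op == "ge":
        return value >= b.low
    return b.low <= value <= b.high


def summarize(cohort: Cohort, db: PatientDatabase, specs: list[CharacteristicSpec],
              ned_threshold: int = DEFAULT_NED_THRESHOLD) -> CohortSummary:
    """Baseline summary of a cohort, one or more table rows per spec."""
    members = cohort.members
    n = len(members)
    rows: list[SummaryRow] = []
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")
    for spec in specs:
        if spec.kind == "demographic_category":
            col = f"{spec.field}_concept"
            persons = members.merge(db.persons[["person_id", col]], on="person_id")
            counts = persons[col].value_counts()
            for concept_id, row_name in spec.categories.items():
                c = int(counts.get(concept_id, 0))
                rows.append(SummaryRow(row_name, "discrete", 100.0 * c / n, n))
        elif spec.kind == "event_flag":
            hits = _in_window_events(db, members, spec)["person_id"].nunique()
            rows.append(SummaryRow(spec.name, "discrete", 100.0 * hits / n, n))
        elif spec.kind == "event_count_category":
            ev = _in_window_events(db, members, spec)
            per_person = ev.groupby("person_id")["concept_id"].nunique()
            counts = members["person_id"].map(per_person).fillna(0).astype(int)
            for b in spec.bins:
                lo = b.min_count if b.min_count is not None else 0
                hi = b.max_count if b.max_count is not None else np.inf
                c = int(((counts >= lo) & (counts <= hi)).sum())
                rows.append(SummaryRow(b.name, "discrete", 100.0 * c / n, n))
        elif spec.kind == "measurement":
            values = _baseline_measurements(db, members, spec)
            n_rec = len(values)
            if n_rec < ned_threshold:
                rows.append(SummaryRow(spec.name, "continuous", None, n_rec, ned=True))
            else:
                agg = getattr(np, spec.aggregate)(values.to_numpy())
                sd = float(values.std(ddof=1)) if n_rec > 1 else None
                rows.append(SummaryRow(spec.name, "continuous", float(agg), n_rec, sd=sd))
        elif spec.kind == "measurement_category":
            values = _baseline_measurements(db, members, spec)
            n_rec = len(values)
            ned = n_rec < ned_threshold
            for b in spec.bins:
                c = int(sum(_bin_ok(v, b) for v in values)) if not ned else 0
                rows.append(SummaryRow(b.name, "discrete",
                                       None if ned else 100.0 * c / n, n_rec, ned=ned))
            if spec.unknown_name:
                rows.append(SummaryRow(spec.unknown_name, "discrete",
                                       100.0 * (n - n_rec) / n, n))
        elif spec.kind in ("age", "age_flag"):
            persons = members.merge(db.persons[["person_id", "birth_year"]], on="person_id")
            age = (persons["index_date"].dt.year - persons["birth_year"]).to_numpy()
            if spec.kind == "age":
                rows.append(SummaryRow(spec.name, "continuous", float(age.mean()), n,
                                       sd=float(age.std(ddof=1)) if n > 1 else None))
            else:
                c = int((age >= spec.bound).sum())
                rows.append(SummaryRow(spec.name, "discrete", 100.0 * c / n, n))
        elif spec.kind == "time_since_first_event":
            ids = resolve(spec.concept_set, db.vocabulary)
            ev = db.events[db.events["concept_id"].isin(ids)]
            first = ev.groupby("person_id")["event_date"].min()
            merged = members.merge(first.rename("first_date"), left_on="person_id",
                                   right_index=True, how="inner")
            years = ((merged["index_date"] - merged["first_date"]).dt.days / 365.25)
            n_rec = len(years)
            if n_rec < ned_threshold:
                rows.append(SummaryRow(spec.name, "continuous", None, n_rec, ned=True))
            else:
                rows.append(SummaryRow(spec.name, "continuous", float(years.mean()), n_rec,
                                       sd=float(years.std(ddof=1)) if n_rec > 1 else None))
        else:  # pragma: no cover
            raise ValueError(f"unknown spec kind {spec.kind!r}")
    return CohortSummary(n=n, rows=rows)
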