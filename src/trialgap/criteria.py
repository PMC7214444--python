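"""Declarative cohort definitions and their evaluation against a patient database.

A cohort definition is an indication criterion (whose earliest qualifying
event fixes each member's index date) plus an ordered list of eligibility
criteria applied conjunctively. Criteria reference concept sets — include
and exclude lists over the vocabulary, each entry optionally pulling in the
concept's descendants — and temporal windows expressed in whole days
relative to the index date. Windows are closed intervals; the index day
belongs to both the "before" and the "after" side.

Two evaluation paths exist on purpose: :func:`build_cohort` is vectorised
over the event table, while :func:`evaluate_criterion` is a per-person
scan used as an independent check and by callers that need one verdict.
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

from .model import PatientDatabase, Vocabulary, descendants

log = logging.getLogger("trialgap.criteria")

CriterionKind = Literal[
    "has_event", "absent_event", "measurement_threshold",
    "age_range", "demographic_equals", "unoperationalizable",
]
Comparator = Literal["gt", "ge", "lt", "le", "between"]


class ConceptSetItem(BaseModel):
    concept_id: str
    include_descendants: bool = True


class ConceptSet(BaseModel):
    """Include/exclude lists over the vocabulary; resolves to a plain id set."""

    included: list[ConceptSetItem] = Field(default_factory=list)
    excluded: list[ConceptSetItem] = Field(default_factory=list)


def resolve(concept_set: ConceptSet, vocabulary: Vocabulary) -> frozenset[str]:
    """Union of included closures minus union of excluded closures."""

    def closure(items: list[ConceptSetItem]) -> set[str]:
        out: set[str] = set()
        for item in items:
            if item.include_descendants:
                out |= descendants(item.concept_id, vocabulary)
            else:
                if item.concept_id not in vocabulary:
                    raise_missing(item.concept_id)
                out.add(item.concept_id)
        return out

    def raise_missing(cid: str):
        from .model import VocabularyError
        raise VocabularyError(cid)

    return frozenset(closure(concept_set.included) - closure(concept_set.excluded))


class Criterion(BaseModel):
    """One computable inclusion/exclusion rule.

    ``days_before``/``days_after`` bound the event window
    ``[index - days_before, index + days_after]``. ``measurement_threshold``
    applies ``comparator`` to the qualifying in-window measurement (the one
    closest to, and preferably not after, the index date); a person with no
    in-window measurement fails the criterion, mirroring a trial's screening
    lab requirement. ``unoperationalizable`` marks a soft criterion that
    cannot be phrased over coded data; the engine skips it with a warning.
    """

    name: str = ""
    kind: CriterionKind
    concept_set: Optional[ConceptSet] = None
    days_before: int = Field(default=0, ge=0)
    days_after: int = Field(default=0, ge=0)
    comparator: Optional[Comparator] = None
    low: Optional[float] = None
    high: Optional[float] = None
    min_age: Optional[int] = None
    max_age: Optional[int] = None
    field: Optional[Literal["gender", "race", "ethnicity"]] = None
    description: str = ""

    @model_validator(mode="after")
    def _check(self):
        if self.kind in ("has_event", "absent_event", "measurement_threshold") \
                and self.concept_set is None:
            raise ValueError(f"{self.kind} criterion requires a concept_set")
        if self.kind == "measurement_threshold":
            if self.comparator is None:
                raise ValueError("measurement_threshold requires a comparator")
            if self.comparator == "between":
                if self.low is None or self.high is None or self.low > self.high:
                    raise ValueError("between requires low <= high")
            elif self.comparator in ("gt", "ge") and self.low is None:
                raise ValueError(f"{self.comparator} requires 'low'")
            elif self.comparator in ("lt", "le") and self.high is None:
                raise ValueError(f"{self.comparator} requires 'high'")
        if self.kind == "age_range" and self.min_age is None and self.max_age is None:
            raise ValueError("age_range requires min_age and/or max_age")
        if self.kind == "demographic_equals" and (self.field is None or self.concept_set is None):
            raise ValueError("demographic_equals requires field and concept_set")
        return self


class CohortDefinition(BaseModel):
    name: str = ""
    indication: Criterion
    eligibility: list[Criterion] = Field(default_factory=list)
    mode: Literal["indication_only", "indication_plus_criteria"] = "indication_plus_criteria"

    @model_validator(mode="after")
    def _check(self):
        if self.indication.kind != "has_event":
            raise ValueError("indication must be a has_event criterion")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDefinition":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(exclude_none=True), fh, sort_keys=False)


@dataclasses.dataclass
class Cohort:
    """Materialised cohort: (person_id, index_date) members plus attrition log."""

    members: pd.DataFrame  # columns: person_id, index_date
    definition: CohortDefinition
    mode: str
    attrition: list[tuple[str, int]]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def person_ids(self) -> frozenset[str]:
        return frozenset(self.members["person_id"])

    def to_csv(self, path: str | Path) -> None:
        out = self.members.copy()
        out["index_date"] = out["index_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def _comparator_ok(value: float, criterion: Criterion) -> bool:
    c = criterion.comparator
    if c == "gt":
        return value > criterion.low
    if c == "ge":
        return value >= criterion.low
    if c == "lt":
        return value < criterion.high
    if c == "le":
        return value <= criterion.high
    return criterion.low <= value <= criterion.high


def select_measurement(events: pd.DataFrame, index_date: pd.Timestamp,
                       days_before: int, days_after: int) -> Optional[float]:
    """Qualifying measurement value for one person, or None.

    Among in-window values: prefer dates not after the index, closest to it;
    otherwise the earliest post-index date; ties resolved by record order.
    """
    if events.empty:
        return None
    days = (events["event_date"] - index_date).dt.days
    ok = (days >= -days_before) & (days <= days_after) & events["value"].notna()
    if not ok.any():
        return None
    sub = events[ok]
    d = days[ok]
    key = pd.DataFrame({"after": (d > 0).astype(int), "dist": d.abs()}, index=sub.index)
    best = key.sort_values(["after", "dist"], kind="stable").index[0]
    return float(sub.loc[best, "value"])


def evaluate_criterion(db: PatientDatabase, person_id: str, criterion: Criterion,
                       index_date: pd.Timestamp) -> bool:
    """Per-person, per-event reference evaluation (no vectorisation)."""
    if criterion.kind == "unoperationalizable":
        log.warning("criterion %r is not operationalizable; ignored", criterion.name)
        return True
    person = db.person(person_id)
    if criterion.kind == "age_range":
        age = index_date.year - int(person["birth_year"])
        lo = criterion.min_age if criterion.min_age is not None else -np.inf
        hi = criterion.max_age if criterion.max_age is not None else np.inf
        return lo <= age <= hi
    if criterion.kind == "demographic_equals":
        ids = resolve(criterion.concept_set, db.vocabulary)
        return str(person[f"{criterion.field}_concept"]) in ids
    ids = resolve(criterion.concept_set, db.vocabulary)
    ev = db.events_for(person_id)
    ev = ev[ev["concept_id"].isin(ids)]
    if criterion.kind in ("has_event", "absent_event"):
        days = (ev["event_date"] - index_date).dt.days
        hit = bool(((days >= -criterion.days_before) & (days <= criterion.days_after)).any())
        return hit if criterion.kind == "has_event" else not hit
    # measurement_threshold
    value = select_measurement(ev[ev["domain"] == "measurement"], index_date,
                               criterion.days_before, criterion.days_after)
    if value is None:
        return False
    return _comparator_ok(value, criterion)


# ---------------------------------------------------------------------------
# vectorised path
# ---------------------------------------------------------------------------

def _members_with_days(db: PatientDatabase, members: pd.DataFrame,
                       ids: frozenset[str]) -> pd.DataFrame:
    ev = db.events[db.events["concept_id"].isin(ids)]
    merged = ev.merge(members, on="person_id", how="inner")
    merged["days"] = (merged["event_date"] - merged["index_date"]).dt.days
    return merged

def _criterion_mask(db: PatientDatabase, members: pd.DataFrame,
                    criterion: Criterion) -> pd.Series:
    """Boolean verdict per member row, vectorised over the event table."""
    idx = members.index
    if criterion.kind == "unoperationalizable":
        log.warning("criterion %r is not operationalizable; ignored", criterion.name)
        return pd.Series(True, index=idx)
    if criterion.kind == "age_range":
        persons = members.merge(db.persons[["person_id", "birth_year"]], on="person_id")
        age = persons["index_date"].dt.year.to_numpy() - persons["birth_year"].to_numpy()
        ok = np.ones(len(members), dtype=bool)
        if criterion.min_age is not None:
            ok &= age >= criterion.min_age
        if criterion.max_age is not None:
            ok &= age <= criterion.max_age
        return pd.Series(ok, index=idx)
    if criterion.kind == "demographic_equals":
        ids = resolve(criterion.concept_set, db.vocabulary)
        col = f"{criterion.field}_concept"
        persons = members.merge(db.persons[["person_id", col]], on="person_id")
        return pd.Series(persons[col].isin(ids).to_numpy(), index=idx)

    ids = resolve(criterion.concept_set, db.vocabulary)
    merged = _members_with_days(db, members, ids)
    in_window = merged[(merged["days"] >= -criterion.days_before)
                       & (merged["days"] <= criterion.days_after)]
    if criterion.kind in ("has_event", "absent_event"):
        hit_ids = set(in_window["person_id"])
        hit = members["person_id"].isin(hit_ids)
        return hit if criterion.kind == "has_event" else ~hit
    # measurement_threshold: pick the qualifying value per person, then compare
    meas = in_window[(in_window["domain"] == "measurement") & in_window["value"].notna()].copy()
    if meas.empty:
        return pd.Series(False, index=idx)
    meas["after"] = (meas["days"] > 0).astype(int)
    meas["dist"] = meas["days"].abs()
    meas = meas.sort_values(["after", "dist"], kind="stable")
    chosen = meas.drop_duplicates("person_id", keep="first")
    ok_vals = chosen[[_comparator_ok(v, criterion) for v in chosen["value"]]]
    passed = set(ok_vals["person_id"])
    return members["person_id"].isin(passed)


def build_cohort(db: PatientDatabase, definition: CohortDefinition,
                 mode: str | None = None) -> Cohort:
    """Materialise a cohort; index date = earliest qualifying indication event.

    ``indication_only`` keeps every person with at least one indication
    event; ``indication_plus_criteria`` additionally requires every
    eligibility criterion to hold at that index date. Per-criterion
    attrition counts are logged and returned on the cohort.
    """
    mode = mode or definition.mode
    if mode not in ("indication_only", "indication_plus_criteria"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = resolve(definition.indication.concept_set, db.vocabulary)
    ev = db.events[db.events["concept_id"].isin(ids)]
    if ev.empty:
        members = pd.DataFrame(columns=["person_id", "index_date"])
        members["index_date"] = pd.to_datetime(members["index_date"])
    else:
        members = (ev.groupby("person_id", as_index=False)["event_date"].min()
                     .rename(columns={"event_date": "index_date"}))
    members = members.sort_values("person_id", ignore_index=True)
    attrition = [("indication", len(members))]
    if mode == "indication_plus_criteria":
        for i, criterion in enumerate(definition.eligibility):
            if members.empty:
                attrition.append((criterion.name or f"criterion_{i}", 0))
                continue
            mask = _criterion_mask(db, members, criterion)
            members = members[mask.to_numpy()].reset_index(drop=True)
            attrition.append((criterion.name or f"criterion_{i}", len(members)))
            log.info("cohort %s: after %r -> %d members",
                     definition.name, criterion.name, len(members))
    return Cohort(members=members, definition=definition, mode=mode, attrition=attrition)
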