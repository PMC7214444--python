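"""Shared fixtures: a small three-level vocabulary, hand-built patient
databases, and random toy databases/definitions for property tests."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trialgap.criteria import (CohortDefinition, ConceptSet, ConceptSetItem,
                               Criterion)
from trialgap.model import Concept, ConceptHierarchy, PatientDatabase, Vocabulary

# three-level, seven-node condition tree:  ROOT -> {B, C}; B -> {D, E}; C -> {F, G}
TOY_EDGES = [("ROOT", "B"), ("ROOT", "C"), ("B", "D"), ("B", "E"), ("C", "F"), ("C", "G")]
TOY_CONDITIONS = ["ROOT", "B", "C", "D", "E", "F", "G"]


@pytest.fixture(scope="session")
def toy_vocabulary() -> Vocabulary:
    concepts = [Concept(cid, "condition", f"condition {cid}") for cid in TOY_CONDITIONS]
    concepts += [
        Concept("M1", "measurement", "toy lab"),
        Concept("M2", "measurement", "second toy lab"),
        Concept("DRUG1", "drug", "toy drug"),
        Concept("G_MALE", "demographic", "male"),
        Concept("G_FEMALE", "demographic", "female"),
        Concept("G_UNKNOWN", "demographic", "unknown gender"),
        Concept("E_UNKNOWN", "demographic", "unknown ethnicity"),
    ]
    return Vocabulary(concepts, ConceptHierarchy(TOY_EDGES))


def make_persons(n: int, genders=None) -> pd.DataFrame:
    return pd.DataFrame({
        "person_id": [f"T{i:03d}" for i in range(n)],
        "birth_year": [1950 + (i % 40) for i in range(n)],
        "gender_concept": genders if genders is not None
        else ["G_MALE" if i % 2 else "G_FEMALE" for i in range(n)],
        "race_concept": "G_UNKNOWN",
        "ethnicity_concept": "E_UNKNOWN",
        "observation_start": pd.Timestamp("2000-01-01"),
        "observation_end": pd.Timestamp("2020-12-31"),
    })


def make_db(vocabulary: Vocabulary, persons: pd.DataFrame,
            events: list[tuple] ) -> PatientDatabase:
    """events: (person_id, concept_id, date_str, value_or_None)"""
    frame = pd.DataFrame(events, columns=["person_id", "concept_id", "event_date", "value"])
    frame["domain"] = frame["concept_id"].map(
        lambda c: vocabulary.concepts[c].domain if c in vocabulary.concepts else "condition")
    frame["event_date"] = pd.to_datetime(frame["event_date"])
    frame["unit"] = None
    cols = ["person_id", "concept_id", "domain", "event_date", "value", "unit"]
    return PatientDatabase(persons, frame[cols], vocabulary)


@pytest.fixture
def toy_db(toy_vocabulary) -> PatientDatabase:
    persons = make_persons(4)
    events = [
        ("T000", "D", "2010-06-01", None),
        ("T000", "M1", "2010-05-02", 7.0),
        ("T000", "M1", "2010-02-21", 9.0),
        ("T001", "B", "2012-01-15", None),
        ("T001", "M1", "2012-01-01", 5.0),
        ("T002", "ROOT", "2015-03-03", None),
        ("T003", "G", "2018-07-07", None),
    ]
    return make_db(toy_vocabulary, persons, events)


def random_toy_db(rng: np.random.Generator, vocabulary: Vocabulary,
                  n_persons: int) -> PatientDatabase:
    persons = make_persons(n_persons)
    n_events = n_persons * 8
    pids = rng.choice(persons["person_id"].to_numpy(), size=n_events)
    concepts = rng.choice(np.array(TOY_CONDITIONS + ["M1", "M2", "DRUG1"], dtype=object),
                          size=n_events)
    offsets = rng.integers(0, 7000, size=n_events)
    events = pd.DataFrame({
        "person_id": pids,
        "concept_id": concepts,
        "event_date": pd.Timestamp("2000-06-01") + pd.to_timedelta(offsets, unit="D"),
    })
    events["domain"] = events["concept_id"].map(lambda c: vocabulary.concepts[c].domain)
    is_meas = events["domain"] == "measurement"
    events["value"] = np.where(is_meas, rng.normal(8.0, 3.0, size=n_events).round(2), np.nan)
    events["unit"] = None
    return PatientDatabase(persons, events, vocabulary)


def random_definition(rng: np.random.Generator) -> CohortDefinition:
    def random_concept_set(pool) -> ConceptSet:
        k = int(rng.integers(1, 3))
        included = [ConceptSetItem(concept_id=str(c),
                                   include_descendants=bool(rng.integers(0, 2)))
                    for c in rng.choice(pool, size=k, replace=False)]
        excluded = []
        if rng.random() < 0.3:
            excluded = [ConceptSetItem(concept_id=str(rng.choice(pool)),
                                       include_descendants=bool(rng.integers(0, 2)))]
        return ConceptSet(included=included, excluded=excluded)

    indication = Criterion(name="ind", kind="has_event",
                           concept_set=random_concept_set(TOY_CONDITIONS))
    eligibility = []
    n_crit = int(rng.integers(0, 4))
    for i in range(n_crit):
        kind = rng.choice(["has_event", "absent_event", "measurement_threshold",
                           "age_range", "demographic_equals"])
        if kind in ("has_event", "absent_event"):
            eligibility.append(Criterion(
                name=f"c{i}", kind=str(kind),
                concept_set=random_concept_set(TOY_CONDITIONS),
                days_before=int(rng.integers(0, 4000)),
                days_after=int(rng.integers(0, 400))))
        elif kind == "measurement_threshold":
            low = float(rng.normal(8, 2))
            eligibility.append(Criterion(
                name=f"c{i}", kind="measurement_threshold",
                concept_set=ConceptSet(included=[ConceptSetItem(concept_id="M1")]),
                days_before=int(rng.integers(30, 2000)),
                days_after=int(rng.integers(0, 100)),
                comparator="between", low=low, high=low + float(rng.uniform(0.5, 6))))
        elif kind == "age_range":
            lo = int(rng.integers(20, 60))
            eligibility.append(Criterion(name=f"c{i}", kind="age_range",
                                         min_age=lo, max_age=lo + int(rng.integers(5, 40))))
        else:
            eligibility.append(Criterion(
                name=f"c{i}", kind="demographic_equals", field="gender",
                concept_set=ConceptSet(included=[
                    ConceptSetItem(concept_id=str(rng.choice(["G_MALE", "G_FEMALE"])),
                                   include_descendants=False)])))
    return CohortDefinition(name="random", indication=indication,
                            eligibility=eligibility)
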