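"""Longitudinal patient-record structures and the concept vocabulary.

The package operates on a deliberately small, OMOP-flavoured data model:
persons with a single observation window, dated clinical events in five
domains (condition, drug, measurement, procedure, demographic), and a
vocabulary of concepts related by is-a edges. Concept identifiers are
opaque strings; no external vocabulary licence is assumed.

On disk a :class:`PatientDatabase` is one UTF-8 CSV per domain
(``persons.csv``, ``condition_occurrence.csv``, ``drug_exposure.csv``,
``measurement.csv``, ``procedure_occurrence.csv``) plus ``vocabulary.csv``
and ``hierarchy.csv`` (``parent_id,child_id``). Dates are ISO-8601 calendar
dates; all temporal logic elsewhere in the package treats them at day
resolution with closed intervals.
"""
from __future__ import annotations

import dataclasses
from collections import deque
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

DOMAINS = ("condition", "drug", "measurement", "procedure", "demographic")

#: demographic concept id used for explicitly unknown gender/race
UNKNOWN = "UNKNOWN"

_DOMAIN_FILES = {
    "condition": "condition_occurrence.csv",
    "drug": "drug_exposure.csv",
    "measurement": "measurement.csv",
    "procedure": "procedure_occurrence.csv",
}


class VocabularyError(KeyError):
    """Raised when a concept id does not resolve in the vocabulary."""


@dataclasses.dataclass(frozen=True)
class Concept:
    concept_id: str
    domain: str
    label: str

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r} for {self.concept_id}")


class ConceptHierarchy:
    """Directed acyclic is-a relations over concept ids (parent -> children)."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self.children: dict[str, set[str]] = {}
        for parent, child in edges:
            self.children.setdefault(parent, set()).add(child)
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        seen: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(node: str, stack: list[str]) -> None:
            state = seen.get(node)
            if state == 1:
                return
            if state == 0:
                raise ValueError(f"hierarchy cycle through {node!r}")
            seen[node] = 0
            for ch in self.children.get(node, ()):
                visit(ch, stack)
            seen[node] = 1

        for node in list(self.children):
            visit(node, [])

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for p, cs in self.children.items() for c in cs)


class Vocabulary:
    """Concept registry plus hierarchy; the unit the criteria engine resolves against."""

    def __init__(self, concepts: Iterable[Concept], hierarchy: ConceptHierarchy | None = None):
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.concept_id in self.concepts:
                raise ValueError(f"duplicate concept id {c.concept_id!r}")
            self.concepts[c.concept_id] = c
        self.hierarchy = hierarchy or ConceptHierarchy()
        self._closure_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def domain(self, concept_id: str) -> str:
        try:
            return self.concepts[concept_id].domain
        except KeyError:
            raise VocabularyError(concept_id) from None

    def descendants(self, concept_id: str) -> frozenset[str]:
        """Transitive is-a closure of ``concept_id``, including itself."""
        return descendants(concept_id, self)

    @classmethod
    def from_frames(cls, vocab: pd.DataFrame, hier: pd.DataFrame) -> "Vocabulary":
        concepts = [Concept(str(r.concept_id), str(r.domain), str(r.label))
                    for r in vocab.itertuples()]
        edges = [(str(r.parent_id), str(r.child_id)) for r in hier.itertuples()]
        return cls(concepts, ConceptHierarchy(edges))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        vocab = pd.DataFrame(
            [(c.concept_id, c.domain, c.label) for c in self.concepts.values()],
            columns=["concept_id", "domain", "label"],
        ).sort_values("concept_id", ignore_index=True)
        hier = pd.DataFrame(self.hierarchy.edges(), columns=["parent_id", "child_id"])
        return vocab, hier


def descendants(concept_id: str, vocabulary: "Vocabulary | ConceptHierarchy") -> frozenset[str]:
    """Transitive is-a closure of a concept (the concept itself included).

    Breadth-first over the child relation; deterministic for a given
    hierarchy. Unknown ids raise :class:`VocabularyError` when a full
    vocabulary is supplied.
    """
    if isinstance(vocabulary, Vocabulary):
        if concept_id not in vocabulary:
            raise VocabularyError(concept_id)
        cached = vocabulary._closure_cache.get(concept_id)
        if cached is not None:
            return cached
        hierarchy = vocabulary.hierarchy
    else:
        hierarchy = vocabulary
    out = {concept_id}
    queue = deque([concept_id])
    while queue:
        node = queue.popleft()
        for child in hierarchy.children.get(node, ()):
            if child not in out:
                out.add(child)
                queue.append(child)
    result = frozenset(out)
    if isinstance(vocabulary, Vocabulary):
        vocabulary._closure_cache[concept_id] = result
    return result


@dataclasses.dataclass(frozen=True)
class Person:
    person_id: str
    birth_year: int
    gender_concept: str
    race_concept: str
    ethnicity_concept: str
    observation_start: pd.Timestamp
    observation_end: pd.Timestamp


@dataclasses.dataclass(frozen=True)
class ClinicalEvent:
    person_id: str
    concept_id: str
    event_date: pd.Timestamp
    value: float | None = None
    unit: str | None = None


_PERSON_COLS = ["person_id", "birth_year", "gender_concept", "race_concept",
                "ethnicity_concept", "observation_start", "observation_end"]
_EVENT_COLS = ["person_id", "concept_id", "domain", "event_date", "value", "unit"]


class PatientDatabase:
    """Persons + events + vocabulary, held as pandas frames.

    ``persons`` columns: person_id, birth_year, gender_concept, race_concept,
    ethnicity_concept, observation_start, observation_end.
    ``events`` columns: person_id, concept_id, domain, event_date, value, unit
    (value/unit only for measurements).
    """

    def __init__(self, persons: pd.DataFrame, events: pd.DataFrame, vocabulary: Vocabulary):
        self.persons = persons.reset_index(drop=True)
        self.events = events.reset_index(drop=True)
        self.vocabulary = vocabulary
        for col in ("observation_start", "observation_end"):
            self.persons[col] = pd.to_datetime(self.persons[col])
        if len(self.events):
            self.events["event_date"] = pd.to_datetime(self.events["event_date"])

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def events_for(self, person_id: str) -> pd.DataFrame:
        return self.events[self.events["person_id"] == person_id]

    def person(self, person_id: str) -> pd.Series:
        rows = self.persons[self.persons["person_id"] == person_id]
        if rows.empty:
            raise KeyError(person_id)
        return rows.iloc[0]

    # -- on-disk representation -------------------------------------------------
    def write_csv_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        persons = self.persons.copy()
        persons["observation_start"] = persons["observation_start"].dt.strftime("%Y-%m-%d")
        persons["observation_end"] = persons["observation_end"].dt.strftime("%Y-%m-%d")
        persons[_PERSON_COLS].to_csv(directory / "persons.csv", index=False)
        events = self.events.copy()
        if len(events):
            events["event_date"] = events["event_date"].dt.strftime("%Y-%m-%d")
        events = events.sort_values(
            ["person_id", "event_date", "concept_id"], kind="stable", ignore_index=True)
        for domain, fname in _DOMAIN_FILES.items():
            sub = events[events["domain"] == domain]
            cols = _EVENT_COLS if domain == "measurement" else _EVENT_COLS[:4]
            sub[cols].to_csv(directory / fname, index=False)
        vocab, hier = self.vocabulary.to_frames()
        vocab.to_csv(directory / "vocabulary.csv", index=False)
        hier.to_csv(directory / "hierarchy.csv", index=False)

    @classmethod
    def read_csv_dir(cls, directory: str | Path) -> "PatientDatabase":
        directory = Path(directory)
        persons = pd.read_csv(directory / "persons.csv", dtype={"person_id": str})
        vocab = pd.read_csv(directory / "vocabulary.csv", dtype=str)
        hier = pd.read_csv(directory / "hierarchy.csv", dtype=str)
        frames = []
        for domain, fname in _DOMAIN_FILES.items():
            path = directory / fname
            if not path.exists():
                continue
            sub = pd.read_csv(path, dtype={"person_id": str, "concept_id": str})
            if sub.empty:
                continue
            sub["domain"] = domain
            if "value" not in sub.columns:
                sub["value"] = float("nan")
                sub["unit"] = None
            frames.append(sub[_EVENT_COLS])
        events = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame(columns=_EVENT_COLS))
        if len(events):
            events = events.sort_values(
                ["person_id", "event_date", "concept_id"], kind="stable", ignore_index=True)
        return cls(persons, events, Vocabulary.from_frames(vocab, hier))


@dataclasses.dataclass(frozen=True)
class Violation:
    code: str
    message: str


def validate_database(db: PatientDatabase) -> list[Violation]:
    """Referential-integrity and invariant check; an empty list means valid.

    Violations are report content, never exceptions: the validator is meant
    to run on arbitrary (possibly broken) inputs.
    """
    out: list[Violation] = []
    persons, events = db.persons, db.events

    dup = persons["person_id"][persons["person_id"].duplicated()]
    for pid in dup.unique():
        out.append(Violation("duplicate_person", f"person_id {pid!r} appears more than once"))

    bad_window = persons[persons["observation_start"] > persons["observation_end"]]
    for pid in bad_window["person_id"]:
        out.append(Violation("observation_window", f"person {pid!r} has start after end"))

    for col in ("gender_concept", "race_concept", "ethnicity_concept"):
        missing = persons[~persons[col].isin(db.vocabulary.concepts) & (persons[col] != UNKNOWN)]
        for pid, cid in zip(missing["person_id"], missing[col]):
            out.append(Violation("unknown_concept", f"person {pid!r} {col} {cid!r} not in vocabulary"))

    if len(events) == 0:
        return out

    known_persons = set(persons["person_id"])
    dangling = events[~events["person_id"].isin(known_persons)]
    for pid in dangling["person_id"].unique():
        out.append(Violation("dangling_person", f"event references unknown person_id {pid!r}"))

    unknown_c = events[~events["concept_id"].isin(db.vocabulary.concepts)]
    for cid in unknown_c["concept_id"].unique():
        out.append(Violation("unknown_concept", f"event concept_id {cid!r} not in vocabulary"))

    vocab_domain = {cid: c.domain for cid, c in db.vocabulary.concepts.items()}
    ev_dom = events["concept_id"].map(vocab_domain)
    mismatch = events[(ev_dom.notna()) & (ev_dom != events["domain"])]
    for _, row in mismatch.iterrows():
        out.append(Violation(
            "domain_mismatch",
            f"event concept {row['concept_id']!r} recorded in domain {row['domain']!r}"))

    meas = events[events["domain"] == "measurement"]
    n_missing_value = int(meas["value"].isna().sum())
    if n_missing_value:
        out.append(Violation("measurement_value",
                             f"{n_missing_value} measurement event(s) lack a numeric value"))
    nonmeas = events[(events["domain"] != "measurement") & events["value"].notna()]
    if len(nonmeas):
        out.append(Violation("unexpected_value",
                             f"{len(nonmeas)} non-measurement event(s) carry a value"))

    merged = events.merge(persons[["person_id", "observation_start", "observation_end"]],
                          on="person_id", how="inner")
    outside = merged[(merged["event_date"] < merged["observation_start"])
                     | (merged["event_date"] > merged["observation_end"])]
    if len(outside):
        out.append(Violation("event_outside_observation",
                             f"{len(outside)} event(s) fall outside the person's observation window"))
    return out
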