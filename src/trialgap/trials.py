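"""Packaged assets for the four source trials.

For each trial the package ships four text artifacts:

* ``<id>.json`` — the machine-readable transcription of the published
  baseline-characteristics table (arms, sigma column, printed pooled and
  cohort columns with their discrepancy cells and audit flags);
* ``<id>_map.yaml`` — the emulation map tying each table row to a concept,
  a window and generator scale parameters;
* ``<id>_definition.yaml`` — the indication plus a representative,
  operationalizable subset of the trial's eligibility criteria.
* the shared toy vocabulary under ``data/vocabulary``.

This module materialises the map into the characteristic specs that
:func:`trialgap.baseline.summarize` consumes, so the generator and the
summariser read the same row-to-concept assignments.
"""
from __future__ import annotations

from .baseline import Bin, CharacteristicSpec
from .criteria import CohortDefinition, ConceptSet, ConceptSetItem
from .rct import TRIAL_IDS, TrialSummary, load_packaged_trial
from .synth import _data_path, load_emulation_map, trial_emulation_config  # noqa: F401

__all__ = [
    "TRIAL_IDS", "load_packaged_trial", "trial_emulation_config",
    "trial_characteristic_specs", "load_trial_definition", "link_excluded_rows",
]


def _concept_set(entry: dict) -> ConceptSet:
    if "concept_ids" in entry:
        items = [ConceptSetItem(concept_id=c, include_descendants=True)
                 for c in entry["concept_ids"]]
    else:
        items = [ConceptSetItem(concept_id=entry["concept_id"],
                                include_descendants=entry.get("include_descendants", True))]
    return ConceptSet(included=items)


def trial_characteristic_specs(trial_id: str) -> list[CharacteristicSpec]:
    """Characteristic specs matching the trial table, in table order."""
    emap = load_emulation_map(trial_id)
    specs: list[CharacteristicSpec] = []
    for entry in emap["characteristics"]:
        kind = entry["kind"]
        if kind == "demographic_category":
            specs.append(CharacteristicSpec(
                name=f"{entry['field']}_distribution", kind="demographic_category",
                field=entry["field"], categories=entry["categories"]))
        elif kind == "age":
            specs.append(CharacteristicSpec(name=entry["row"], kind="age"))
        elif kind == "age_flags":
            for row, bound in entry["rows"].items():
                specs.append(CharacteristicSpec(name=row, kind="age_flag", bound=bound))
        elif kind == "event_flag":
            specs.append(CharacteristicSpec(
                name=entry["row"], kind="event_flag", concept_set=_concept_set(entry),
                days_before=entry.get("days_before", 3650),
                days_after=entry.get("days_after", 0)))
        elif kind == "event_count_category":
            specs.append(CharacteristicSpec(
                name="event_count", kind="event_count_category",
                concept_set=_concept_set(entry),
                days_before=entry.get("days_before", 365),
                days_after=entry.get("days_after", 0),
                bins=[Bin.model_validate(b) for b in entry["bins"]]))
        elif kind == "index_subtypes":
            for row, concept_id in entry["rows"].items():
                specs.append(CharacteristicSpec(
                    name=row, kind="event_flag",
                    concept_set=ConceptSet(included=[
                        ConceptSetItem(concept_id=concept_id, include_descendants=True)]),
                    days_before=0, days_after=0))
        elif kind == "measurement":
            base = dict(concept_set=_concept_set(entry),
                        days_before=entry.get("days_before", 365),
                        days_after=entry.get("days_after", 0))
            specs.append(CharacteristicSpec(
                name=entry["row"], kind="measurement",
                aggregate=entry.get("aggregate", "mean"), **base))
            for agg, row in entry.get("extra_aggregates", {}).items():
                specs.append(CharacteristicSpec(
                    name=row, kind="measurement", aggregate=agg, **base))
            cat = entry.get("category")
            if cat:
                specs.append(CharacteristicSpec(
                    name=f"{entry['row']}_categories", kind="measurement_category",
                    bins=[Bin.model_validate(b) for b in cat["bins"]],
                    unknown_name=cat.get("unknown_name"), **base))
        elif kind == "time_since_first_event":
            specs.append(CharacteristicSpec(
                name=entry["row"], kind="time_since_first_event",
                concept_set=_concept_set(entry)))
        else:
            raise ValueError(f"{trial_id}: unknown map kind {kind!r}")
    return specs


def load_trial_definition(trial_id: str) -> CohortDefinition:
    if trial_id not in TRIAL_IDS:
        raise KeyError(f"unknown trial id {trial_id!r}")
    return CohortDefinition.from_yaml(_data_path("trials", f"{trial_id}_definition.yaml"))


def link_excluded_rows(trial_id: str) -> frozenset[str]:
    """Table rows the generator deliberately does not recover (documented in the map)."""
    return frozenset(load_emulation_map(trial_id).get("link_exclude", []))


def figure_excluded_rows(trial_id: str) -> frozenset[str]:
    """Rows dropped from the paired-delta figure (implausible extreme values)."""
    return frozenset(load_emulation_map(trial_id).get("figure_exclude", []))
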