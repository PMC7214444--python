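"""Concept-set resolution and cohort construction vs. a brute-force evaluator."""
import numpy as np
import pandas as pd
import pytest

from trialgap.criteria import (CohortDefinition, ConceptSet, ConceptSetItem,
                               Criterion, build_cohort, evaluate_criterion,
                               resolve)
from trialgap.model import VocabularyError

from conftest import random_definition, random_toy_db, make_db, make_persons


def cs(*included, excluded=()):
    return ConceptSet(
        included=[ConceptSetItem(concept_id=c) for c in included],
        excluded=[ConceptSetItem(concept_id=c) for c in excluded])


# ---------------------------------------------------------------------------
# brute-force oracle: plain python loops, no concept-set precomputation
# ---------------------------------------------------------------------------

def oracle_closure(vocab, cid):
    out, stack = {cid}, [cid]
    while stack:
        node = stack.pop()
        for child in sorted(vocab.hierarchy.children.get(node, ())):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def oracle_resolve(concept_set, vocab):
    inc, exc = set(), set()
    for item in concept_set.included:
        inc |= oracle_closure(vocab, item.concept_id) if item.include_descendants \
            else {item.concept_id}
    for item in concept_set.excluded:
        exc |= oracle_closure(vocab, item.concept_id) if item.include_descendants \
            else {item.concept_id}
    return inc - exc


def oracle_criterion(db, person_row, criterion, index_date):
    """Scan every event of the person; no vectorisation, no caching."""
    if criterion.kind == "unoperationalizable":
        return True
    if criterion.kind == "age_range":
        age = index_date.year - int(person_row["birth_year"])
        return ((criterion.min_age is None or age >= criterion.min_age)
                and (criterion.max_age is None or age <= criterion.max_age))
    if criterion.kind == "demographic_equals":
        allowed = oracle_resolve(criterion.concept_set, db.vocabulary)
        return person_row[f"{criterion.field}_concept"] in allowed
    ids = oracle_resolve(criterion.concept_set, db.vocabulary)
    lo = index_date - pd.Timedelta(days=criterion.days_before)
    hi = index_date + pd.Timedelta(days=criterion.days_after)
    in_window = []
    for _, ev in db.events[db.events["person_id"] == person_row["person_id"]].iterrows():
        if ev["concept_id"] in ids and lo <= ev["event_date"] <= hi:
            in_window.append(ev)
    if criterion.kind == "has_event":
        return len(in_window) > 0
    if criterion.kind == "absent_event":
        return len(in_window) == 0
    meas = [ev for ev in in_window
            if ev["domain"] == "measurement" and not pd.isna(ev["value"])]
    if not meas:
        return False
    not_after = [ev for ev in meas if ev["event_date"] <= index_date]
    pool = not_after if not_after else meas
    pool.sort(key=lambda ev: abs((ev["event_date"] - index_date).days))
    value = pool[0]["value"]
    if criterion.comparator == "between":
        return criterion.low <= value <= criterion.high
    return {"gt": value > (criterion.low or 0), "ge": value >= (criterion.low or 0),
            "lt": value < (criterion.high or 0), "le": value <= (criterion.high or 0),
            }[criterion.comparator]


def oracle_cohort(db, definition, mode):
    ids = oracle_resolve(definition.indication.concept_set, db.vocabulary)
    members = {}
    for _, person in db.persons.iterrows():
        dates = [ev["event_date"] for _, ev in
                 db.events[db.events["person_id"] == person["person_id"]].iterrows()
                 if ev["concept_id"] in ids]
        if not dates:
            continue
        index_date = min(dates)
        if mode == "indication_plus_criteria":
            if not all(oracle_criterion(db, person, c, index_date)
                       for c in definition.eligibility):
                continue
        members[person["person_id"]] = index_date
    return members


def as_dict(cohort):
    return dict(zip(cohort.members["person_id"], cohort.members["index_date"]))


# ---------------------------------------------------------------------------

class TestResolve:
    def test_root_minus_child_closure(self, toy_vocabulary):
        got = resolve(cs("ROOT", excluded=("B",)), toy_vocabulary)
        assert got == frozenset({"ROOT", "C", "F", "G"})

    def test_empty_included_is_empty(self, toy_vocabulary):
        assert resolve(cs(), toy_vocabulary) == frozenset()

    def test_include_exclude_same_leaf_is_empty(self, toy_vocabulary):
        assert resolve(cs("D", excluded=("D",)), toy_vocabulary) == frozenset()

    def test_unknown_concept_raises(self, toy_vocabulary):
        with pytest.raises(VocabularyError):
            resolve(cs("MISSING"), toy_vocabulary)

    def test_matches_set_algebra_oracle_on_random_sets(self, toy_vocabulary):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = random_definition(rng)
            s = d.indication.concept_set
            assert resolve(s, toy_vocabulary) == frozenset(
                oracle_resolve(s, toy_vocabulary))


class TestEvaluateCriterion:
    @pytest.fixture
    def person_db(self, toy_vocabulary):
        return make_db(toy_vocabulary, make_persons(1),
                       [("T000", "D", "2010-05-02", None)])  # 30 days before index

    def test_event_in_lookback_window_found(self, person_db):
        c = Criterion(kind="has_event", concept_set=cs("D"), days_before=365)
        assert evaluate_criterion(person_db, "T000", c, pd.Timestamp("2010-06-01"))

    def test_absent_event_is_negation(self, person_db):
        c = Criterion(kind="absent_event", concept_set=cs("D"), days_before=365)
        assert not evaluate_criterion(person_db, "T000", c, pd.Timestamp("2010-06-01"))

    def test_measurement_missing_fails_threshold(self, toy_db):
        c = Criterion(kind="measurement_threshold", concept_set=cs("M1"),
                      days_before=365, comparator="ge", low=1.0)
        # T002 has no M1 measurement at all
        assert not evaluate_criterion(toy_db, "T002", c, pd.Timestamp("2015-06-01"))

    def test_closest_not_after_value_used(self, toy_db):
        # T000 has M1=9.0 (99 days before) and 7.0 (30 days before): use 7.0
        c = Criterion(kind="measurement_threshold", concept_set=cs("M1"),
                      days_before=365, comparator="le", high=8.0)
        assert evaluate_criterion(toy_db, "T000", c, pd.Timestamp("2010-06-01"))

    def test_verdicts_match_bruteforce_on_random_population(self, toy_vocabulary):
        rng = np.random.default_rng(7)
        db = random_toy_db(rng, toy_vocabulary, 50)
        index = pd.Timestamp("2010-01-01")
        for _ in range(25):
            d = random_definition(rng)
            for crit in [d.indication] + d.eligibility:
                for _, person in db.persons.iloc[:10].iterrows():
                    assert evaluate_criterion(db, person["person_id"], crit, index) \
                        == oracle_criterion(db, person, crit, index)


class TestBuildCohort:
    def test_zero_criteria_equals_indication_only(self, toy_vocabulary):
        rng = np.random.default_rng(3)
        db = random_toy_db(rng, toy_vocabulary, 60)
        d = random_definition(rng).model_copy(update={"eligibility": []})
        a = build_cohort(db, d, mode="indication_only")
        b = build_cohort(db, d, mode="indication_plus_criteria")
        assert as_dict(a) == as_dict(b)

    def test_matches_bruteforce_intersection(self, toy_vocabulary):
        rng = np.random.default_rng(11)
        db = random_toy_db(rng, toy_vocabulary, 80)
        for _ in range(15):
            d = random_definition(rng)
            for mode in ("indication_only", "indication_plus_criteria"):
                assert as_dict(build_cohort(db, d, mode=mode)) \
                    == oracle_cohort(db, d, mode)

    def test_subset_property(self, toy_vocabulary):
        rng = np.random.default_rng(23)
        db = random_toy_db(rng, toy_vocabulary, 100)
        for _ in range(25):
            d = random_definition(rng)
            io = build_cohort(db, d, mode="indication_only")
            wc = build_cohort(db, d, mode="indication_plus_criteria")
            assert wc.person_ids <= io.person_ids

    def test_monotone_shrinkage_with_added_criterion(self, toy_vocabulary):
        rng = np.random.default_rng(29)
        db = random_toy_db(rng, toy_vocabulary, 100)
        for _ in range(20):
            d = random_definition(rng)
            extra = Criterion(kind="has_event", concept_set=cs("B"),
                              days_before=int(rng.integers(0, 3000)))
            bigger = d.model_copy(update={"eligibility": d.eligibility + [extra]})
            assert len(build_cohort(db, bigger)) <= len(build_cohort(db, d))

    def test_order_invariance_of_eligibility_list(self, toy_vocabulary):
        rng = np.random.default_rng(31)
        db = random_toy_db(rng, toy_vocabulary, 100)
        for _ in range(15):
            d = random_definition(rng)
            if len(d.eligibility) < 2:
                continue
            perm = list(rng.permutation(len(d.eligibility)))
            shuffled = d.model_copy(update={
                "eligibility": [d.eligibility[i] for i in perm]})
            assert as_dict(build_cohort(db, d)) == as_dict(build_cohort(db, shuffled))

    def test_attrition_log_is_monotone(self, toy_vocabulary):
        rng = np.random.default_rng(37)
        db = random_toy_db(rng, toy_vocabulary, 100)
        d = random_definition(rng)
        counts = [n for _, n in build_cohort(db, d).attrition]
        assert counts == sorted(counts, reverse=True)

    def test_unoperationalizable_criterion_skipped_with_warning(self, toy_vocabulary, caplog):
        rng = np.random.default_rng(41)
        db = random_toy_db(rng, toy_vocabulary, 40)
        d = CohortDefinition(
            name="soft_only",
            indication=Criterion(kind="has_event", concept_set=cs("ROOT")),
            eligibility=[Criterion(name="soft", kind="unoperationalizable",
                                   description="expected survival of at least 2 years")])
        import logging
        with caplog.at_level(logging.WARNING, logger="trialgap.criteria"):
            wc = build_cohort(db, d, mode="indication_plus_criteria")
        io = build_cohort(db, d, mode="indication_only")
        assert as_dict(wc) == as_dict(io)
        assert any("not operationalizable" in r.message for r in caplog.records)


class TestDefinitionSerialization:
    def test_yaml_round_trip(self, tmp_path):
        rng = np.random.default_rng(43)
        d = random_definition(rng)
        d.to_yaml(tmp_path / "d.yaml")
        assert CohortDefinition.from_yaml(tmp_path / "d.yaml") == d

    def test_packaged_definitions_parse(self):
        from trialgap.trials import TRIAL_IDS, load_trial_definition
        for tid in TRIAL_IDS:
            d = load_trial_definition(tid)
            assert d.indication.kind == "has_event"
            assert d.mode == "indication_plus_criteria"

    def test_invalid_between_bounds_rejected(self):
        with pytest.raises(ValueError, match="low <= high"):
            Criterion(kind="measurement_threshold", concept_set=cs("M1"),
                      comparator="between", low=5.0, high=1.0)
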