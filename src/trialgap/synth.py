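"""Synthetic longitudinal patient database with configurable marginal structure.

The generator emulates what a hospital data warehouse looks like to the
rest of this package: persons with demographics and one observation
window, an indication condition with a configurable prevalence, dated
condition/drug/procedure events, and repeated-measurement values with
per-characteristic recording probabilities (missingness). Characteristics
are sampled independently per person — published cohort columns report
marginals only, and inventing an unprinted joint distribution would be
worse than assuming independence. An optional Gaussian-copula hook can
correlate continuous measurements, but the packaged configurations leave
it off.

Temporal layout: every person shares one long observation window. Persons
carrying the indication get an index-defining indication event at a
uniform date inside the index window; their condition/drug/procedure
events are placed relative to that date (before, at, or after index) so
that downstream baseline windows see them, and measurement values land
shortly before index. Persons without the indication receive the same
event mix at uniform dates, so the database is not empty outside the
cohorts of interest.

``trial_emulation_config`` assembles a configuration whose marginals are
the printed Indication-Only column of one of the four packaged source
trials, combining the trial transcription with a packaged emulation map
(concept assignments, windows, and the handful of scale parameters the
published tables do not print).
"""
from __future__ import annotations

import math
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .model import (Concept, ConceptHierarchy, PatientDatabase, Vocabulary)

DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


class AgeSpec(BaseModel):
    """Age at index, in years. ``mean`` targets the integer-age mean."""

    mean: float = Field(gt=0)
    sd: float = Field(ge=0)
    minimum: int = 18
    maximum: int = 105


class CategoricalSpec(BaseModel):
    """Demographic category probabilities (concept id -> probability)."""

    probabilities: dict[str, float]

    @model_validator(mode="after")
    def _check(self):
        for cid, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {cid!r} outside [0, 1]")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"category probabilities sum to {total}, expected 1")
        return self


class EventSpec(BaseModel):
    """One condition/drug/procedure concept with a population prevalence."""

    concept_id: str
    prevalence: float = Field(ge=0.0, le=1.0)
    placement: Literal["pre_index", "post_index", "at_index"] = "pre_index"
    span_days: int = Field(default=1825, ge=1)  # offset drawn from [1, span_days]


class MeasurementSpec(BaseModel):
    """One recorded characteristic. ``distribution='lognormal'`` keeps the
    configured mean and sd exactly on positive support (right-skewed labs);
    truncation bounds apply to the normal family only and should sit far
    (|z| >= ~2.8) from the mean, or they visibly shift it."""

    concept_id: str
    mean: float
    sd: float = Field(ge=0)
    distribution: Literal["normal", "lognormal"] = "normal"
    recording_probability: float = Field(default=1.0, ge=0.0, le=1.0)
    lower: Optional[float] = None
    upper: Optional[float] = None
    span_days: int = Field(default=365, ge=1)  # recorded within this many days pre-index

    @model_validator(mode="after")
    def _check(self):
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ValueError(f"{self.concept_id}: lower must be < upper")
        if self.distribution == "lognormal" and self.mean <= 0:
            raise ValueError(f"{self.concept_id}: lognormal requires mean > 0")
        return self


class FirstEventSpec(BaseModel):
    """Backdated first occurrence of a concept (exponential years before index)."""

    concept_id: str
    mean_years: float = Field(gt=0)


class IndicationSpec(BaseModel):
    concept_id: str
    prevalence: float = Field(gt=0.0, le=1.0)


class CorrelationSpec(BaseModel):
    """Gaussian copula between two measurement concepts (optional hook)."""

    concept_a: str
    concept_b: str
    rho: float = Field(ge=-1.0, le=1.0)


class PopulationConfig(BaseModel):
    n_persons: int = Field(ge=1)
    observation_start: date = date(1995, 1, 1)
    observation_end: date = date(2019, 12, 31)
    index_start: date = date(2012, 1, 1)
    index_end: date = date(2019, 6, 30)
    age: AgeSpec
    gender: CategoricalSpec
    race: CategoricalSpec
    ethnicity_concept: str = "E_UNKNOWN"
    indication: IndicationSpec
    index_subtypes: Optional[dict[str, float]] = None  # concept -> prob, replaces indication event
    events: list[EventSpec] = Field(default_factory=list)
    measurements: list[MeasurementSpec] = Field(default_factory=list)
    first_events: list[FirstEventSpec] = Field(default_factory=list)
    correlations: list[CorrelationSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self):
        if self.observation_start > self.observation_end:
            raise ValueError("observation_start after observation_end")
        if not (self.observation_start <= self.index_start
                <= self.index_end <= self.observation_end):
            raise ValueError("index window must lie inside the observation window")
        if self.index_subtypes is not None:
            total = sum(self.index_subtypes.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"index_subtypes probabilities sum to {total}, expected 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls.model_validate(doc)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        doc = self.model_dump(mode="json", exclude_none=True)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _choice(rng: np.random.Generator, spec: CategoricalSpec, n: int) -> np.ndarray:
    cats = sorted(spec.probabilities)  # fixed order for determinism
    p = np.array([spec.probabilities[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(cats, dtype=object), size=n, p=p)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: Optional[float], upper: Optional[float],
                      n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a = -np.inf if lower is None else (lower - mean) / sd
    b = np.inf if upper is None else (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_population(config: PopulationConfig, seed: int,
                        vocabulary: Optional[Vocabulary] = None) -> PatientDatabase:
    """Draw a :class:`PatientDatabase` from the configured marginals.

    Identical ``(config, seed)`` pairs produce identical databases, down to
    the written text tables. The vocabulary defaults to the packaged one.
    """
    if vocabulary is None:
        vocabulary = load_packaged_vocabulary()
    rng = np.random.default_rng(seed)
    n = config.n_persons
    width = max(6, len(str(n)))
    person_ids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)], dtype=object)

    indicated = rng.random(n) < config.indication.prevalence
    obs_start = pd.Timestamp(config.observation_start)
    obs_end = pd.Timestamp(config.observation_end)
    idx_lo = (pd.Timestamp(config.index_start) - obs_start).days
    idx_hi = (pd.Timestamp(config.index_end) - obs_start).days
    index_offset = rng.integers(idx_lo, idx_hi + 1, size=n)
    index_date = obs_start + pd.to_timedelta(index_offset, unit="D")

    # age targets the integer age at index: floor(continuous age + 0.5 shift)
    age_cont = _truncated_normal(rng, config.age.mean + 0.5, config.age.sd,
                                 config.age.minimum, config.age.maximum + 1, n)
    age_int = np.floor(age_cont).astype(int)
    ref_year = pd.DatetimeIndex(index_date).year.to_numpy()
    birth_year = ref_year - age_int

    persons = pd.DataFrame({
        "person_id": person_ids,
        "birth_year": birth_year,
        "gender_concept": _choice(rng, config.gender, n),
        "race_concept": _choice(rng, config.race, n),
        "ethnicity_concept": config.ethnicity_concept,
        "observation_start": obs_start,
        "observation_end": obs_end,
    })

    frames: list[pd.DataFrame] = []
    obs_start_off = 0
    obs_end_off = (obs_end - obs_start).days

    def add_events(mask: np.ndarray, concept_id: str, offsets: np.ndarray,
                   values: Optional[np.ndarray] = None) -> None:
        if not mask.any():
            return
        domain = vocabulary.domain(concept_id)
        dates = obs_start + pd.to_timedelta(offsets[mask], unit="D")
        frame = pd.DataFrame({
            "person_id": person_ids[mask],
            "concept_id": concept_id,
            "domain": domain,
            "event_date": dates,
            "value": values[mask] if values is not None else np.nan,
            "unit": None,
        })
        frames.append(frame)

    # indication / index event
    if config.index_subtypes is None:
        add_events(indicated, config.indication.concept_id, index_offset)
    else:
        cats = sorted(config.index_subtypes)
        p = np.array([config.index_subtypes[c] for c in cats], dtype=float)
        p = p / p.sum()
        subtype = rng.choice(np.array(cats, dtype=object), size=n, p=p)
        for cid in cats:
            add_events(indicated & (subtype == cid), cid, index_offset)

    # backdated first occurrences (e.g. years since diagnosis)
    for spec in config.first_events:
        years_back = rng.exponential(spec.mean_years, size=n)
        offsets = np.maximum(index_offset - np.round(years_back * DAYS_PER_YEAR).astype(int),
                             obs_start_off)
        add_events(indicated, spec.concept_id, offsets)

    # prevalent events
    for spec in config.events:
        has = rng.random(n) < spec.prevalence
        if spec.placement == "at_index":
            rel = np.zeros(n, dtype=int)
        else:
            rel = rng.integers(1, spec.span_days + 1, size=n)
            if spec.placement == "pre_index":
                rel = -rel
        offsets = np.clip(index_offset + rel, obs_start_off, obs_end_off)
        # persons without an index date get a uniform event date instead
        uniform = rng.integers(obs_start_off, obs_end_off + 1, size=n)
        offsets = np.where(indicated, offsets, uniform)
        add_events(has, spec.concept_id, offsets)

    # measurements, optionally copula-correlated
    z_cache: dict[str, np.ndarray] = {}
    corr = {(c.concept_a, c.concept_b): c.rho for c in config.correlations}
    for spec in config.measurements:
        recorded = rng.random(n) < spec.recording_probability
        rho_partner = next(((a, r) for (a, b), r in corr.items()
                            if b == spec.concept_id and a in z_cache), None)
        if spec.distribution == "lognormal":
            # moment-matched: preserves the configured mean and sd exactly
            s2 = math.log(1.0 + (spec.sd / spec.mean) ** 2)
            mu = math.log(spec.mean) - s2 / 2.0
            values = rng.lognormal(mu, math.sqrt(s2), size=n)
        elif rho_partner is not None and spec.sd > 0:
            a_name, rho = rho_partner
            z = rho * z_cache[a_name] + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            values = spec.mean + spec.sd * z
            if spec.lower is not None or spec.upper is not None:
                values = np.clip(values, spec.lower, spec.upper)
        else:
            values = _truncated_normal(rng, spec.mean, spec.sd, spec.lower, spec.upper, n)
            if spec.sd > 0:
                z_cache[spec.concept_id] = (values - spec.mean) / spec.sd
        rel = -rng.integers(0, spec.span_days + 1, size=n)
        offsets = np.clip(index_offset + rel, obs_start_off, obs_end_off)
        uniform = rng.integers(obs_start_off, obs_end_off + 1, size=n)
        offsets = np.where(indicated, offsets, uniform)
        add_events(recorded, spec.concept_id, offsets, values=values)

    events = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["person_id", "concept_id", "domain",
                                         "event_date", "value", "unit"]))
    events = events.sort_values(["person_id", "event_date", "concept_id"],
                                kind="stable", ignore_index=True)
    return PatientDatabase(persons, events, vocabulary)


# ---------------------------------------------------------------------------
# packaged vocabulary and trial emulation configs
# ---------------------------------------------------------------------------

def _data_path(*parts: str) -> Path:
    return Path(resources.files("trialgap").joinpath("data", *parts))


def load_packaged_vocabulary() -> Vocabulary:
    vocab = pd.read_csv(_data_path("vocabulary", "vocabulary.csv"), dtype=str)
    hier = pd.read_csv(_data_path("vocabulary", "hierarchy.csv"), dtype=str)
    return Vocabulary.from_frames(vocab, hier)


def load_emulation_map(trial_id: str) -> dict:
    path = _data_path("trials", f"{trial_id}_map.yaml")
    if not path.exists():
        raise KeyError(f"unknown trial id {trial_id!r}")
    with open(path) as fh:
        return yaml.safe_load(fh)


def _solve_sd_from_fraction(mean: float, bound: float, frac_ge: float) -> float:
    """SD making P(X >= bound) = frac_ge under X ~ Normal(mean, sd)."""
    z = stats.norm.ppf(1.0 - frac_ge)
    if abs(z) < 1e-9:
        raise ConfigError("cannot solve sd: fraction at bound is 0.5 with mean at bound")
    return (bound - mean) / z


def _solve_age_from_flags(targets: dict[float, float]) -> tuple[float, float]:
    """(mean, sd) of continuous age matching two exceedance probabilities.

    ``targets`` maps cutoff -> P(age >= cutoff). With two cutoffs the normal
    location/scale is exactly identified.
    """
    (c1, p1), (c2, p2) = sorted(targets.items())
    z1, z2 = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
    sd = (c2 - c1) / (z2 - z1)
    mu = c1 - z1 * sd
    return mu - 0.5, sd  # undo the integer-age shift applied at generation


def trial_emulation_config(trial_id: str) -> PopulationConfig:
    """Generator configuration emulating one trial's Indication-Only column.

    Marginals (category percents, prevalences, measurement means) are read
    from the packaged trial transcription at call time; concept
    assignments, windows and unprinted scale parameters come from the
    trial's emulation map. See docs/methods.md for the field-by-field
    provenance rules.
    """
    from .rct import load_packaged_trial

    emap = load_emulation_map(trial_id)
    trial = load_packaged_trial(trial_id)
    io = trial.reported("indication_only")

    def io_value(row: str) -> float:
        v = io.values.get(row)
        if v is None:
            raise ConfigError(f"{trial_id}: no printed indication-only value for {row!r}")
        return v

    pop = emap["population"]
    age_spec = None
    gender = race = None
    events: list[EventSpec] = []
    measurements: list[MeasurementSpec] = []
    first_events: list[FirstEventSpec] = []
    index_subtypes = None

    for entry in emap["characteristics"]:
        kind = entry["kind"]
        synth = entry.get("synth") or {}
        if synth.get("skip"):
            continue
        if kind == "demographic_category":
            probs = {}
            remainder_cid = None
            for cid, row in entry["categories"].items():
                probs[cid] = io_value(row) / 100.0
                if entry.get("remainder") == row:
                    remainder_cid = cid
            total = sum(probs.values())
            if remainder_cid is not None and total < 1.0:
                probs[remainder_cid] += 1.0 - total
            else:
                probs = {c: p / total for c, p in probs.items()}
            spec = CategoricalSpec(probabilities=probs)
            if entry["field"] == "gender":
                gender = spec
            else:
                race = spec
        elif kind == "age":
            age_spec = AgeSpec(mean=io_value(entry["row"]), sd=synth["sd"])
        elif kind == "age_flags":
            targets = {float(bound): io_value(row) / 100.0
                       for row, bound in entry["rows"].items()}
            mean, sd = _solve_age_from_flags(targets)
            age_spec = AgeSpec(mean=mean, sd=sd)
        elif kind == "event_flag":
            events.append(EventSpec(
                concept_id=synth.get("emit_concept", entry["concept_id"]),
                prevalence=io_value(entry["row"]) / 100.0,
                placement=synth.get("placement", "pre_index"),
                span_days=synth.get("span_days", 1825),
            ))
        elif kind == "measurement":
            row = entry["row"]
            if row in io.ned:
                measurements.append(MeasurementSpec(
                    concept_id=entry["concept_id"], mean=0.0, sd=0.0,
                    recording_probability=0.0))
                continue
            mean = io_value(row)
            cat = entry.get("category")
            if "sd_from_fraction" in synth:
                sf = synth["sd_from_fraction"]
                n_unknown = io_value(sf["unknown_row"]) / 100.0
                frac_ge = (io_value(sf["ge_row"]) / 100.0) / (1.0 - n_unknown)
                sd = _solve_sd_from_fraction(mean, sf["bound"], frac_ge)
                recording = 1.0 - n_unknown
            else:
                sd = synth["sd"]
                if cat and cat.get("unknown_name"):
                    recording = 1.0 - io_value(cat["unknown_name"]) / 100.0
                else:
                    recording = synth.get("recording_probability", 0.97)
            measurements.append(MeasurementSpec(
                concept_id=entry["concept_id"], mean=mean, sd=sd,
                distribution=synth.get("distribution", "normal"),
                recording_probability=recording,
                lower=synth.get("lower"), upper=synth.get("upper"),
                span_days=synth.get("span_days", 365),
            ))
        elif kind == "time_since_first_event":
            first_events.append(FirstEventSpec(
                concept_id=synth.get("emit_concept", entry["concept_id"]),
                mean_years=io_value(entry["row"])))
        elif kind == "index_subtypes":
            probs = {cid: io_value(row) for row, cid in entry["rows"].items()}
            total = sum(probs.values())
            index_subtypes = {c: p / total for c, p in probs.items()}
        elif kind == "event_count_category":
            continue  # counts emerge from the per-class event specs
        else:
            raise ConfigError(f"{trial_id}: unknown map kind {kind!r}")

    for extra in pop.get("extra_events", []):
        events.append(EventSpec.model_validate(extra))

    if age_spec is None or gender is None or race is None:
        raise ConfigError(f"{trial_id}: emulation map must define age, gender and race")
    return PopulationConfig(
        n_persons=pop["n_persons"],
        age=age_spec, gender=gender, race=race,
        indication=IndicationSpec.model_validate(pop["indication"]),
        index_subtypes=index_subtypes,
        events=events, measurements=measurements, first_events=first_events,
    )
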