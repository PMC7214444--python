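"""End-to-end run for one trial: generate, build both cohorts, summarise, compare.

The output bundle holds everything the analysis produces: the two cohorts
(indication-only and indication-plus-criteria), their baseline summaries,
one comparison table per cohort against the pooled trial values, and the
paired-discrepancy points that show whether adding the eligibility
criteria moved each characteristic toward or away from the trial.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

from .baseline import CohortSummary, summarize
from .concordance import (ComparisonRow, PairedDelta, compare, comparison_frame,
                          comparison_markdown, figure1_pairs, pairs_frame)
from .criteria import Cohort, build_cohort
from .model import PatientDatabase
from .rct import TrialSummary, load_packaged_trial
from .synth import generate_population, trial_emulation_config
from .trials import (figure_excluded_rows, load_trial_definition,
                     trial_characteristic_specs)


@dataclasses.dataclass
class TrialRun:
    trial: TrialSummary
    db: PatientDatabase
    cohort_indication: Cohort
    cohort_criteria: Cohort
    summary_indication: CohortSummary
    summary_criteria: CohortSummary
    rows_indication: list[ComparisonRow]
    rows_criteria: list[ComparisonRow]
    pairs: list[PairedDelta]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort_indication.to_csv(out / "cohort_indication_only.csv")
        self.cohort_criteria.to_csv(out / "cohort_with_criteria.csv")
        self.summary_indication.to_csv(out / "summary_indication_only.csv")
        self.summary_criteria.to_csv(out / "summary_with_criteria.csv")
        comparison_frame(self.rows_indication).to_csv(
            out / "comparison_indication_only.csv", index=False)
        comparison_frame(self.rows_criteria).to_csv(
            out / "comparison_with_criteria.csv", index=False)
        (out / "comparison_with_criteria.md").write_text(
            comparison_markdown(self.rows_criteria))
        pairs_frame(self.pairs).to_csv(out / "paired_deltas.csv", index=False)


def run_trial(trial_id: str, seed: int, n_persons: Optional[int] = None,
              db: Optional[PatientDatabase] = None,
              with_significance: bool = True) -> TrialRun:
    """Full pipeline for one packaged trial.

    ``n_persons`` overrides the emulation config's population size (the
    sampling structure is unchanged); pass a prebuilt ``db`` to skip
    generation entirely.
    """
    trial = load_packaged_trial(trial_id)
    if db is None:
        config = trial_emulation_config(trial_id)
        if n_persons is not None:
            config = config.model_copy(update={"n_persons": n_persons})
        db = generate_population(config, seed)
    definition = load_trial_definition(trial_id)
    specs = trial_characteristic_specs(trial_id)
    excluded = figure_excluded_rows(trial_id)

    cohort_io = build_cohort(db, definition, mode="indication_only")
    cohort_wc = build_cohort(db, definition, mode="indication_plus_criteria")
    summary_io = summarize(cohort_io, db, specs)
    summary_wc = summarize(cohort_wc, db, specs)
    rows_io = compare(trial, summary_io, with_significance=with_significance)
    rows_wc = compare(trial, summary_wc, with_significance=with_significance)
    pairs = figure1_pairs(rows_io, rows_wc, exclude=sorted(excluded))
    return TrialRun(trial, db, cohort_io, cohort_wc, summary_io, summary_wc,
                    rows_io, rows_wc, pairs)
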