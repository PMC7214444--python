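"""The cohort-vs-trial discrepancy statistic and the comparison table.

For each baseline characteristic the discrepancy from the pooled trial
value is:

* discrete rows — the difference in percentage points, expressed as a
  signed proportion: ``(cohort% − pooled%)/100``;
* continuous rows — a standardized difference of means. The default
  denominator is the symmetric two-sample form
  ``sqrt((σ_RCT² + σ_cohort²)/2)``; the trial-only (``σ_RCT``) and
  cohort-only denominators are selectable. The symmetric form is the
  package default because the published discrepancies for continuous rows
  are not consistent with dividing by the trial σ alone, and back-solving
  the implied cohort SD under the symmetric form yields plausible values
  (see docs/methods.md).

Zero means the observational cohort does not differ from the trial on that
characteristic; sign follows cohort-minus-trial. Significance flags are a
reconstruction (the source tables print p-values without naming a test)
and every output labels them as such.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .baseline import CohortSummary
from .rct import TrialSummary, pooled_value

log = logging.getLogger("trialgap.concordance")

Denominator = Literal["pooled", "rct", "cohort"]


class AlignmentError(ValueError):
    """Trial and cohort characteristic names do not line up."""


def delta_discrete(cohort_percent: float, rct_pooled_percent: float) -> float:
    """Percentage-point difference as a signed proportion (cohort − trial)."""
    return (cohort_percent - rct_pooled_percent) / 100.0


def delta_continuous(cohort_mean: float, cohort_sd: Optional[float],
                     rct_pooled_mean: float, sigma_rct: Optional[float],
                     denominator: Denominator = "pooled") -> float:
    """Standardized difference of means (cohort − trial)."""
    if denominator == "rct":
        denom = sigma_rct
    elif denominator == "cohort":
        denom = cohort_sd
    else:
        if sigma_rct is None and cohort_sd is None:
            denom = None
        elif sigma_rct is None:
            denom = cohort_sd  # only one scale available
        elif cohort_sd is None:
            denom = sigma_rct
        else:
            denom = math.sqrt((sigma_rct ** 2 + cohort_sd ** 2) / 2.0)
    if denom is None or denom <= 0:
        raise ValueError("standardized difference undefined: no positive denominator")
    return (cohort_mean - rct_pooled_mean) / denom


def implied_cohort_sd(delta: float, cohort_mean: float, rct_pooled_mean: float,
                      sigma_rct: float) -> Optional[float]:
    """Cohort SD that would make the symmetric-denominator delta equal ``delta``.

    Back-solve oracle: with d = (m_c − m_r)/sqrt((σ_r² + s²)/2), the implied
    s² = 2((m_c − m_r)/d)² − σ_r². Returns None when no real solution exists.
    """
    if delta == 0:
        return None
    s2 = 2.0 * ((cohort_mean - rct_pooled_mean) / delta) ** 2 - sigma_rct ** 2
    return math.sqrt(s2) if s2 >= 0 else None


@dataclasses.dataclass
class ComparisonRow:
    characteristic: str
    data_type: Literal["discrete", "continuous"]
    rct_pooled: float
    cohort_value: Optional[float]
    delta_rct: Optional[float]
    sigma_rct: Optional[float] = None
    cohort_sd: Optional[float] = None
    ned: bool = False
    median_based: bool = False
    p_value: Optional[float] = None
    method: Optional[str] = None


def significance(row: ComparisonRow, cohort_n: int) -> Optional[float]:
    """Reconstructed two-sided z-test of the cohort value against the pooled trial value.

    Continuous rows use a one-sample z with scale ``sigma_rct/sqrt(n)``;
    discrete rows a one-proportion z against the pooled proportion. The
    source analysis did not name its test, so results are labelled
    reconstructions. Degenerate inputs return None.
    """
    if row.ned or row.cohort_value is None or cohort_n < 2:
        row.p_value, row.method = None, "undefined"
        return None
    if row.data_type == "discrete":
        p0 = row.rct_pooled / 100.0
        if not 0.0 < p0 < 1.0:
            row.p_value, row.method = None, "undefined"
            return None
        se = math.sqrt(p0 * (1 - p0) / cohort_n)
        z = (row.cohort_value / 100.0 - p0) / se
        row.method = "reconstructed_one_proportion_z"
    else:
        scale = row.sigma_rct if row.sigma_rct else row.cohort_sd
        if not scale:
            row.p_value, row.method = None, "undefined"
            return None
        z = (row.cohort_value - row.rct_pooled) / (scale / math.sqrt(cohort_n))
        row.method = "reconstructed_one_sample_z"
    row.p_value = float(2.0 * stats.norm.sf(abs(z)))
    return row.p_value


def compare(trial: TrialSummary,
            cohort: "CohortSummary | Mapping[str, Optional[float]]",
            cohort_sds: Optional[Mapping[str, float]] = None,
            cohort_n: Optional[int] = None,
            denominator: Denominator = "pooled",
            ned: Sequence[str] = (),
            with_significance: bool = False,
            strict: bool = True) -> list[ComparisonRow]:
    """One comparison row per trial characteristic, in trial-table order.

    ``cohort`` may be a :class:`CohortSummary` or a plain name->value
    mapping (e.g. a transcribed published cohort column). NED entries get a
    row with no delta. With ``strict`` a trial characteristic missing from
    the cohort raises :class:`AlignmentError` listing the offenders.
    """
    if isinstance(cohort, CohortSummary):
        values = {r.name: r.value for r in cohort.rows}
        ned = tuple(r.name for r in cohort.rows if r.ned)
        cohort_sds = cohort.sds() if cohort_sds is None else cohort_sds
        cohort_n = cohort.n if cohort_n is None else cohort_n
    else:
        values = dict(cohort)
    cohort_sds = cohort_sds or {}
    missing = [name for name, _ in trial.characteristics
               if name not in values and name not in ned]
    if missing and strict:
        raise AlignmentError(f"cohort summary lacks characteristics: {missing}")
    rows: list[ComparisonRow] = []
    for name, kind in trial.characteristics:
        if name in missing:
            continue
        pooled = pooled_value(trial, name).value
        cval = values.get(name)
        is_ned = name in ned
        row = ComparisonRow(
            characteristic=name,
            data_type="discrete" if kind == "discrete" else "continuous",
            rct_pooled=pooled,
            cohort_value=cval,
            delta_rct=None,
            sigma_rct=trial.sigma.get(name),
            cohort_sd=cohort_sds.get(name),
            ned=is_ned,
            median_based=kind == "median",
        )
        if not is_ned and cval is not None:
            if kind == "discrete":
                row.delta_rct = delta_discrete(cval, pooled)
            else:
                try:
                    row.delta_rct = delta_continuous(
                        cval, row.cohort_sd, pooled, row.sigma_rct, denominator)
                except ValueError:
                    row.delta_rct = None
        if with_significance and cohort_n:
            significance(row, cohort_n)
        rows.append(row)
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    df["delta_display"] = df["delta_rct"].map(
        lambda d: None if d is None or pd.isna(d) else round(d, 3))
    return df


def comparison_markdown(rows: list[ComparisonRow]) -> str:
    lines = ["| characteristic | type | RCT pooled | cohort | delta | p (reconstructed) |",
             "|---|---|---|---|---|---|"]
    for r in rows:
        fmt = lambda v, d=2: "NED" if v is None else f"{v:.{d}f}"
        delta = "" if r.delta_rct is None else f"{r.delta_rct:.3f}"
        p = "" if r.p_value is None else f"{r.p_value:.3g}"
        lines.append(f"| {r.characteristic} | {r.data_type} | {r.rct_pooled:.2f} "
                     f"| {fmt(r.cohort_value)} | {delta} | {p} |")
    return "\n".join(lines) + "\n"


@dataclasses.dataclass(frozen=True)
class PairedDelta:
    characteristic: str
    delta_indication_only: float
    delta_with_criteria: float
    marker: Literal["circle_continuous", "plus_discrete"]


def figure1_pairs(rows_indication: list[ComparisonRow],
                  rows_with_criteria: list[ComparisonRow],
                  exclude: Sequence[str] = ()) -> list[PairedDelta]:
    """Paired discrepancy points (indication-only vs. with-criteria).

    Inner join on characteristic; rows lacking a delta on either side, and
    explicitly excluded names (e.g. implausible extreme-value rows), are
    omitted with a log line.
    """
    wc = {r.characteristic: r for r in rows_with_criteria}
    out: list[PairedDelta] = []
    for r in rows_indication:
        other = wc.get(r.characteristic)
        if r.characteristic in exclude:
            log.info("figure pairs: %r excluded by request", r.characteristic)
            continue
        if other is None or r.delta_rct is None or other.delta_rct is None:
            log.info("figure pairs: %r lacks a delta on one side; omitted", r.characteristic)
            continue
        out.append(PairedDelta(
            r.characteristic, r.delta_rct, other.delta_rct,
            "plus_discrete" if r.data_type == "discrete" else "circle_continuous"))
    return out


def pairs_frame(pairs: list[PairedDelta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in pairs])
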