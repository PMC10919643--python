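"""Diagnostic-performance evaluation of DIC calls against hospital mortality.

The condition-positive state is in-hospital death; the test-positive state
is the DIC call of a given criterion.  From the resulting 2x2 table the five
standard metrics are derived:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    accuracy    = (TP + TN) / N

Percentages are displayed truncated toward zero at one decimal (e.g.
147/154 -> 95.4); full-precision fractions are retained on every metric.
Zero-denominator metrics are flagged undefined, never coerced to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from scipy import stats
from scipy.stats.contingency import expected_freq

from .errors import EmptyCohortError, MissingVariableError, ValidationError
from .policy import ScorePolicy
from .scoring import compute_sirs, score_all
from .types import (
    CRITERION_ORDER,
    Criterion,
    CriterionScore,
    Outcome,
    PatientRecord,
)

__all__ = [
    "ContingencyTable",
    "Metric",
    "DiagnosticPerformance",
    "GroupComparisonRow",
    "ReportBundle",
    "build_mortality_contingency",
    "diagnostic_performance",
    "dic_prevalence",
    "mortality_among_positive",
    "compare_groups",
    "criteria_report",
    "truncate_percent",
    "round_percent",
]


def truncate_percent(fraction: float, decimals: int = 1) -> float:
    """Display form of a proportion: percent truncated toward zero.

    ``round`` at 9 decimals first guards against float fuzz such as
    0.7 * 100 = 70.00000000000001.
    """
    q = 10**decimals
    return math.trunc(round(fraction * 100 * q, 6)) / q


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Percent rounded half-to-even at ``decimals`` places."""
    return round(fraction * 100, decimals)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification of DIC call vs in-hospital outcome.

    tp: DIC-positive and expired;   fp: DIC-positive and survived;
    fn: DIC-negative and expired;   tn: DIC-negative and survived.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    criterion: Optional[Criterion] = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n_expired(self) -> int:
        return self.tp + self.fn

    @property
    def n_survived(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Metric:
    """One diagnostic metric with its defining fraction retained."""

    name: str
    numerator: int
    denominator: int

    @property
    def undefined(self) -> bool:
        return self.denominator == 0

    @property
    def value(self) -> Optional[float]:
        if self.undefined:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> Optional[float]:
        """Truncated one-decimal percent display, or None if undefined."""
        if self.undefined:
            return None
        return truncate_percent(self.value)

    def display(self) -> str:
        return "undefined" if self.undefined else f"{self.percent:.1f}"


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    accuracy: Metric

    def as_dict(self) -> dict[str, Metric]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


ScoreLike = Union[CriterionScore, bool]


def _is_positive(score: ScoreLike) -> bool:
    return score.dic_positive if isinstance(score, CriterionScore) else bool(score)


def build_mortality_contingency(
    scores: Mapping[str, ScoreLike],
    outcomes: Mapping[str, Outcome],
    criterion: Optional[Criterion] = None,
) -> ContingencyTable:
    """Cross-classify per-patient DIC calls against in-hospital outcome.

    ``scores`` maps patient id to a :class:`CriterionScore` (or a bare DIC
    call for count-reconstruction work).  Patients with unknown outcome are
    dropped; their count is recorded on the returned table via logging.
    """
    if not scores:
        raise EmptyCohortError("no scored patients")
    tp = fp = fn = tn = 0
    n_unknown = 0
    for pid, score in scores.items():
        if pid not in outcomes:
            raise ValidationError(f"no outcome for patient {pid}")
        outcome = outcomes[pid]
        if outcome is Outcome.UNKNOWN:
            n_unknown += 1
            continue
        positive = _is_positive(score)
        expired = outcome is Outcome.EXPIRED
        if positive and expired:
            tp += 1
        elif positive:
            fp += 1
        elif expired:
            fn += 1
        else:
            tn += 1
    if n_unknown:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d patients with unknown outcome", n_unknown
        )
    if tp + fp + fn + tn == 0:
        raise EmptyCohortError("no patients with known outcome")
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn, criterion=criterion)


def diagnostic_performance(table: ContingencyTable) -> DiagnosticPerformance:
    """The five standard metrics from a 2x2 table, fractions retained."""
    return DiagnosticPerformance(
        sensitivity=Metric("sensitivity", table.tp, table.tp + table.fn),
        specificity=Metric("specificity", table.tn, table.tn + table.fp),
        ppv=Metric("ppv", table.tp, table.tp + table.fp),
        npv=Metric("npv", table.tn, table.tn + table.fn),
        accuracy=Metric("accuracy", table.tp + table.tn, table.total),
    )


def dic_prevalence(scores: Mapping[str, ScoreLike]) -> Metric:
    """Fraction of scored patients called DIC-positive."""
    if not scores:
        raise EmptyCohortError("no scored patients")
    positive = sum(1 for s in scores.values() if _is_positive(s))
    return Metric("prevalence", positive, len(scores))


def mortality_among_positive(table: ContingencyTable) -> Metric:
    """Expired fraction among DIC-positive patients; identical to PPV."""
    return Metric("mortality_among_positive", table.tp, table.tp + table.fp)


# --- survivor vs non-survivor group comparison (baseline table) -----------

_PANEL_FIELDS = {
    "platelet_count", "platelet_prior_24h", "pt_seconds", "aptt_seconds",
    "d_dimer", "fdp", "fibrinogen",
}
_VITAL_FIELDS = {
    "temperature", "heart_rate", "respiratory_rate", "wbc", "map_mmhg", "lactate",
}
_CONTEXT_FIELDS = {
    "underlying_disease", "bleeding", "organ_failure", "septic_shock",
    "dialysis", "ventilated", "sofa_score", "assessment_day",
}


def _resolve_variable(record: PatientRecord, variable: str):
    if variable in _PANEL_FIELDS:
        return getattr(record.panel, variable)
    if variable in _VITAL_FIELDS:
        return getattr(record.vitals, variable)
    if variable in _CONTEXT_FIELDS:
        return getattr(record.context, variable)
    if variable == "sirs_score":
        if record.context.sirs_precomputed is not None:
            return record.context.sirs_precomputed
        try:
            return compute_sirs(record.vitals)
        except Exception:
            return None
    raise MissingVariableError(f"unknown variable {variable!r}")


@dataclass(frozen=True)
class GroupComparisonRow:
    """One row of the survivor vs non-survivor baseline comparison."""

    variable: str
    survivor_summary: str
    nonsurvivor_summary: str
    test_name: str
    p_value: float
    n_survivor: int
    n_nonsurvivor: int


def _summaries(values: np.ndarray, kind: str, n_group: int) -> str:
    if kind == "dichotomous":
        k = int(values.sum())
        pct = round_percent(k / len(values)) if len(values) else float("nan")
        return f"{k} ({pct:.1f}%)"
    if kind == "continuous_normal":
        return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def compare_groups(
    cohort: Iterable[PatientRecord], variable: str, kind: str
) -> GroupComparisonRow:
    """Compare one variable between survivors and non-survivors.

    ``kind`` selects the test and summary form:

    * ``dichotomous`` — chi-square without continuity correction, switching
      to Fisher's exact test when any expected cell count is < 5; count (%).
    * ``continuous_normal`` — two-sample Student t-test; mean +/- sd.
    * ``continuous_skewed`` — two-sided Mann-Whitney U; median (IQR).

    All p-values are two-sided.  Summaries use non-missing values only.
    """
    if kind not in {"dichotomous", "continuous_normal", "continuous_skewed"}:
        raise ValidationError(f"unknown variable kind {kind!r}")
    surv_values, nons_values = [], []
    for record in cohort:
        if record.outcome is Outcome.UNKNOWN:
            continue
        value = _resolve_variable(record, variable)
        if value is None:
            continue
        (nons_values if record.outcome is Outcome.EXPIRED else surv_values).append(
            float(value)
        )
    if not surv_values and not nons_values:
        raise MissingVariableError(f"variable {variable!r} absent on all records")
    if not surv_values or not nons_values:
        raise EmptyCohortError("both outcome groups must be non-empty")
    surv = np.asarray(surv_values)
    nons = np.asarray(nons_values)

    if kind == "dichotomous":
        table = np.array(
            [
                [surv.sum(), len(surv) - surv.sum()],
                [nons.sum(), len(nons) - nons.sum()],
            ]
        )
        if (expected_freq(table) < 5).any():
            _, p = stats.fisher_exact(table, alternative="two-sided")
            test_name = "Fisher exact"
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
            test_name = "chi-square"
    elif kind == "continuous_normal":
        _, p = stats.ttest_ind(surv, nons, equal_var=True)
        test_name = "t-test"
    else:
        _, p = stats.mannwhitneyu(surv, nons, alternative="two-sided")
        test_name = "Mann-Whitney U"

    return GroupComparisonRow(
        variable=variable,
        survivor_summary=_summaries(surv, kind, len(surv)),
        nonsurvivor_summary=_summaries(nons, kind, len(nons)),
        test_name=test_name,
        p_value=float(p),
        n_survivor=len(surv),
        n_nonsurvivor=len(nons),
    )


# --- per-criterion report bundle ------------------------------------------

@dataclass(frozen=True)
class CriterionReportRow:
    criterion: Criterion
    prevalence: Metric
    table: ContingencyTable
    performance: DiagnosticPerformance


@dataclass
class ReportBundle:
    """Per-criterion prevalence, outcome split and diagnostic metrics.

    Rows are ordered KSTH, ISTH, JAAM, R-JAAM, JMHW.  The policy snapshot is
    embedded for provenance; the footer records the percent-display
    convention (truncation at one decimal).
    """

    rows: list[CriterionReportRow]
    policy: ScorePolicy
    cohort_size: int
    n_expired: int
    n_survived: int
    footer: str = (
        "Percentages truncated toward zero at one decimal; "
        "full-precision fractions retained internally."
    )

    def to_frame(self):
        """Metrics grid as a pandas DataFrame with a stable column order."""
        import pandas as pd

        records = []
        for row in self.rows:
            t = row.table
            records.append(
                {
                    "criterion": row.criterion.display_name,
                    "n_positive": t.n_positive,
                    "discharged_n": t.fp,
                    "discharged_pct": round_percent(t.fp / t.n_positive)
                    if t.n_positive
                    else None,
                    "expired_n": t.tp,
                    "expired_pct": round_percent(t.tp / t.n_positive)
                    if t.n_positive
                    else None,
                    "prevalence_pct": round_percent(row.prevalence.value),
                    "sensitivity_pct": row.performance.sensitivity.percent,
                    "specificity_pct": row.performance.specificity.percent,
                    "ppv_pct": row.performance.ppv.percent,
                    "npv_pct": row.performance.npv.percent,
                    "accuracy_pct": row.performance.accuracy.percent,
                }
            )
        return pd.DataFrame.from_records(
            records,
            columns=[
                "criterion", "n_positive", "discharged_n", "discharged_pct",
                "expired_n", "expired_pct", "prevalence_pct", "sensitivity_pct",
                "specificity_pct", "ppv_pct", "npv_pct", "accuracy_pct",
            ],
        )

    def to_text(self) -> str:
        lines = [
            "DIC criteria diagnostic-performance report",
            f"cohort: {self.cohort_size} patients with known outcome "
            f"({self.n_expired} expired, {self.n_survived} survived)",
            "",
        ]
        header = (
            f"{'criterion':<10}{'N+':>6}{'disch N(%)':>14}{'exp N(%)':>14}"
            f"{'sens':>8}{'spec':>8}{'ppv':>8}{'npv':>8}{'acc':>8}"
        )
        lines.append(header)
        for row in self.rows:
            t = row.table
            disch = (
                f"{t.fp} ({round_percent(t.fp / t.n_positive):.1f})"
                if t.n_positive
                else "-"
            )
            exp = (
                f"{t.tp} ({round_percent(t.tp / t.n_positive):.1f})"
                if t.n_positive
                else "-"
            )
            perf = row.performance
            lines.append(
                f"{row.criterion.display_name:<10}{t.n_positive:>6}{disch:>14}"
                f"{exp:>14}{perf.sensitivity.display():>8}"
                f"{perf.specificity.display():>8}{perf.ppv.display():>8}"
                f"{perf.npv.display():>8}{perf.accuracy.display():>8}"
            )
        lines += ["", self.footer, "", "policy:"]
        for line in self.policy.to_yaml().rstrip().splitlines():
            lines.append("  " + line)
        return "\n".join(lines) + "\n"


def criteria_report(
    cohort: Iterable[PatientRecord],
    policy: Optional[ScorePolicy] = None,
    calls: Optional[Mapping[Criterion, Mapping[str, ScoreLike]]] = None,
) -> ReportBundle:
    """Score a cohort and assemble the per-criterion evaluation report.

    When ``calls`` is given it supplies per-criterion DIC calls directly
    (count-reconstruction mode, e.g. rebuilding a published table from its
    printed counts); otherwise every record is scored under ``policy``.
    Records with unknown outcome are excluded from the tables.
    """
    policy = policy or ScorePolicy()
    records = list(cohort)
    if not records:
        raise EmptyCohortError("empty cohort")
    outcomes = {r.patient_id: r.outcome for r in records}
    if len(outcomes) != len(records):
        raise ValidationError("duplicate patient ids in cohort")

    if calls is None:
        per_crit: dict[Criterion, dict[str, ScoreLike]] = {
            c: {} for c in CRITERION_ORDER
        }
        for record in records:
            scores = score_all(record, policy)
            for crit, score in scores.items():
                per_crit[crit][record.patient_id] = score
    else:
        per_crit = {c: dict(calls[c]) for c in CRITERION_ORDER}

    rows = []
    for crit in CRITERION_ORDER:
        scores = per_crit[crit]
        table = build_mortality_contingency(scores, outcomes, crit)
        rows.append(
            CriterionReportRow(
                criterion=crit,
                prevalence=dic_prevalence(scores),
                table=table,
                performance=diagnostic_performance(table),
            )
        )
    known = [r for r in records if r.outcome is not Outcome.UNKNOWN]
    return ReportBundle(
        rows=rows,
        policy=policy,
        cohort_size=len(known),
        n_expired=sum(1 for r in known if r.outcome is Outcome.EXPIRED),
        n_survived=sum(1 for r in known if r.outcome is Outcome.SURVIVED),
    )
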