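"""The five DIC scoring rubrics plus the SIRS sub-score.

Each ``score_*`` function maps a single-day coagulation panel (and, where the
rubric requires them, the SIRS score or clinical flags) to a
:class:`~dicscore.types.CriterionScore` with per-component points, the total,
and the DIC call at the policy threshold.

Rubric summary (points per band; positivity at the policy threshold):

* KSTH (>=3 of 5 one-point items): platelets <=100; PT prolongation >=3 s;
  aPTT prolongation >=5 s; D-dimer >=1.0 ug/mL; fibrinogen <=1.5 g/L.
* ISTH overt DIC (>=5): platelets <=100 (1) / <=50 (2); PT prolongation
  3-6 s (1) / >=6 s (2); D-dimer 1.0-5.0 (2) / >=5.0 (3); fibrinogen
  <=1.0 g/L (1).
* JAAM acute-phase DIC (>=5): platelets 80-120 or >30% 24-h drop (1),
  <80 or >50% drop (3); PT ratio >=1.2 (1); FDP 10-25 (1) / >=25 (3);
  fibrinogen <=3.5 g/L (1); SIRS >=3 (1).
* R-JAAM (>=5): JAAM with the fibrinogen item removed.
* JMHW (>=7): platelets 80-120/50-80/<=50 (1/2/3); PT ratio 1.25-1.67 (1) /
  >=1.67 (2); FDP 10-20/20-40/>=40 (1/2/3); fibrinogen 1.0-1.5 (1) /
  <=1.0 (2); one point each for underlying disease, bleeding, organ failure.

KSTH and ISTH band D-dimer; JAAM, R-JAAM and JMHW band FDP.  The exact
open/closed endpoint conventions are listed in
:data:`dicscore.policy.BOUNDARY_CONVENTIONS`.
"""

from __future__ import annotations

from typing import Optional

from .errors import ConfigurationError, MissingDataError
from .policy import MissingMarkerPolicy, ScorePolicy
from .types import (
    ClinicalContext,
    CoagulationPanel,
    Criterion,
    CriterionScore,
    PatientRecord,
    VitalSet,
)

__all__ = [
    "pt_prolongation",
    "pt_ratio",
    "aptt_prolongation",
    "compute_sirs",
    "score_ksth",
    "score_isth",
    "score_jaam",
    "score_rjaam",
    "score_jmhw",
    "score_all",
]


def pt_prolongation(pt_seconds: float, reference: float) -> float:
    """Prothrombin-time prolongation in seconds (patient minus reference).

    May be negative for a PT shorter than the reference.
    """
    if pt_seconds is None:
        raise MissingDataError("pt_seconds is missing")
    if reference is None:
        raise MissingDataError("PT reference is missing")
    if reference <= 0:
        raise ConfigurationError(f"PT reference must be > 0, got {reference}")
    return pt_seconds - reference


def pt_ratio(pt_seconds: float, reference: float) -> float:
    """Prothrombin-time ratio (patient / reference)."""
    if pt_seconds is None:
        raise MissingDataError("pt_seconds is missing")
    if reference is None or reference <= 0:
        raise ConfigurationError(f"PT reference must be > 0, got {reference}")
    return pt_seconds / reference


def aptt_prolongation(aptt_seconds: float, reference: float) -> float:
    """aPTT prolongation in seconds (patient minus reference)."""
    if aptt_seconds is None:
        raise MissingDataError("aptt_seconds is missing")
    if reference is None:
        raise MissingDataError("aPTT reference is missing")
    if reference <= 0:
        raise ConfigurationError(f"aPTT reference must be > 0, got {reference}")
    return aptt_seconds - reference


def compute_sirs(vitals: VitalSet, warnings: Optional[list[str]] = None) -> int:
    """SIRS score, 0-4: one point per criterion met.

    Standard consensus thresholds: temperature > 38 or < 36 degC; heart rate
    > 90/min; respiratory rate > 20/min; WBC > 12 or < 4 x10^9/L (strict
    inequalities; values exactly at a threshold score 0).  Missing components
    contribute 0 with a warning; if all four are missing the score is
    undefined and a :class:`MissingDataError` is raised.
    """
    if warnings is None:
        warnings = []
    parts = {
        "temperature": vitals.temperature,
        "heart_rate": vitals.heart_rate,
        "respiratory_rate": vitals.respiratory_rate,
        "wbc": vitals.wbc,
    }
    if all(v is None for v in parts.values()):
        raise MissingDataError("SIRS: all four components missing")
    for name, value in parts.items():
        if value is None:
            warnings.append(f"SIRS: {name} missing, contributes 0")
    score = 0
    t, hr, rr, wbc = (
        vitals.temperature,
        vitals.heart_rate,
        vitals.respiratory_rate,
        vitals.wbc,
    )
    if t is not None and (t > 38.0 or t < 36.0):
        score += 1
    if hr is not None and hr > 90.0:
        score += 1
    if rr is not None and rr > 20.0:
        score += 1
    if wbc is not None and (wbc > 12.0 or wbc < 4.0):
        score += 1
    return score


def _require(
    value: Optional[float],
    marker: str,
    criterion: Criterion,
    policy: ScorePolicy,
    warnings: list[str],
) -> Optional[float]:
    """Resolve a marker under the missing-marker policy.

    Returns None (component scores 0, warning attached) in lenient mode;
    raises in strict mode.
    """
    if value is not None:
        return value
    if policy.missing_marker_policy is MissingMarkerPolicy.STRICT:
        raise MissingDataError(
            f"{criterion.display_name}: required marker '{marker}' is missing"
        )
    warnings.append(
        f"{criterion.display_name}: marker '{marker}' missing, component scored 0"
    )
    return None


def _fibrin_marker(
    panel: CoagulationPanel,
    primary: str,
    criterion: Criterion,
    policy: ScorePolicy,
    warnings: list[str],
) -> Optional[float]:
    """Fetch the criterion's fibrin-related marker, with optional fallback.

    ``primary`` is ``"d_dimer"`` (KSTH/ISTH) or ``"fdp"`` (JAAM family).
    """
    value = getattr(panel, primary)
    if value is None and policy.fibrin_marker_fallback:
        other = "fdp" if primary == "d_dimer" else "d_dimer"
        alt = getattr(panel, other)
        if alt is not None:
            warnings.append(
                f"{criterion.display_name}: '{primary}' missing, "
                f"fell back to '{other}' against the same bands"
            )
            return alt
    return _require(value, primary, criterion, policy, warnings)


def _pt_ref(panel: CoagulationPanel, policy: ScorePolicy) -> float:
    return (
        panel.pt_reference_seconds
        if panel.pt_reference_seconds is not None
        else policy.pt_reference_seconds
    )


def _aptt_ref(panel: CoagulationPanel, policy: ScorePolicy) -> float:
    return (
        panel.aptt_reference_seconds
        if panel.aptt_reference_seconds is not None
        else policy.aptt_reference_seconds
    )


def _make_score(
    criterion: Criterion,
    components: dict[str, int],
    policy: ScorePolicy,
    warnings: list[str],
) -> CriterionScore:
    total = sum(components.values())
    threshold = policy.threshold(criterion)
    return CriterionScore(
        criterion=criterion,
        components=components,
        total=total,
        threshold=threshold,
        dic_positive=total >= threshold,
        warnings=warnings,
    )


def score_ksth(panel: CoagulationPanel, policy: Optional[ScorePolicy] = None) -> CriterionScore:
    """KSTH: five one-point items, DIC at >= 3 (default threshold)."""
    policy = policy or ScorePolicy()
    warnings: list[str] = []
    crit = Criterion.KSTH
    plt = _require(panel.platelet_count, "platelet_count", crit, policy, warnings)
    pt = _require(panel.pt_seconds, "pt_seconds", crit, policy, warnings)
    aptt = _require(panel.aptt_seconds, "aptt_seconds", crit, policy, warnings)
    dd = _fibrin_marker(panel, "d_dimer", crit, policy, warnings)
    fib = _require(panel.fibrinogen, "fibrinogen", crit, policy, warnings)

    components = {
        "platelets": 1 if (plt is not None and plt <= 100.0) else 0,
        "pt": 1
        if (pt is not None and pt_prolongation(pt, _pt_ref(panel, policy)) >= 3.0)
        else 0,
        "aptt": 1
        if (aptt is not None and aptt_prolongation(aptt, _aptt_ref(panel, policy)) >= 5.0)
        else 0,
        "fibrin_marker": 1 if (dd is not None and dd >= 1.0) else 0,
        "fibrinogen": 1 if (fib is not None and fib <= 1.5) else 0,
    }
    return _make_score(crit, components, policy, warnings)


def score_isth(panel: CoagulationPanel, policy: Optional[ScorePolicy] = None) -> CriterionScore:
    """ISTH overt DIC: weighted four-item score, DIC at >= 5 (default)."""
    policy = policy or ScorePolicy()
    warnings: list[str] = []
    crit = Criterion.ISTH
    plt = _require(panel.platelet_count, "platelet_count", crit, policy, warnings)
    pt = _require(panel.pt_seconds, "pt_seconds", crit, policy, warnings)
    dd = _fibrin_marker(panel, "d_dimer", crit, policy, warnings)
    fib = _require(panel.fibrinogen, "fibrinogen", crit, policy, warnings)

    plt_pts = 0
    if plt is not None:
        if plt <= 50.0:
            plt_pts = 2
        elif plt <= 100.0:
            plt_pts = 1
    pt_pts = 0
    if pt is not None:
        prol = pt_prolongation(pt, _pt_ref(panel, policy))
        if prol >= 6.0:
            pt_pts = 2
        elif prol >= 3.0:
            pt_pts = 1
    dd_pts = 0
    if dd is not None:
        if dd >= 5.0:
            dd_pts = 3
        elif dd >= 1.0:
            dd_pts = 2
    components = {
        "platelets": plt_pts,
        "pt": pt_pts,
        "fibrin_marker": dd_pts,
        "fibrinogen": 1 if (fib is not None and fib <= 1.0) else 0,
    }
    return _make_score(crit, components, policy, warnings)


def _jaam_platelet_points(
    plt: Optional[float],
    prior: Optional[float],
    warnings: list[str],
) -> int:
    """JAAM platelet item: absolute bands plus 24-h relative-drop clauses.

    The drop clauses are active only when a prior-24-h platelet value is
    available; otherwise a warning is attached and only the absolute bands
    apply (the usual situation for single-day data).
    """
    if plt is None:
        return 0
    drop = None
    if prior is not None and prior > 0:
        drop = (prior - plt) / prior
    else:
        warnings.append(
            "JAAM platelet-drop clause inactive: no prior 24 h platelet value"
        )
    if plt < 80.0 or (drop is not None and drop > 0.50):
        return 3
    if (80.0 <= plt < 120.0) or (drop is not None and drop > 0.30):
        return 1
    return 0


def _jaam_components(
    panel: CoagulationPanel,
    sirs: int,
    criterion: Criterion,
    policy: ScorePolicy,
    warnings: list[str],
) -> dict[str, int]:
    plt = _require(panel.platelet_count, "platelet_count", criterion, policy, warnings)
    pt = _require(panel.pt_seconds, "pt_seconds", criterion, policy, warnings)
    fdp = _fibrin_marker(panel, "fdp", criterion, policy, warnings)

    fdp_pts = 0
    if fdp is not None:
        if fdp >= 25.0:
            fdp_pts = 3
        elif fdp >= 10.0:
            fdp_pts = 1
    return {
        "platelets": _jaam_platelet_points(plt, panel.platelet_prior_24h, warnings),
        "pt": 1
        if (pt is not None and pt_ratio(pt, _pt_ref(panel, policy)) >= 1.2)
        else 0,
        "fibrin_marker": fdp_pts,
        "sirs": 1 if sirs >= 3 else 0,
    }


def score_jaam(
    panel: CoagulationPanel, sirs: int, policy: Optional[ScorePolicy] = None
) -> CriterionScore:
    """JAAM acute-phase DIC, DIC at >= 5 (default threshold)."""
    policy = policy or ScorePolicy()
    if not (0 <= sirs <= 4):
        raise ConfigurationError(f"SIRS score must be in [0, 4], got {sirs}")
    warnings: list[str] = []
    crit = Criterion.JAAM
    components = _jaam_components(panel, sirs, crit, policy, warnings)
    fib = _require(panel.fibrinogen, "fibrinogen", crit, policy, warnings)
    components["fibrinogen"] = 1 if (fib is not None and fib <= 3.5) else 0
    return _make_score(crit, components, policy, warnings)


def score_rjaam(
    panel: CoagulationPanel, sirs: int, policy: Optional[ScorePolicy] = None
) -> CriterionScore:
    """Revised JAAM: the JAAM rubric without the fibrinogen item."""
    policy = policy or ScorePolicy()
    if not (0 <= sirs <= 4):
        raise ConfigurationError(f"SIRS score must be in [0, 4], got {sirs}")
    warnings: list[str] = []
    crit = Criterion.RJAAM
    components = _jaam_components(panel, sirs, crit, policy, warnings)
    return _make_score(crit, components, policy, warnings)


def score_jmhw(
    panel: CoagulationPanel,
    context: ClinicalContext,
    policy: Optional[ScorePolicy] = None,
) -> CriterionScore:
    """JMHW: banded labs plus three clinical items, DIC at >= 7 (default)."""
    policy = policy or ScorePolicy()
    warnings: list[str] = []
    crit = Criterion.JMHW
    plt = _require(panel.platelet_count, "platelet_count", crit, policy, warnings)
    pt = _require(panel.pt_seconds, "pt_seconds", crit, policy, warnings)
    fdp = _fibrin_marker(panel, "fdp", crit, policy, warnings)
    fib = _require(panel.fibrinogen, "fibrinogen", crit, policy, warnings)

    plt_pts = 0
    if plt is not None:
        if plt <= 50.0:
            plt_pts = 3
        elif plt <= 80.0:
            plt_pts = 2
        elif plt <= 120.0:
            plt_pts = 1
    pt_pts = 0
    if pt is not None:
        ratio = pt_ratio(pt, _pt_ref(panel, policy))
        if ratio >= 1.67:
            pt_pts = 2
        elif ratio >= 1.25:
            pt_pts = 1
    fdp_pts = 0
    if fdp is not None:
        if fdp >= 40.0:
            fdp_pts = 3
        elif fdp >= 20.0:
            fdp_pts = 2
        elif fdp >= 10.0:
            fdp_pts = 1
    fib_pts = 0
    if fib is not None:
        if fib <= 1.0:
            fib_pts = 2
        elif fib <= 1.5:
            fib_pts = 1

    components = {
        "platelets": plt_pts,
        "pt": pt_pts,
        "fibrin_marker": fdp_pts,
        "fibrinogen": fib_pts,
    }
    for flag_name in ("underlying_disease", "bleeding", "organ_failure"):
        flag = getattr(context, flag_name)
        if flag is None:
            warnings.append(f"JMHW: clinical flag '{flag_name}' missing, treated as absent")
            flag = False
        components[flag_name] = 1 if flag else 0
    return _make_score(crit, components, policy, warnings)


def _sirs_for_record(record: PatientRecord, warnings: list[str]) -> int:
    if record.context.sirs_precomputed is not None:
        return record.context.sirs_precomputed
    return compute_sirs(record.vitals, warnings)


def score_all(
    record: PatientRecord,
    policy: Optional[ScorePolicy] = None,
    criteria: Optional[list[Criterion]] = None,
    collect_errors: bool = False,
):
    """Score one record under all five criteria (or a selected subset).

    All five scores are computed from the same single-day values; the SIRS
    score is taken from ``context.sirs_precomputed`` when present, else
    derived from the vitals.

    Returns a dict ``Criterion -> CriterionScore``.  If any criterion fails
    (missing marker under the strict policy), the default behaviour is to
    raise a :class:`MissingDataError` whose ``partial`` attribute holds the
    criteria that did score and whose ``failures`` maps each failed
    criterion to its message.  With ``collect_errors=True`` the pair
    ``(scores, failures)`` is returned instead of raising.
    """
    from .types import CRITERION_ORDER

    policy = policy or ScorePolicy()
    selected = list(criteria) if criteria else list(CRITERION_ORDER)
    scores: dict[Criterion, CriterionScore] = {}
    failures: dict[Criterion, str] = {}

    sirs: Optional[int] = None
    sirs_error: Optional[str] = None
    if any(c in (Criterion.JAAM, Criterion.RJAAM) for c in selected):
        sirs_warnings: list[str] = []
        try:
            sirs = _sirs_for_record(record, sirs_warnings)
        except MissingDataError as exc:
            sirs_error = str(exc)

    for crit in selected:
        try:
            if crit is Criterion.KSTH:
                scores[crit] = score_ksth(record.panel, policy)
            elif crit is Criterion.ISTH:
                scores[crit] = score_isth(record.panel, policy)
            elif crit is Criterion.JAAM:
                if sirs is None:
                    raise MissingDataError(f"JAAM: SIRS unavailable ({sirs_error})")
                scores[crit] = score_jaam(record.panel, sirs, policy)
            elif crit is Criterion.RJAAM:
                if sirs is None:
                    raise MissingDataError(f"R-JAAM: SIRS unavailable ({sirs_error})")
                scores[crit] = score_rjaam(record.panel, sirs, policy)
            elif crit is Criterion.JMHW:
                scores[crit] = score_jmhw(record.panel, record.context, policy)
        except MissingDataError as exc:
            failures[crit] = str(exc)

    if collect_errors:
        return scores, failures
    if failures:
        failed = ", ".join(f"{c.display_name}: {m}" for c, m in failures.items())
        raise MissingDataError(
            f"record {record.patient_id}: scoring failed for "
            f"{len(failures)} criteria ({failed})",
            partial=scores,
            failures=failures,
        )
    return scores
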