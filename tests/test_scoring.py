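"""Unit tests for the five scoring rubrics, SIRS, and score_all dispatch."""

import itertools

import pytest

from dicscore import (
    ClinicalContext,
    CoagulationPanel,
    Criterion,
    MissingDataError,
    MissingMarkerPolicy,
    ScorePolicy,
    VitalSet,
    compute_sirs,
    pt_prolongation,
    pt_ratio,
    score_all,
    score_isth,
    score_jaam,
    score_jmhw,
    score_ksth,
    score_rjaam,
)
from conftest import make_panel, make_record
from oracles import (
    oracle_isth,
    oracle_jaam,
    oracle_jmhw,
    oracle_ksth,
    oracle_rjaam,
)


class TestPtTransforms:
    @pytest.mark.parametrize(
        "pt,ref,expected",
        [(15.0, 12.0, 3.0), (12.0, 12.0, 0.0), (20.3, 12.0, 8.3)],
    )
    def test_prolongation(self, pt, ref, expected):
        assert pt_prolongation(pt, ref) == pytest.approx(expected)

    def test_prolongation_may_be_negative(self):
        assert pt_prolongation(10.0, 12.0) == pytest.approx(-2.0)

    @pytest.mark.parametrize(
        "pt,ref,expected",
        [(12.0, 12.0, 1.0), (15.0, 12.0, 1.25), (24.0, 12.0, 2.0)],
    )
    def test_ratio(self, pt, ref, expected):
        assert pt_ratio(pt, ref) == pytest.approx(expected)

    def test_missing_input_names_the_field(self):
        with pytest.raises(MissingDataError, match="pt_seconds"):
            pt_prolongation(None, 12.0)


class TestSirs:
    @pytest.mark.parametrize(
        "temp,hr,rr,wbc,expected",
        [
            (37.0, 80.0, 16.0, 8.0, 0),
            (38.5, 110.0, 24.0, 15.0, 4),
            # HR and RR sit exactly at their thresholds: strict inequality, 0 points
            (35.5, 90.0, 20.0, 3.5, 2),
        ],
    )
    def test_standard_thresholds(self, temp, hr, rr, wbc, expected):
        vitals = VitalSet(temperature=temp, heart_rate=hr, respiratory_rate=rr, wbc=wbc)
        assert compute_sirs(vitals) == expected

    def test_missing_component_contributes_zero_with_warning(self):
        warnings = []
        score = compute_sirs(
            VitalSet(temperature=38.5, heart_rate=110.0), warnings
        )
        assert score == 2
        assert any("respiratory_rate" in w for w in warnings)
        assert any("wbc" in w for w in warnings)

    def test_all_missing_raises(self):
        with pytest.raises(MissingDataError):
            compute_sirs(VitalSet())


class TestKsth:
    def test_all_normal_scores_zero(self, policy):
        score = score_ksth(make_panel(), policy)
        assert score.total == 0 and not score.dic_positive

    def test_fully_deranged_panel_scores_five(self, policy):
        # prolongations 4 s PT / 6 s aPTT at references 12 / 30
        panel = make_panel(platelet_count=90, pt_seconds=16.0, aptt_seconds=36.0,
                           d_dimer=2.0, fibrinogen=1.2)
        score = score_ksth(panel, policy)
        assert score.total == 5 and score.dic_positive

    def test_inclusive_boundaries(self, policy):
        # every scored item exactly at its inclusive edge: platelets 100,
        # PT prolongation 2 (below), aPTT prolongation 5, D-dimer 1.0,
        # fibrinogen 1.6 (above) -> platelet + aPTT + D-dimer = 3, positive
        panel = make_panel(platelet_count=100.0, pt_seconds=14.0,
                           aptt_seconds=35.0, d_dimer=1.0, fibrinogen=1.6)
        score = score_ksth(panel, policy)
        assert score.components == {
            "platelets": 1, "pt": 0, "aptt": 1, "fibrin_marker": 1, "fibrinogen": 0,
        }
        assert score.total == 3 and score.dic_positive


class TestIsth:
    def test_all_normal_scores_zero(self, policy):
        score = score_isth(make_panel(), policy)
        assert score.total == 0 and not score.dic_positive

    def test_severe_panel(self, policy):
        # platelets 45 (2), PT prolongation 6.5 (2), D-dimer 6.0 (3), fibrinogen 0.8 (1)
        panel = make_panel(platelet_count=45.0, pt_seconds=18.5, d_dimer=6.0,
                           fibrinogen=0.8)
        score = score_isth(panel, policy)
        assert score.components == {
            "platelets": 2, "pt": 2, "fibrin_marker": 3, "fibrinogen": 1,
        }
        assert score.total == 8 and score.dic_positive

    def test_inclusive_boundaries(self, policy):
        # platelets 100 (1), PT prolongation exactly 3.0 (1), D-dimer exactly
        # 5.0 (3), fibrinogen exactly 1.0 (1) -> 6, positive
        panel = make_panel(platelet_count=100.0, pt_seconds=15.0, d_dimer=5.0,
                           fibrinogen=1.0)
        score = score_isth(panel, policy)
        assert score.components == {
            "platelets": 1, "pt": 1, "fibrin_marker": 3, "fibrinogen": 1,
        }
        assert score.total == 6 and score.dic_positive


class TestJaamFamily:
    def test_all_normal_scores_zero(self, policy):
        panel = make_panel(platelet_count=150.0, fibrinogen=4.0)
        score = score_jaam(panel, sirs=1, policy=policy)
        assert score.total == 0 and not score.dic_positive

    def test_severe_panel(self, policy):
        # platelets 70 (3), PT ratio 1.3 (1), FDP 30 (3), fibrinogen 3.0 (1), SIRS 3 (1)
        panel = make_panel(platelet_count=70.0, pt_seconds=15.6, fdp=30.0,
                           fibrinogen=3.0)
        score = score_jaam(panel, sirs=3, policy=policy)
        assert score.total == 9 and score.dic_positive

    def test_relative_drop_clause_overrides_absolute_band(self, policy):
        # 130 with prior 220 is a 40.9% drop: >30% but <=50% -> 1 point
        # despite the absolute count being >= 120
        panel = make_panel(platelet_count=130.0, platelet_prior_24h=220.0,
                           pt_seconds=13.2, fdp=12.0, fibrinogen=4.0)
        score = score_jaam(panel, sirs=2, policy=policy)
        assert score.components["platelets"] == 1
        assert score.total == 2 and not score.dic_positive

    def test_drop_clause_inactive_without_prior_value(self, policy):
        panel = make_panel(platelet_count=150.0, fibrinogen=4.0)
        score = score_jaam(panel, sirs=0, policy=policy)
        assert score.components["platelets"] == 0
        assert any("drop clause inactive" in w for w in score.warnings)

    def test_rjaam_is_jaam_without_fibrinogen(self, policy):
        panel = make_panel(platelet_count=70.0, pt_seconds=15.6, fdp=30.0,
                           fibrinogen=3.0)
        jaam = score_jaam(panel, sirs=3, policy=policy)
        rjaam = score_rjaam(panel, sirs=3, policy=policy)
        assert rjaam.total == jaam.total - jaam.components["fibrinogen"] == 8
        assert "fibrinogen" not in rjaam.components
        assert rjaam.dic_positive


class TestJmhw:
    def test_all_normal_no_flags_scores_zero(self, policy):
        score = score_jmhw(make_panel(), ClinicalContext(
            underlying_disease=False, bleeding=False, organ_failure=False), policy)
        assert score.total == 0 and not score.dic_positive

    def test_severe_record(self, policy):
        # platelets 45 (3), ratio 1.8 (2), FDP 45 (3), fibrinogen 0.9 (2), flags (3)
        panel = make_panel(platelet_count=45.0, pt_seconds=21.6, fdp=45.0,
                           fibrinogen=0.9)
        context = ClinicalContext(underlying_disease=True, bleeding=True,
                                  organ_failure=True)
        score = score_jmhw(panel, context, policy)
        assert score.total == 13 and score.dic_positive

    def test_band_boundaries_reach_threshold_exactly(self, policy):
        # platelets 75 (2), ratio 1.30 (1), FDP 25 (2), fibrinogen 1.2 (1),
        # underlying disease (1) -> exactly 7
        panel = make_panel(platelet_count=75.0, pt_seconds=15.6, fdp=25.0,
                           fibrinogen=1.2)
        context = ClinicalContext(underlying_disease=True, bleeding=False,
                                  organ_failure=False)
        score = score_jmhw(panel, context, policy)
        assert score.components == {
            "platelets": 2, "pt": 1, "fibrin_marker": 2, "fibrinogen": 1,
            "underlying_disease": 1, "bleeding": 0, "organ_failure": 0,
        }
        assert score.total == 7 and score.dic_positive

    def test_missing_flags_treated_false_with_warning(self, policy):
        score = score_jmhw(make_panel(), ClinicalContext(), policy)
        assert score.components["bleeding"] == 0
        assert sum("clinical flag" in w for w in score.warnings) == 3


class TestMissingMarkerPolicy:
    def test_strict_policy_names_marker_and_criterion(self, policy):
        panel = make_panel(d_dimer=None)
        with pytest.raises(MissingDataError, match="KSTH.*d_dimer"):
            score_ksth(panel, policy)

    def test_lenient_policy_scores_zero_with_warning(self):
        lenient = ScorePolicy(
            missing_marker_policy=MissingMarkerPolicy.SCORE_ZERO_WITH_WARNING
        )
        score = score_ksth(make_panel(d_dimer=None), lenient)
        assert score.components["fibrin_marker"] == 0
        assert any("d_dimer" in w for w in score.warnings)

    def test_fibrin_fallback_uses_other_marker_with_warning(self):
        fallback = ScorePolicy(fibrin_marker_fallback=True)
        # D-dimer missing, FDP 2.0 >= 1.0 under the KSTH band
        score = score_ksth(make_panel(d_dimer=None, fdp=2.0), fallback)
        assert score.components["fibrin_marker"] == 1
        assert any("fell back" in w for w in score.warnings)


class TestScoreAll:
    def test_all_normal_record_all_negative(self, policy, normal_record):
        scores = score_all(normal_record, policy)
        assert set(scores) == set(Criterion)
        assert all(not s.dic_positive for s in scores.values())
        assert all(s.total == 0 for c, s in scores.items()
                   if c is not Criterion.JAAM)  # JAAM fibrinogen <=3.5 scores 1
        assert scores[Criterion.JAAM].total == 1

    def test_severe_record_all_positive(self, policy, severe_record):
        scores = score_all(severe_record, policy)
        assert all(s.dic_positive for s in scores.values())

    def test_missing_fdp_fails_only_fdp_criteria(self, policy):
        record = make_record(panel=make_panel(fdp=None))
        with pytest.raises(MissingDataError) as excinfo:
            score_all(record, policy)
        exc = excinfo.value
        assert set(exc.partial) == {Criterion.KSTH, Criterion.ISTH}
        assert set(exc.failures) == {Criterion.JAAM, Criterion.RJAAM, Criterion.JMHW}

    def test_collect_errors_returns_partial_scores(self, policy):
        record = make_record(panel=make_panel(fdp=None))
        scores, failures = score_all(record, policy, collect_errors=True)
        assert set(scores) == {Criterion.KSTH, Criterion.ISTH}
        assert len(failures) == 3

    def test_precomputed_sirs_takes_precedence(self, policy):
        record = make_record(
            context=ClinicalContext(sirs_precomputed=4),
            vitals=VitalSet(temperature=37.0, heart_rate=80.0,
                            respiratory_rate=16.0, wbc=8.0),  # would give SIRS 0
        )
        scores = score_all(record, policy)
        assert scores[Criterion.JAAM].components["sirs"] == 1


class TestOracleGrid:
    """Each scorer matches the literal nested-conditional rubric on a grid
    straddling every band boundary (>= 3 points per band per marker)."""

    PLT = [30.0, 49.0, 50.0, 51.0, 79.0, 80.0, 81.0, 100.0, 101.0, 119.0, 120.0, 150.0]
    DD = [0.5, 0.9, 1.0, 1.1, 4.9, 5.0, 5.1, 8.0]
    FDP = [5.0, 9.0, 10.0, 11.0, 20.0, 24.0, 25.0, 26.0, 39.0, 40.0, 41.0]
    FIB = [0.5, 0.9, 1.0, 1.1, 1.4, 1.5, 1.6, 3.4, 3.5, 3.6, 4.0]

    def test_ksth_matches_oracle(self, policy):
        prols = [0.0, 2.9, 3.0, 3.1, 6.0]
        aptts = [0.0, 4.9, 5.0, 5.1]
        for plt, prol, aptt, dd, fib in itertools.product(
            self.PLT[::2], prols, aptts, self.DD, self.FIB[::2]
        ):
            panel = CoagulationPanel(
                platelet_count=plt, pt_seconds=12.0 + prol,
                pt_reference_seconds=12.0, aptt_seconds=30.0 + aptt,
                aptt_reference_seconds=30.0, d_dimer=dd, fibrinogen=fib)
            # feed the oracle the same resolved prolongations the scorer sees
            assert score_ksth(panel, policy).total == oracle_ksth(
                plt, panel.pt_seconds - 12.0, panel.aptt_seconds - 30.0, dd, fib)

    def test_isth_matches_oracle(self, policy):
        prols = [0.0, 2.9, 3.0, 5.9, 6.0, 6.1]
        for plt, prol, dd, fib in itertools.product(
            self.PLT, prols, self.DD, self.FIB
        ):
            panel = CoagulationPanel(
                platelet_count=plt, pt_seconds=12.0 + prol,
                pt_reference_seconds=12.0, aptt_seconds=30.0, d_dimer=dd,
                fibrinogen=fib)
            assert score_isth(panel, policy).total == oracle_isth(
                plt, panel.pt_seconds - 12.0, dd, fib)

    def test_jaam_and_rjaam_match_oracle(self, policy):
        ratios = [1.0, 1.19, 1.2, 1.21, 1.5]
        priors = [None, 100.0, 200.0, 400.0]
        for plt, prior, ratio, fdp, fib in itertools.product(
            self.PLT[::2], priors, ratios, self.FDP, self.FIB[::3]
        ):
            panel = CoagulationPanel(
                platelet_count=plt, platelet_prior_24h=prior,
                pt_seconds=12.0 * ratio, pt_reference_seconds=12.0,
                aptt_seconds=30.0, fdp=fdp, fibrinogen=fib)
            resolved_ratio = panel.pt_seconds / 12.0
            for sirs in (2, 3):
                assert score_jaam(panel, sirs, policy).total == oracle_jaam(
                    plt, prior, resolved_ratio, fdp, fib, sirs)
                assert score_rjaam(panel, sirs, policy).total == oracle_rjaam(
                    plt, prior, resolved_ratio, fdp, fib, sirs)

    def test_jmhw_matches_oracle(self, policy):
        ratios = [1.0, 1.24, 1.25, 1.26, 1.66, 1.67, 1.68]
        context = ClinicalContext(underlying_disease=True, bleeding=False,
                                  organ_failure=True)
        for plt, ratio, fdp, fib in itertools.product(
            self.PLT, ratios, self.FDP, self.FIB[:7]
        ):
            panel = CoagulationPanel(
                platelet_count=plt, pt_seconds=12.0 * ratio,
                pt_reference_seconds=12.0, aptt_seconds=30.0, fdp=fdp,
                fibrinogen=fib)
            assert score_jmhw(panel, context, policy).total == oracle_jmhw(
                plt, panel.pt_seconds / 12.0, fdp, fib, True, False, True)
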