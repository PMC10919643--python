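import pytest

from dicscore import (
    ClinicalContext,
    CoagulationPanel,
    Criterion,
    Outcome,
    PatientRecord,
    ScorePolicy,
    VitalSet,
)

# Published five-criterion outcome split: criterion -> (n DIC-positive,
# expired among positive), over a 222-patient cohort with 154 expired and
# 68 survived.  Table-4-style metrics are exactly derivable from these.
COHORT_TOTAL = 222
N_EXPIRED = 154
N_SURVIVED = 68
OUTCOME_SPLIT = {
    Criterion.KSTH: (210, 147),
    Criterion.ISTH: (142, 107),
    Criterion.JAAM: (154, 117),
    Criterion.RJAAM: (108, 85),
    Criterion.JMHW: (118, 92),
}


def contingency_counts(criterion):
    """(tp, fp, fn, tn) for one criterion from the published counts."""
    n_pos, tp = OUTCOME_SPLIT[criterion]
    fp = n_pos - tp
    return tp, fp, N_EXPIRED - tp, N_SURVIVED - fp


@pytest.fixture
def policy():
    return ScorePolicy()


def make_panel(**overrides):
    """A panel with unremarkable coagulation values; override per test."""
    defaults = dict(
        platelet_count=250.0,
        pt_seconds=12.0,
        aptt_seconds=30.0,
        d_dimer=0.5,
        fdp=5.0,
        fibrinogen=3.0,
    )
    defaults.update(overrides)
    return CoagulationPanel(**defaults)


def make_record(patient_id="P1", outcome=Outcome.SURVIVED, panel=None,
                vitals=None, context=None, **kwargs):
    return PatientRecord(
        patient_id=patient_id,
        panel=panel if panel is not None else make_panel(),
        vitals=vitals
        if vitals is not None
        else VitalSet(temperature=37.0, heart_rate=80.0, respiratory_rate=16.0,
                      wbc=8.0),
        context=context if context is not None else ClinicalContext(
            underlying_disease=False, bleeding=False, organ_failure=False),
        outcome=outcome,
        **kwargs,
    )


@pytest.fixture
def normal_record():
    return make_record()


@pytest.fixture
def severe_record():
    """A record every criterion calls DIC-positive."""
    return make_record(
        panel=make_panel(
            platelet_count=45.0,
            pt_seconds=24.0,  # prolongation 12 s, ratio 2.0 at reference 12
            aptt_seconds=45.0,
            d_dimer=6.0,
            fdp=45.0,
            fibrinogen=0.9,
        ),
        vitals=VitalSet(temperature=38.5, heart_rate=110.0, respiratory_rate=24.0,
                        wbc=15.0),
        context=ClinicalContext(underlying_disease=True, bleeding=True,
                                organ_failure=True),
        outcome=Outcome.EXPIRED,
    )
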