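"""Domain types: patient records, laboratory panels and per-criterion scores.

Missing values are represented as ``None`` throughout; every numeric field is
validated against its physical range when present.  The unit of scoring is a
single patient-day: one coagulation panel, one vital-sign set and one set of
clinical flags, all drawn from the day the clinician suspected disseminated
intravascular coagulation (DIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import ValidationError


class Criterion(str, Enum):
    """The five rule-based DIC scoring systems.

    KSTH  -- Korean Society on Thrombosis and Hemostasis
    ISTH  -- International Society on Thrombosis and Haemostasis (overt DIC)
    JAAM  -- Japanese Association for Acute Medicine (acute-phase DIC)
    RJAAM -- revised JAAM (JAAM without the fibrinogen item)
    JMHW  -- Japanese Ministry of Health and Welfare
    """

    KSTH = "KSTH"
    ISTH = "ISTH"
    JAAM = "JAAM"
    RJAAM = "RJAAM"
    JMHW = "JMHW"

    @property
    def display_name(self) -> str:
        return "R-JAAM" if self is Criterion.RJAAM else self.value

    @classmethod
    def parse(cls, name: str) -> "Criterion":
        """Parse a criterion name case-insensitively; accepts 'R-JAAM'."""
        key = name.strip().upper().replace("-", "").replace("_", "")
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown criterion {name!r}; expected one of "
                f"{', '.join(c.display_name for c in cls)}"
            ) from None


#: Canonical report ordering of the five criteria.
CRITERION_ORDER = (
    Criterion.KSTH,
    Criterion.ISTH,
    Criterion.JAAM,
    Criterion.RJAAM,
    Criterion.JMHW,
)


class Outcome(str, Enum):
    SURVIVED = "survived"
    EXPIRED = "expired"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Outcome":
        """Map outcome synonyms (discharged/alive, died/dead/deceased)."""
        key = (value or "").strip().lower()
        synonyms = {
            "survived": cls.SURVIVED,
            "discharged": cls.SURVIVED,
            "alive": cls.SURVIVED,
            "expired": cls.EXPIRED,
            "died": cls.EXPIRED,
            "dead": cls.EXPIRED,
            "deceased": cls.EXPIRED,
            "unknown": cls.UNKNOWN,
            "": cls.UNKNOWN,
        }
        if key not in synonyms:
            raise ValidationError(f"unknown outcome {value!r}")
        return synonyms[key]


class ExclusionFlag(str, Enum):
    """Cohort-eligibility exclusions applied before scoring."""

    HEMATOLOGIC_DISEASE = "hematologic_disease"
    BLEEDING_DISORDER = "bleeding_disorder"
    ANTICOAGULATION_OR_CHEMO = "anticoagulation_or_chemo"
    CHILD_PUGH_C = "child_pugh_C"


def _check_nonneg(name: str, value: Optional[float]) -> None:
    if value is not None and value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")


def _check_range(name: str, value: Optional[float], lo: float, hi: float) -> None:
    if value is not None and not (lo <= value <= hi):
        raise ValidationError(f"{name} must be in [{lo}, {hi}], got {value}")


@dataclass(frozen=True)
class CoagulationPanel:
    """Single-day coagulation laboratory panel.

    Units: platelets x10^9/L; PT/aPTT seconds; D-dimer and FDP ug/mL;
    fibrinogen g/L (the canonical storage unit — readers convert mg/dL).
    ``platelet_prior_24h`` enables the JAAM/R-JAAM platelet-drop clauses and
    is usually absent in single-day data.  Per-record PT/aPTT references
    override the policy defaults when present.
    """

    platelet_count: Optional[float] = None
    platelet_prior_24h: Optional[float] = None
    pt_seconds: Optional[float] = None
    pt_reference_seconds: Optional[float] = None
    aptt_seconds: Optional[float] = None
    aptt_reference_seconds: Optional[float] = None
    d_dimer: Optional[float] = None
    fdp: Optional[float] = None
    fibrinogen: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "platelet_count",
            "platelet_prior_24h",
            "pt_seconds",
            "aptt_seconds",
            "d_dimer",
            "fdp",
            "fibrinogen",
        ):
            _check_nonneg(name, getattr(self, name))
        for name in ("pt_reference_seconds", "aptt_reference_seconds"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class VitalSet:
    """Vital signs plus white-cell count; inputs to the SIRS score.

    ``map_mmhg`` and ``lactate`` are carried for cohort comparison only and
    never scored.
    """

    temperature: Optional[float] = None  # degrees C
    heart_rate: Optional[float] = None  # beats/min
    respiratory_rate: Optional[float] = None  # breaths/min
    wbc: Optional[float] = None  # x10^9/L
    map_mmhg: Optional[float] = None
    lactate: Optional[float] = None  # mmol/L

    def __post_init__(self) -> None:
        _check_range("temperature", self.temperature, 25.0, 45.0)
        for name in ("heart_rate", "respiratory_rate"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be > 0, got {value}")
        _check_nonneg("wbc", self.wbc)
        _check_nonneg("map_mmhg", self.map_mmhg)
        _check_nonneg("lactate", self.lactate)


@dataclass(frozen=True)
class ClinicalContext:
    """Clinical flags and pass-through severity scores.

    Booleans are tri-state (True/False/None-missing).  ``sofa_score`` is a
    provided covariate, never derived here.  ``sirs_precomputed``, when set,
    takes precedence over deriving SIRS from the vitals.
    """

    underlying_disease: Optional[bool] = None
    bleeding: Optional[bool] = None
    organ_failure: Optional[bool] = None
    septic_shock: Optional[bool] = None
    dialysis: Optional[bool] = None
    ventilated: Optional[bool] = None
    sofa_score: Optional[int] = None
    sirs_precomputed: Optional[int] = None
    assessment_day: int = 1

    def __post_init__(self) -> None:
        if self.sofa_score is not None and not (0 <= self.sofa_score <= 24):
            raise ValidationError(f"sofa_score must be in [0, 24], got {self.sofa_score}")
        if self.sirs_precomputed is not None and not (0 <= self.sirs_precomputed <= 4):
            raise ValidationError(
                f"sirs_precomputed must be in [0, 4], got {self.sirs_precomputed}"
            )
        if self.assessment_day < 1:
            raise ValidationError(f"assessment_day must be >= 1, got {self.assessment_day}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's single-day labs, vitals, flags and hospital outcome."""

    patient_id: str
    panel: CoagulationPanel = field(default_factory=CoagulationPanel)
    vitals: VitalSet = field(default_factory=VitalSet)
    context: ClinicalContext = field(default_factory=ClinicalContext)
    outcome: Outcome = Outcome.UNKNOWN
    icd9_codes: tuple[str, ...] = ()
    exclusion_flags: frozenset[ExclusionFlag] = frozenset()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        object.__setattr__(self, "icd9_codes", tuple(self.icd9_codes))
        object.__setattr__(self, "exclusion_flags", frozenset(self.exclusion_flags))


@dataclass
class CriterionScore:
    """Per-component points, total and DIC call for one criterion.

    Invariants (checked on construction): the total equals the sum of the
    component points, and the DIC call is exactly ``total >= threshold``.
    """

    criterion: Criterion
    components: dict[str, int]
    total: int
    threshold: int
    dic_positive: bool
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValidationError("component points must be >= 0")
        if self.total != sum(self.components.values()):
            raise ValidationError(
                f"{self.criterion.display_name}: total {self.total} != "
                f"component sum {sum(self.components.values())}"
            )
        if self.dic_positive != (self.total >= self.threshold):
            raise ValidationError(
                f"{self.criterion.display_name}: dic_positive inconsistent with "
                f"total {self.total} vs threshold {self.threshold}"
            )
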