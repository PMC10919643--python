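"""Scoring policy: thresholds, references, boundary conventions, missing-data mode.

Every tunable of the scoring engine lives here so that a report can embed the
exact configuration it was produced under.  The policy round-trips through
YAML bit-exactly (``to_yaml`` / ``from_yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import yaml

from .errors import ConfigurationError
from .types import Criterion

POLICY_VERSION = "1.0"

#: Documented interval-endpoint conventions for every scored band.  Touching
#: printed bands are made half-open so each value maps to exactly one band:
#: the more-severe band takes the shared endpoint for platelets and
#: fibrinogen (falling markers), and PT-ratio/FDP bands are closed on their
#: listed lower bound (rising markers).  This table is embedded in reports
#: for provenance; the scoring code implements it literally.
BOUNDARY_CONVENTIONS: dict[str, str] = {
    "ksth.platelets": "1 point iff <= 100",
    "ksth.pt_prolongation_s": "1 point iff >= 3",
    "ksth.aptt_prolongation_s": "1 point iff >= 5",
    "ksth.d_dimer": "1 point iff >= 1.0",
    "ksth.fibrinogen": "1 point iff <= 1.5",
    "isth.platelets": "2 points iff <= 50; 1 point iff (50, 100]",
    "isth.pt_prolongation_s": "2 points iff >= 6; 1 point iff [3, 6)",
    "isth.d_dimer": "3 points iff >= 5.0; 2 points iff [1.0, 5.0)",
    "isth.fibrinogen": "1 point iff <= 1.0",
    "jaam.platelets": "3 points iff < 80 or >50% drop in <=24 h; "
    "1 point iff [80, 120) or >30% drop",
    "jaam.pt_ratio": "1 point iff >= 1.2",
    "jaam.fdp": "3 points iff >= 25; 1 point iff [10, 25)",
    "jaam.fibrinogen": "1 point iff <= 3.5",
    "jaam.sirs": "1 point iff >= 3",
    "jmhw.platelets": "3 points iff <= 50; 2 iff (50, 80]; 1 iff (80, 120]",
    "jmhw.pt_ratio": "2 points iff >= 1.67; 1 iff [1.25, 1.67)",
    "jmhw.fdp": "3 points iff >= 40; 2 iff [20, 40); 1 iff [10, 20)",
    "jmhw.fibrinogen": "2 points iff <= 1.0; 1 iff (1.0, 1.5]",
    "jmhw.clinical": "1 point each iff underlying disease / bleeding / organ failure",
}


class MissingMarkerPolicy(str, Enum):
    """What to do when a marker a criterion scores is absent.

    ``strict`` raises a :class:`~dicscore.errors.MissingDataError` naming the
    marker and criterion; ``score_zero_with_warning`` scores the component 0
    and attaches a warning (exploratory use only — silent zeros bias totals
    downward).
    """

    STRICT = "strict"
    SCORE_ZERO_WITH_WARNING = "score_zero_with_warning"


def _default_thresholds() -> dict[Criterion, int]:
    return {
        Criterion.KSTH: 3,
        Criterion.ISTH: 5,
        Criterion.JAAM: 5,
        Criterion.RJAAM: 5,
        Criterion.JMHW: 7,
    }


@dataclass
class ScorePolicy:
    """All configurable knobs of the DIC scoring engine.

    Parameters
    ----------
    pt_reference_seconds, aptt_reference_seconds
        Laboratory reference values used to derive PT prolongation/ratio and
        aPTT prolongation when a record does not carry its own references.
        Defaults 12.0 s and 30.0 s are typical laboratory midpoints and are
        meant to be overridden with the site's own references.
    thresholds
        DIC positivity cut-offs: KSTH >=3, ISTH >=5, JAAM >=5, R-JAAM >=5
        (mirrors JAAM; no separately published cut-off), JMHW >=7.
    missing_marker_policy
        See :class:`MissingMarkerPolicy`.
    fibrin_marker_fallback
        If True, a criterion whose fibrin-related marker (D-dimer for
        KSTH/ISTH, FDP for JAAM/R-JAAM/JMHW) is missing falls back to the
        other marker against the same bands, with a warning.  Off by default:
        the two markers are not interchangeable.
    """

    pt_reference_seconds: float = 12.0
    aptt_reference_seconds: float = 30.0
    thresholds: dict[Criterion, int] = field(default_factory=_default_thresholds)
    missing_marker_policy: MissingMarkerPolicy = MissingMarkerPolicy.STRICT
    fibrin_marker_fallback: bool = False
    version: str = POLICY_VERSION

    def __post_init__(self) -> None:
        if self.pt_reference_seconds <= 0:
            raise ConfigurationError("pt_reference_seconds must be > 0")
        if self.aptt_reference_seconds <= 0:
            raise ConfigurationError("aptt_reference_seconds must be > 0")
        for crit in Criterion:
            if crit not in self.thresholds:
                raise ConfigurationError(f"missing threshold for {crit.display_name}")
            t = self.thresholds[crit]
            if not isinstance(t, int) or t <= 0:
                raise ConfigurationError(
                    f"threshold for {crit.display_name} must be a positive integer"
                )

    def threshold(self, criterion: Criterion) -> int:
        return self.thresholds[criterion]

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "pt_reference_seconds": self.pt_reference_seconds,
            "aptt_reference_seconds": self.aptt_reference_seconds,
            "thresholds": {c.value: self.thresholds[c] for c in Criterion},
            "missing_marker_policy": self.missing_marker_policy.value,
            "fibrin_marker_fallback": self.fibrin_marker_fallback,
            "boundary_conventions": dict(BOUNDARY_CONVENTIONS),
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ScorePolicy":
        data = dict(data)
        data.pop("boundary_conventions", None)  # informational, not a knob
        thresholds = {
            Criterion.parse(k): int(v) for k, v in data.pop("thresholds", {}).items()
        }
        missing = MissingMarkerPolicy(
            data.pop("missing_marker_policy", MissingMarkerPolicy.STRICT.value)
        )
        kwargs = {
            "pt_reference_seconds": float(
                data.pop("pt_reference_seconds", cls.pt_reference_seconds)
            ),
            "aptt_reference_seconds": float(
                data.pop("aptt_reference_seconds", cls.aptt_reference_seconds)
            ),
            "fibrin_marker_fallback": bool(data.pop("fibrin_marker_fallback", False)),
            "version": str(data.pop("version", POLICY_VERSION)),
        }
        if data:
            raise ConfigurationError(f"unknown policy keys: {sorted(data)}")
        full = _default_thresholds()
        full.update(thresholds)
        return cls(thresholds=full, missing_marker_policy=missing, **kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScorePolicy":
        return cls.from_dict(yaml.safe_load(text))
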