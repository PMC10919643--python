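"""Seed-deterministic synthetic sepsis cohorts.

The generator emulates a retrospective sepsis cohort under clinical
suspicion of DIC: the hospital outcome is drawn first (Bernoulli, default
in-hospital mortality 69.4%), then every laboratory marker, vital sign and
clinical flag is drawn from an outcome-conditional distribution.  Skewed
laboratory markers are lognormal with parameters solved from published
per-group medians and interquartile ranges via the lognormal quantile
relation (median m -> mu = ln m; IQR (q1, q3) -> sigma = (ln q3 - ln q1) /
(2 * z_0.75)); temperature and mean arterial pressure are normal.  FDP is
left-censored at the assay floor of 5 ug/mL, which reproduces the
degenerate published quantiles 5.0 (5.0-16.2).

Markers are drawn independently given the outcome group; no correlation
structure is imposed.  Fibrinogen is calibrated in mg/dL (the scale of the
published summaries) and converted to g/L at generation.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml

from .errors import ValidationError
from .types import (
    ClinicalContext,
    CoagulationPanel,
    Outcome,
    PatientRecord,
    VitalSet,
)

__all__ = [
    "GroupParams",
    "MarkerDistribution",
    "CohortSimConfig",
    "default_config",
    "simulate_cohort",
    "inject_missingness",
]

#: standard normal 75th-percentile quantile, used by the IQR -> sigma solver
_Z75 = 0.6744897501960817

#: survivor/non-survivor group keys, in draw order
GROUPS = ("survivor", "nonsurvivor")


@dataclass(frozen=True)
class GroupParams:
    """Location/scale of one outcome group's marker distribution.

    For the lognormal family the location is the log-median and the scale is
    the log-sd; for the normal family they are the mean and sd.
    """

    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class MarkerDistribution:
    family: str  # "lognormal" | "normal"
    survivor: GroupParams
    nonsurvivor: GroupParams
    floor: Optional[float] = None  # left-censoring floor (assay floor)
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ValidationError(f"unknown family {self.family!r}")

    @classmethod
    def from_quantiles(
        cls,
        family: str,
        survivor: tuple[float, float, float],
        nonsurvivor: tuple[float, float, float],
        floor: Optional[float] = None,
        unit: str = "",
    ) -> "MarkerDistribution":
        """Solve group parameters from (median, q1, q3) summaries.

        With a censoring floor at/above q1 the scale is solved one-sided from
        the upper quartile, since the lower quartile is censored.
        """

        def solve(summary: tuple[float, float, float]) -> GroupParams:
            median, q1, q3 = summary
            if family == "normal":
                return GroupParams(location=median, scale=(q3 - q1) / (2 * _Z75))
            if median <= 0 or q1 <= 0 or q3 <= 0:
                raise ValidationError("lognormal quantiles must be > 0")
            mu = math.log(median)
            if floor is not None and q1 <= floor:
                sigma = (math.log(q3) - mu) / _Z75
            else:
                sigma = (math.log(q3) - math.log(q1)) / (2 * _Z75)
            return GroupParams(location=mu, scale=sigma)

        return cls(
            family=family,
            survivor=solve(survivor),
            nonsurvivor=solve(nonsurvivor),
            floor=floor,
            unit=unit,
        )

    def params(self, group: str) -> GroupParams:
        return self.survivor if group == "survivor" else self.nonsurvivor

    def sample(self, rng: np.random.Generator, group: str) -> float:
        p = self.params(group)
        if self.family == "lognormal":
            value = float(rng.lognormal(mean=p.location, sigma=p.scale))
        else:
            value = float(rng.normal(loc=p.location, scale=p.scale))
        if self.floor is not None:
            value = max(value, self.floor)
        return max(value, 0.0)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "survivor": [self.survivor.location, self.survivor.scale],
            "nonsurvivor": [self.nonsurvivor.location, self.nonsurvivor.scale],
            "floor": self.floor,
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MarkerDistribution":
        return cls(
            family=data["family"],
            survivor=GroupParams(*data["survivor"]),
            nonsurvivor=GroupParams(*data["nonsurvivor"]),
            floor=data.get("floor"),
            unit=data.get("unit", ""),
        )


def _default_markers() -> dict[str, MarkerDistribution]:
    """Marker distributions calibrated to published survivor/non-survivor
    median (IQR) summaries of a sepsis-with-suspected-DIC cohort.

    WBC has no published per-group summary; a clinically plausible
    leukocytosis distribution is used (see docs/methods.md).
    """
    q = MarkerDistribution.from_quantiles
    return {
        # coagulation panel
        "platelet_count": q(
            "lognormal", (82.0, 35.7, 164.5), (55.0, 31.7, 93.2), unit="1e9/L"
        ),
        "pt_seconds": q(
            "lognormal", (16.2, 14.0, 19.5), (20.3, 14.8, 27.3), unit="s"
        ),
        "aptt_seconds": q(
            "lognormal", (35.0, 27.2, 46.1), (40.7, 30.0, 62.7), unit="s"
        ),
        "d_dimer": q(
            "lognormal", (6.0, 2.4, 14.3), (7.7, 3.7, 19.6), unit="ug/mL"
        ),
        "fdp": q(
            "lognormal", (5.0, 5.0, 16.2), (5.0, 5.0, 20.0), floor=5.0, unit="ug/mL"
        ),
        "fibrinogen_mg_dl": q(
            "lognormal", (258.0, 168.2, 454.5), (216.0, 131.7, 352.7), unit="mg/dL"
        ),
        # vitals
        "temperature": q(
            "normal", (36.1, 36.0, 37.0), (37.0, 36.0, 38.0), unit="degC"
        ),
        "heart_rate": q(
            "lognormal", (110.0, 94.0, 115.0), (113.0, 104.7, 123.0), unit="/min"
        ),
        "respiratory_rate": q(
            "lognormal", (26.0, 20.0, 26.0), (28.0, 26.0, 30.0), unit="/min"
        ),
        "map_mmhg": q(
            "normal", (65.5, 56.0, 72.7), (50.0, 45.0, 62.2), unit="mmHg"
        ),
        "lactate": q(
            "lognormal", (2.0, 1.0, 2.9), (5.0, 2.0, 13.2), unit="mmol/L"
        ),
        "wbc": q(
            "lognormal", (12.0, 8.0, 18.0), (15.0, 9.0, 22.0), unit="1e9/L"
        ),
    }


def _default_flag_probs() -> dict[str, tuple[float, float]]:
    """(survivor, non-survivor) probabilities for the clinical flags.

    Dialysis, ventilation and septic-shock rates follow published per-group
    percentages; the three JMHW clinical items have no published rates and
    use plausible defaults for a sepsis-with-suspected-DIC cohort.
    """
    return {
        "dialysis": (0.191, 0.390),
        "ventilated": (0.221, 0.481),
        "septic_shock": (0.809, 0.994),
        "underlying_disease": (0.60, 0.70),
        "bleeding": (0.10, 0.20),
        "organ_failure": (0.70, 0.90),
    }


def _default_sirs_pmf() -> dict[str, dict[int, float]]:
    """Per-group SIRS score distributions matching median (IQR) 3 (2-3) in
    survivors and 3 (3-4) in non-survivors."""
    return {
        "survivor": {1: 0.10, 2: 0.30, 3: 0.45, 4: 0.15},
        "nonsurvivor": {2: 0.15, 3: 0.55, 4: 0.30},
    }


def _default_day_weights() -> dict[int, float]:
    """Assessment-day mix: 44.3/33.3/13.1/4.2/3.4% on days 1-5; the ~1.7%
    remainder spread evenly over days 6, 8, 10 and 11."""
    base = {1: 0.443, 2: 0.333, 3: 0.131, 4: 0.042, 5: 0.034}
    remainder = 1.0 - sum(base.values())
    for day in (6, 8, 10, 11):
        base[day] = remainder / 4
    return base


@dataclass
class CohortSimConfig:
    """Generative parameters of the synthetic sepsis cohort.

    The defaults are the study conditions the generator emulates: n = 222,
    in-hospital mortality 69.4%, outcome-conditional marker distributions
    solved from published median/IQR summaries, and the published
    assessment-day mix.  ``sirs_mode`` selects whether the SIRS score is
    drawn from its per-group distribution (default, avoids
    double-specification against the generated vitals) or derived from the
    generated vitals.
    """

    n: int = 222
    mortality_rate: float = 0.694
    markers: dict[str, MarkerDistribution] = field(default_factory=_default_markers)
    flag_probs: dict[str, tuple[float, float]] = field(
        default_factory=_default_flag_probs
    )
    sirs_pmf: dict[str, dict[int, float]] = field(default_factory=_default_sirs_pmf)
    sofa_params: dict[str, GroupParams] = field(
        default_factory=lambda: {
            "survivor": GroupParams(8.0, (10.0 - 5.0) / (2 * _Z75)),
            "nonsurvivor": GroupParams(13.0, (15.0 - 11.7) / (2 * _Z75)),
        }
    )
    day_weights: dict[int, float] = field(default_factory=_default_day_weights)
    prior_platelet_rate: float = 0.30
    prior_drop_mean: float = 0.15
    prior_drop_sd: float = 0.20
    missingness: dict[str, float] = field(default_factory=dict)
    sirs_mode: str = "distribution"  # "distribution" | "derive"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be >= 0")
        if not (0.0 <= self.mortality_rate <= 1.0):
            raise ValidationError("mortality_rate must be in [0, 1]")
        for name, (p_s, p_n) in self.flag_probs.items():
            if not (0.0 <= p_s <= 1.0 and 0.0 <= p_n <= 1.0):
                raise ValidationError(f"flag probability out of [0, 1]: {name}")
        for group, pmf in self.sirs_pmf.items():
            total = sum(pmf.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"SIRS pmf for {group} sums to {total}, not 1")
        total = sum(self.day_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"day weights sum to {total}, not 1")
        if not (0.0 <= self.prior_platelet_rate <= 1.0):
            raise ValidationError("prior_platelet_rate must be in [0, 1]")
        for name, rate in self.missingness.items():
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(f"missingness rate out of [0, 1]: {name}")
        if self.sirs_mode not in ("distribution", "derive"):
            raise ValidationError(f"unknown sirs_mode {self.sirs_mode!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mortality_rate": self.mortality_rate,
            "markers": {k: v.to_dict() for k, v in self.markers.items()},
            "flag_probs": {k: list(v) for k, v in self.flag_probs.items()},
            "sirs_pmf": {
                g: {int(k): float(v) for k, v in pmf.items()}
                for g, pmf in self.sirs_pmf.items()
            },
            "sofa_params": {
                g: [p.location, p.scale] for g, p in self.sofa_params.items()
            },
            "day_weights": {int(k): float(v) for k, v in self.day_weights.items()},
            "prior_platelet_rate": self.prior_platelet_rate,
            "prior_drop_mean": self.prior_drop_mean,
            "prior_drop_sd": self.prior_drop_sd,
            "missingness": dict(self.missingness),
            "sirs_mode": self.sirs_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSimConfig":
        data = dict(data)
        return cls(
            n=int(data["n"]),
            mortality_rate=float(data["mortality_rate"]),
            markers={
                k: MarkerDistribution.from_dict(v) for k, v in data["markers"].items()
            },
            flag_probs={k: tuple(v) for k, v in data["flag_probs"].items()},
            sirs_pmf={
                g: {int(k): float(v) for k, v in pmf.items()}
                for g, pmf in data["sirs_pmf"].items()
            },
            sofa_params={
                g: GroupParams(*p) for g, p in data["sofa_params"].items()
            },
            day_weights={int(k): float(v) for k, v in data["day_weights"].items()},
            prior_platelet_rate=float(data["prior_platelet_rate"]),
            prior_drop_mean=float(data["prior_drop_mean"]),
            prior_drop_sd=float(data["prior_drop_sd"]),
            missingness=dict(data.get("missingness", {})),
            sirs_mode=data.get("sirs_mode", "distribution"),
            seed=data.get("seed"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSimConfig":
        return cls.from_dict(yaml.safe_load(text))


def default_config(**overrides) -> CohortSimConfig:
    """The default study-condition configuration (see class docstring)."""
    config = CohortSimConfig()
    for key, value in overrides.items():
        if not hasattr(config, key):
            raise ValidationError(f"unknown config field {key!r}")
        setattr(config, key, value)
    config.__post_init__()
    return config


def _sample_pmf(rng: np.random.Generator, pmf: Mapping[int, float]) -> int:
    keys = sorted(pmf)
    probs = np.array([pmf[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(keys, p=probs))


def simulate_cohort(
    config: Optional[CohortSimConfig] = None, seed: Optional[int] = None
) -> list[PatientRecord]:
    """Draw a synthetic cohort; identical (config, seed) gives an identical
    cohort.  ``seed`` overrides ``config.seed`` when given."""
    config = config or default_config()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValidationError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(int(seed))

    m = config.markers
    days = sorted(config.day_weights)
    day_probs = np.array([config.day_weights[d] for d in days], dtype=float)
    day_probs = day_probs / day_probs.sum()

    records: list[PatientRecord] = []
    for i in range(config.n):
        expired = bool(rng.random() < config.mortality_rate)
        group = "nonsurvivor" if expired else "survivor"

        platelet = m["platelet_count"].sample(rng, group)
        prior_platelet = None
        if rng.random() < config.prior_platelet_rate:
            drop = float(
                np.clip(
                    rng.normal(config.prior_drop_mean, config.prior_drop_sd),
                    -0.5,
                    0.85,
                )
            )
            prior_platelet = platelet / (1.0 - drop)

        panel = CoagulationPanel(
            platelet_count=platelet,
            platelet_prior_24h=prior_platelet,
            pt_seconds=m["pt_seconds"].sample(rng, group),
            aptt_seconds=m["aptt_seconds"].sample(rng, group),
            d_dimer=m["d_dimer"].sample(rng, group),
            fdp=m["fdp"].sample(rng, group),
            fibrinogen=m["fibrinogen_mg_dl"].sample(rng, group) / 100.0,
        )
        vitals = VitalSet(
            temperature=float(
                np.clip(m["temperature"].sample(rng, group), 25.0, 45.0)
            ),
            heart_rate=m["heart_rate"].sample(rng, group),
            respiratory_rate=m["respiratory_rate"].sample(rng, group),
            wbc=m["wbc"].sample(rng, group),
            map_mmhg=max(m["map_mmhg"].sample(rng, group), 10.0),
            lactate=m["lactate"].sample(rng, group),
        )
        flags = {
            name: bool(rng.random() < probs[1 if expired else 0])
            for name, probs in config.flag_probs.items()
        }
        if config.sirs_mode == "distribution":
            sirs = _sample_pmf(rng, config.sirs_pmf[group])
        else:
            from .scoring import compute_sirs

            sirs = compute_sirs(vitals)
        sofa_p = config.sofa_params[group]
        sofa = int(np.clip(round(rng.normal(sofa_p.location, sofa_p.scale)), 0, 24))
        day = int(rng.choice(days, p=day_probs))

        context = ClinicalContext(
            underlying_disease=flags["underlying_disease"],
            bleeding=flags["bleeding"],
            organ_failure=flags["organ_failure"],
            septic_shock=flags["septic_shock"],
            dialysis=flags["dialysis"],
            ventilated=flags["ventilated"],
            sofa_score=sofa,
            sirs_precomputed=sirs,
            assessment_day=day,
        )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                panel=panel,
                vitals=vitals,
                context=context,
                outcome=Outcome.EXPIRED if expired else Outcome.SURVIVED,
            )
        )

    if config.missingness:
        records = inject_missingness(records, config.missingness, seed=int(seed) + 1)
    return records


_MASKABLE_PANEL = (
    "platelet_count", "platelet_prior_24h", "pt_seconds", "aptt_seconds",
    "d_dimer", "fdp", "fibrinogen",
)
_MASKABLE_VITALS = (
    "temperature", "heart_rate", "respiratory_rate", "wbc", "map_mmhg", "lactate",
)


def inject_missingness(
    cohort: Iterable[PatientRecord],
    rates: Mapping[str, float],
    seed: int,
) -> list[PatientRecord]:
    """Mask fields independently at the given per-field rates (reproducible
    under ``seed``).  Field names refer to panel or vital-set attributes."""
    for name, rate in rates.items():
        if name not in _MASKABLE_PANEL and name not in _MASKABLE_VITALS:
            raise ValidationError(f"unknown maskable field {name!r}")
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"missingness rate out of [0, 1]: {name}")
    rng = np.random.default_rng(int(seed))
    masked: list[PatientRecord] = []
    for record in cohort:
        panel_kw = {f: getattr(record.panel, f) for f in _MASKABLE_PANEL}
        panel_kw["pt_reference_seconds"] = record.panel.pt_reference_seconds
        panel_kw["aptt_reference_seconds"] = record.panel.aptt_reference_seconds
        vitals_kw = {f: getattr(record.vitals, f) for f in _MASKABLE_VITALS}
        changed = False
        for name in sorted(rates):
            if rng.random() < rates[name]:
                if name in _MASKABLE_PANEL:
                    panel_kw[name] = None
                else:
                    vitals_kw[name] = None
                changed = True
        if changed:
            record = PatientRecord(
                patient_id=record.patient_id,
                panel=CoagulationPanel(**panel_kw),
                vitals=VitalSet(**vitals_kw),
                context=record.context,
                outcome=record.outcome,
                icd9_codes=record.icd9_codes,
                exclusion_flags=record.exclusion_flags,
            )
        else:
            record = copy.copy(record)
        masked.append(record)
    return masked
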