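"""ICD-9-CM sepsis screening and cohort eligibility filtering.

Two published administrative-code definitions of sepsis are supported, each
requiring at least one infection code AND at least one organ-dysfunction code:

* ``dombrovskiy`` — the Dombrovskiy code sets.
* ``modified_martin`` — the modified Martin code sets.

Code matching rules: codes are normalised (trimmed, upper-cased, decimal
point retained).  A printed range such as ``038.0-038.4`` expands over the
tenths digit.  Entries flagged "with all sub codes" match any code equal to
the entry or extending it past the decimal point (prefix match); all other
entries match exactly.
"""

from __future__ import annotations

from typing import Iterable

from .errors import ConfigurationError
from .types import PatientRecord

__all__ = ["sepsis_screen", "apply_eligibility", "SEPSIS_CODE_SETS"]


def _expand_range(start: str, stop: str) -> list[str]:
    """Expand an ICD-9 tenths-digit range, e.g. 038.0-038.4 or 287.3-287.5."""
    stem_a, _, frac_a = start.partition(".")
    stem_b, _, frac_b = stop.partition(".")
    if stem_a != stem_b or len(frac_a) != 1 or len(frac_b) != 1:
        raise ConfigurationError(f"cannot expand code range {start}-{stop}")
    return [f"{stem_a}.{d}" for d in range(int(frac_a), int(frac_b) + 1)]


def _codeset(exact: Iterable[str], ranges: Iterable[tuple[str, str]] = (),
             prefixes: Iterable[str] = ()) -> tuple[frozenset[str], tuple[str, ...]]:
    codes = set(exact)
    for a, b in ranges:
        codes.update(_expand_range(a, b))
    return frozenset(codes), tuple(prefixes)


# Dombrovskiy definition.
_DOMBROVSKIY_INFECTION = _codeset(
    exact=[
        "003.1", "020.2", "022.3", "036.2", "036.3", "038.8", "038.9",
        "054.5", "098.89", "112.5", "785.52", "995.91", "995.92",
    ],
    ranges=[("038.0", "038.4")],
)
_DOMBROVSKIY_ORGAN = _codeset(
    exact=[
        "286.6", "286.9", "287.5", "293.0", "297.4", "348.1", "348.3",
        "427.5", "458.0", "458.8", "458.9", "518.81", "518.82", "570",
        "572.2", "573.4", "584", "780.01", "785.5", "786.09", "799.1",
        "796.3",
    ],
)

# Modified Martin criteria.
_MARTIN_INFECTION = _codeset(
    exact=[
        "038.8", "038.9", "003.1", "020.2", "036.2", "036.3", "054.5",
        "098.89", "112.5", "112.81", "117.9", "790.7", "995.91",
    ],
    ranges=[("038.0", "038.4")],
)
_MARTIN_ORGAN = _codeset(
    exact=[
        "518.81", "518.82", "518.84", "518.85", "786.09", "799.1", "458",
        "580", "570", "572.2", "573.3", "286.6", "286.9", "293", "348.1",
        "348.3", "357.82", "780.01", "780.09", "276.2",
    ],
    ranges=[("287.3", "287.5")],
    prefixes=["785.5", "584"],  # listed "with all sub codes"
)

SEPSIS_CODE_SETS: dict[str, dict[str, tuple[frozenset[str], tuple[str, ...]]]] = {
    "dombrovskiy": {
        "infection": _DOMBROVSKIY_INFECTION,
        "organ_dysfunction": _DOMBROVSKIY_ORGAN,
    },
    "modified_martin": {
        "infection": _MARTIN_INFECTION,
        "organ_dysfunction": _MARTIN_ORGAN,
    },
}


def _normalize(code: str) -> str:
    return code.strip().upper()


def _matches(code: str, codeset: tuple[frozenset[str], tuple[str, ...]]) -> bool:
    exact, prefixes = codeset
    if code in exact:
        return True
    for prefix in prefixes:
        if code == prefix or code.startswith(prefix + "."):
            return True
    return False


def sepsis_screen(icd9_codes: Iterable[str], definition: str = "dombrovskiy") -> bool:
    """True iff the code list satisfies the selected sepsis definition.

    Requires at least one infection code and at least one organ-dysfunction
    code from the definition's printed lists.
    """
    if definition not in SEPSIS_CODE_SETS:
        raise ConfigurationError(
            f"unknown sepsis definition {definition!r}; "
            f"expected one of {sorted(SEPSIS_CODE_SETS)}"
        )
    sets = SEPSIS_CODE_SETS[definition]
    codes = [_normalize(c) for c in icd9_codes if c and c.strip()]
    has_infection = any(_matches(c, sets["infection"]) for c in codes)
    has_organ = any(_matches(c, sets["organ_dysfunction"]) for c in codes)
    return has_infection and has_organ


def apply_eligibility(
    cohort: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], list[tuple[PatientRecord, list[str]]]]:
    """Partition a cohort into (included, excluded-with-reasons).

    A record is excluded when it carries any exclusion flag (hematologic
    disease, underlying bleeding disorder, anticoagulation/chemotherapy,
    Child-Pugh grade C cirrhosis); the triggering flags are returned with it.
    Records with no flag information are included.
    """
    included: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, list[str]]] = []
    for record in cohort:
        if record.exclusion_flags:
            reasons = sorted(f.value for f in record.exclusion_flags)
            excluded.append((record, reasons))
        else:
            included.append(record)
    return included, excluded
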