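"""The ten chronic conditions under study and their six-group rollup.

The cohort tracks ten predefined chronic conditions: cancer, cardiovascular
disease (CVD), hypertension, dyslipidemia, diabetes, asthma, mental disorders,
neurodegenerative disorders, hip replacement, and osteoarthritis.  For pattern
analysis they roll up into six groups: the four cardiometabolic disorders
(CMDs: CVD, diabetes, hypertension, dyslipidemia) form one group, hip
replacement and osteoarthritis form the musculoskeletal group, and each
remaining condition is its own group.

The enum declaration order is the canonical ordering used everywhere for
tie-breaking and output sorting.
"""

from __future__ import annotations

import enum
from typing import Iterable, Sequence


class Condition(str, enum.Enum):
    """One of the ten chronic conditions, in canonical order."""

    CANCER = "CANCER"
    CVD = "CVD"
    HYPERTENSION = "HYPERTENSION"
    DYSLIPIDEMIA = "DYSLIPIDEMIA"
    DIABETES = "DIABETES"
    ASTHMA = "ASTHMA"
    MENTAL = "MENTAL"
    NEURODEGEN = "NEURODEGEN"
    HIP_REPLACEMENT = "HIP_REPLACEMENT"
    OSTEOARTHRITIS = "OSTEOARTHRITIS"


class Group(str, enum.Enum):
    """Six-group rollup of the ten conditions, in canonical order."""

    CMD = "CMD"
    CANCER = "CANCER"
    ASTHMA = "ASTHMA"
    MENTAL = "MENTAL"
    NEURODEGEN = "NEURODEGEN"
    MUSCULOSKELETAL = "MUSCULOSKELETAL"


CONDITIONS: tuple[Condition, ...] = tuple(Condition)
GROUPS: tuple[Group, ...] = tuple(Group)

CONDITION_INDEX: dict[str, int] = {c.value: i for i, c in enumerate(CONDITIONS)}
GROUP_INDEX: dict[str, int] = {g.value: i for i, g in enumerate(GROUPS)}

CONDITION_TO_GROUP: dict[Condition, Group] = {
    Condition.CANCER: Group.CANCER,
    Condition.CVD: Group.CMD,
    Condition.HYPERTENSION: Group.CMD,
    Condition.DYSLIPIDEMIA: Group.CMD,
    Condition.DIABETES: Group.CMD,
    Condition.ASTHMA: Group.ASTHMA,
    Condition.MENTAL: Group.MENTAL,
    Condition.NEURODEGEN: Group.NEURODEGEN,
    Condition.HIP_REPLACEMENT: Group.MUSCULOSKELETAL,
    Condition.OSTEOARTHRITIS: Group.MUSCULOSKELETAL,
}

# string -> string view of the rollup, convenient for DataFrame .map()
CONDITION_TO_GROUP_NAME: dict[str, str] = {
    c.value: g.value for c, g in CONDITION_TO_GROUP.items()
}


def as_condition(code: str | Condition) -> Condition:
    """Coerce a string code to a :class:`Condition`, raising on unknown codes."""
    if isinstance(code, Condition):
        return code
    try:
        return Condition(code)
    except ValueError as exc:
        raise ValueError(f"unknown condition code: {code!r}") from exc


def to_group(condition: str | Condition) -> Group:
    """Map a condition to its group."""
    return CONDITION_TO_GROUP[as_condition(condition)]


def canonical_sort(codes: Iterable[str], level: str = "condition") -> tuple[str, ...]:
    """Sort code strings by the canonical condition or group ordering."""
    index = CONDITION_INDEX if level == "condition" else GROUP_INDEX
    return tuple(sorted(codes, key=index.__getitem__))


def canonical_key(codes: Sequence[str], level: str = "condition") -> tuple[int, ...]:
    """Integer sort key for a code tuple under the canonical ordering."""
    index = CONDITION_INDEX if level == "condition" else GROUP_INDEX
    return tuple(index[c] for c in codes)
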