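"""Health-state taxonomy and age-band definitions.

The model classifies an elderly person into one of five ordered states:
four living states graded by ADL disability (healthy, mild, moderate,
severe) and an absorbing death state. Transition matrices, panels and
population tables are stratified by five-year age bands from 65-69 up to
the open band 85+.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = [
    "HealthState",
    "LIVING_STATES",
    "STATE_LABELS",
    "LIVING_LABELS",
    "AgeGroup",
    "AGE_LABELS",
    "default_age_groups",
    "group_index_for_age",
]


class HealthState(enum.IntEnum):
    """Five-level health status; ``DEATH`` is absorbing."""

    HEALTHY = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4
    DEATH = 5

    @property
    def index(self) -> int:
        """Zero-based position used for array indexing."""
        return int(self) - 1

    @property
    def is_living(self) -> bool:
        return self is not HealthState.DEATH

    @classmethod
    def from_label(cls, label: str) -> "HealthState":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ConfigurationError(f"unknown health state label {label!r}") from None


LIVING_STATES: tuple[HealthState, ...] = tuple(s for s in HealthState if s.is_living)
STATE_LABELS: tuple[str, ...] = tuple(s.name for s in HealthState)
LIVING_LABELS: tuple[str, ...] = tuple(s.name for s in LIVING_STATES)


@dataclass(frozen=True)
class AgeGroup:
    """A five-year age band; ``upper`` is ``None`` for the open 85+ band.

    ``midpoint`` is the representative age used when a cohort is advanced
    through time and must be matched back to a band.
    """

    label: str
    lower: int
    upper: int | None
    midpoint: float

    def contains(self, age: float) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age <= self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


AGE_LABELS: tuple[str, ...] = ("65-69", "70-74", "75-79", "80-84", "85+")

#: Alternate spellings accepted when parsing age-band labels from files.
_AGE_ALIASES = {
    "≥85": "85+",  # ≥85
    ">=85": "85+",
    "85+": "85+",
}


def normalize_age_label(label: str) -> str:
    lab = str(label).strip()
    lab = _AGE_ALIASES.get(lab, lab)
    if lab not in AGE_LABELS:
        raise ConfigurationError(f"unknown age group label {label!r}")
    return lab


def default_age_groups(open_band_midpoint: float = 87.0) -> tuple[AgeGroup, ...]:
    """The five study bands. The open 85+ band needs one representative
    age for cohort aging; 87 is the default and it is configurable."""
    return (
        AgeGroup("65-69", 65, 69, 67.0),
        AgeGroup("70-74", 70, 74, 72.0),
        AgeGroup("75-79", 75, 79, 77.0),
        AgeGroup("80-84", 80, 84, 82.0),
        AgeGroup("85+", 85, None, float(open_band_midpoint)),
    )


def group_index_for_age(age: float, groups: tuple[AgeGroup, ...]) -> int:
    """Index of the band containing ``age``; ages past the last closed band
    fall into the open band. Ages below the youngest band are an error."""
    if age < groups[0].lower:
        raise ConfigurationError(
            f"age {age} is below the youngest band ({groups[0].label})"
        )
    for i, g in enumerate(groups):
        if g.contains(age):
            return i
    return len(groups) - 1
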