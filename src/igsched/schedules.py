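"""Image-guidance schedules as per-fraction imaging masks.

Six named schedules over a course of ``n_fractions`` delivered
``fractions_per_week`` per week:

========  =============================================  F (25 fx, 5/wk)
NIG       first fraction only                            1
WIG       first fraction of each week                    5
TIG       fractions {1, 4} of each week                  10
THRIG     fractions {1, 3, 5} of each week               15
3D+WIG    fractions 1-3, then first of each later week   7
DIG       every fraction                                 25
========  =============================================  F (25 fx, 5/wk)

Every schedule images at fraction 1 (positioning verification is mandatory
there regardless of schedule).  Weeks are consecutive blocks of
``fractions_per_week`` fractions; a trailing partial week uses the same
within-week pattern.  On imaged fractions the post-correction dose is
delivered; otherwise the pre-correction dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import FractionDose
from .dvh import accumulate
from .grid import DoseGrid

SCHEDULE_NAMES = ("NIG", "WIG", "TIG", "THRIG", "3D+WIG", "DIG")

# within-week imaged day indices (0-based); None marks the daily schedule
_WEEK_PATTERNS: dict[str, tuple[int, ...] | None] = {
    "NIG": (),
    "WIG": (0,),
    "TIG": (0, 3),
    "THRIG": (0, 2, 4),
    "DIG": None,
}


@dataclass(frozen=True)
class IGSchedule:
    """A named boolean imaging mask over the fractions of a course."""

    name: str
    mask: np.ndarray  # bool, length n_fractions, 0-based index = fraction-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if self.mask.ndim != 1 or self.mask.size < 1:
            raise ValueError("schedule mask must be a nonempty 1-D boolean array")
        if not self.mask[0]:
            raise ValueError("every schedule images at fraction 1")

    @property
    def n_fractions(self) -> int:
        return self.mask.size

    @property
    def frequency(self) -> int:
        """Number of imaged fractions F (drives imaging dose and cost)."""
        return int(self.mask.sum())

    @classmethod
    def from_mask(cls, name: str, mask: Sequence[bool]) -> "IGSchedule":
        """Escape hatch for custom imaging policies given as explicit masks."""
        mask = np.asarray(mask, dtype=bool).copy()
        mask[0] = True
        return cls(name, mask)


def build_schedule(
    name: str, n_fractions: int = 25, fractions_per_week: int = 5
) -> IGSchedule:
    """Build one of the six named schedules."""
    key = name.upper().replace(" ", "")
    if key == "3D+WIG":
        mask = np.zeros(n_fractions, dtype=bool)
        mask[: min(3, n_fractions)] = True
        for start in range(fractions_per_week, n_fractions, fractions_per_week):
            mask[start] = True
    elif key in _WEEK_PATTERNS:
        pattern = _WEEK_PATTERNS[key]
        if pattern is None:
            mask = np.ones(n_fractions, dtype=bool)
        else:
            mask = np.zeros(n_fractions, dtype=bool)
            days = [d for d in pattern if d < fractions_per_week]
            for start in range(0, n_fractions, fractions_per_week):
                for d in days:
                    if start + d < n_fractions:
                        mask[start + d] = True
    else:
        raise ValueError(
            f"unknown schedule '{name}'; valid names: {', '.join(SCHEDULE_NAMES)}"
        )
    mask[0] = True
    return IGSchedule("3D+WIG" if key == "3D+WIG" else key, mask)


def default_schedules(
    n_fractions: int = 25, fractions_per_week: int = 5
) -> list[IGSchedule]:
    return [build_schedule(n, n_fractions, fractions_per_week) for n in SCHEDULE_NAMES]


def frequency(schedule: IGSchedule) -> int:
    """Imaging frequency F of a schedule (count of imaged fractions)."""
    return schedule.frequency


def select_and_accumulate(
    fractions: Sequence[FractionDose], schedule: IGSchedule
) -> DoseGrid:
    """Accumulate a course under a schedule.

    For each fraction the post-correction dose is used where imaging (and
    couch correction) was scheduled, the pre-correction dose otherwise.
    """
    if len(fractions) != schedule.n_fractions:
        raise ValueError(
            f"schedule '{schedule.name}' covers {schedule.n_fractions} fractions "
            f"but {len(fractions)} were supplied"
        )
    picked = [
        fx.dose_post if imaged else fx.dose_pre
        for fx, imaged in zip(fractions, schedule.mask)
    ]
    return accumulate(picked)
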