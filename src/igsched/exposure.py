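"""Cumulative imaging dose and direct imaging-related cost per schedule.

Both quantities are linear in the imaging frequency F of a schedule:

    D_cum   = D_single x F      (per organ, mGy)
    C_total = C_single x F      (currency units)

Per-scan organ doses are treated as constants from published Monte-Carlo
tables for the CBCT system (no patient-size scaling); the heart has no
tabulated per-scan dose, so no heart imaging dose is reported.  Scanner
presets (kV, collimator, filter, mAs, rotation) are carried as metadata only
and never entered into the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .schedules import IGSchedule


def _default_organ_doses() -> dict[str, float]:
    return {"lung_ipsi": 2.85, "breast_contra": 1.26}


def _default_scan_metadata() -> dict:
    return {"kV": 120, "collimator": "S20", "filter": "F1",
            "total_mAs": 117.1, "rotation": "half"}


@dataclass
class ExposureTable:
    """Per-scan organ doses (mGy) and the single-scan fee."""

    organ_dose_mgy: dict[str, float] = field(default_factory=_default_organ_doses)
    single_cost: float = 288.0
    currency: str = "CNY"
    scan_metadata: dict = field(default_factory=_default_scan_metadata)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.organ_dose_mgy.values()) or self.single_cost < 0:
            raise ValueError("per-scan doses and cost must be >= 0")


def cumulative_imaging_dose(d_single: float, f: int) -> float:
    """Cumulative organ imaging dose over a course: D_single x F (mGy)."""
    if d_single < 0 or f < 0:
        raise ValueError("dose and frequency must be >= 0")
    return d_single * f


def total_cost(c_single: float, f: int) -> float:
    """Total direct imaging-related cost over a course: C_single x F."""
    if c_single < 0 or f < 0:
        raise ValueError("cost and frequency must be >= 0")
    return c_single * f


def exposure_report(
    schedules: Sequence[IGSchedule],
    table: ExposureTable | None = None,
    reference_name: str = "DIG",
) -> pd.DataFrame:
    """Per-schedule imaging dose, cost, and percent-of-reference.

    One row per schedule with columns ``schedule``, ``F``,
    ``dose_<organ>_mgy`` per tabulated organ, ``cost_<currency>``, and
    ``pct_of_reference`` (identical for dose and cost since both are linear
    in F; per-scan constants cancel in the ratio).
    """
    table = table or ExposureTable()
    names = [s.name for s in schedules]
    if reference_name not in names:
        raise ValueError(
            f"reference schedule '{reference_name}' not among {names}"
        )
    f_ref = schedules[names.index(reference_name)].frequency
    rows = []
    for s in schedules:
        row: dict = {"schedule": s.name, "F": s.frequency}
        for organ, d1 in table.organ_dose_mgy.items():
            row[f"dose_{organ}_mgy"] = cumulative_imaging_dose(d1, s.frequency)
        row[f"cost_{table.currency}"] = total_cost(table.single_cost, s.frequency)
        row["pct_of_reference"] = 100.0 * s.frequency / f_ref
        rows.append(row)
    return pd.DataFrame(rows)
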