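"""Time-and-motion analysis of observed PrEP clinic visits.

Observers record start/end clock times for each activity of a visit
(counselling + HIV testing, clinical examination, laboratory testing, PrEP
dispensing) along with periods of client inactivity (waiting).  This module
turns such logs into per-activity duration summaries, per-visit provider-time
totals, annual projections, and wage-weighted personnel costs per visit.

Waiting time is reported but always excluded from provider-time totals and
from personnel costs (payer perspective: only staffed contact time is
valued).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, time
from decimal import ROUND_HALF_UP, Decimal
from numbers import Real
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ledger import Arm, Cadre, CadreSalary, EconomicParams, MoneyAmount

__all__ = [
    "Activity",
    "VisitType",
    "ACTIVITY_CADRE",
    "ActivityObservation",
    "read_observations",
    "write_observations",
    "activity_durations",
    "visit_totals",
    "summarize",
    "project_annual",
    "personnel_cost_per_visit",
    "round_minutes",
]


class Activity(str, enum.Enum):
    counselling_hiv_testing = "counselling_hiv_testing"
    clinical_examination = "clinical_examination"
    laboratory_testing = "laboratory_testing"
    prep_dispensing = "prep_dispensing"
    waiting = "waiting"


class VisitType(str, enum.Enum):
    enrollment = "enrollment"
    refill = "refill"


#: Which cadre performs each activity (lab time excludes the lab technician;
#: specimen collection at the visit is nurse work).
ACTIVITY_CADRE: dict[Activity, Optional[Cadre]] = {
    Activity.counselling_hiv_testing: Cadre.hiv_testing_counsellor,
    Activity.clinical_examination: Cadre.clinical_officer,
    Activity.laboratory_testing: Cadre.nurse,
    Activity.prep_dispensing: Cadre.pharmacy_technologist,
    Activity.waiting: None,
}

PROVIDER_ACTIVITIES: tuple[Activity, ...] = tuple(a for a in Activity if a is not Activity.waiting)


@dataclass(frozen=True)
class ActivityObservation:
    """One timed activity within an observed clinic visit."""

    visit_id: str
    arm: Arm
    visit_type: VisitType
    activity: Activity
    start: datetime
    end: datetime
    cadre: Optional[Cadre] = None

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"visit {self.visit_id}: end time precedes start time")
        if self.activity is Activity.waiting and self.cadre is not None:
            raise ValueError(f"visit {self.visit_id}: waiting carries no cadre")

    @property
    def minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def round_minutes(x: float) -> int:
    """Display rounding of durations to the nearest whole minute (half-up)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _parse_clock(value, visit_id: str) -> datetime:
    if isinstance(value, datetime):
        return value
    if isinstance(value, time):
        return datetime.combine(date(2019, 7, 1), value)
    ts = pd.to_datetime(str(value), errors="coerce")
    if pd.isna(ts):
        raise ValueError(f"visit {visit_id}: unparseable time {value!r}")
    return ts.to_pydatetime()


def read_observations(path: Union[str, Path]) -> list[ActivityObservation]:
    """Read an observation log CSV.

    Expected columns (header case-insensitive, quoted fields fine):
    visit_id, arm, visit_type, activity, cadre, start_time, end_time with
    ISO-8601 clock times.  An empty cadre field is only valid for waiting.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"visit_id", "arm", "visit_type", "activity", "start_time", "end_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    obs = []
    for row in df.itertuples(index=False):
        cadre_raw = getattr(row, "cadre", None)
        cadre = None
        if isinstance(cadre_raw, str) and cadre_raw.strip():
            cadre = Cadre(cadre_raw.strip())
        obs.append(
            ActivityObservation(
                visit_id=str(row.visit_id),
                arm=Arm(row.arm.strip()),
                visit_type=VisitType(row.visit_type.strip()),
                activity=Activity(row.activity.strip()),
                cadre=cadre,
                start=_parse_clock(row.start_time, str(row.visit_id)),
                end=_parse_clock(row.end_time, str(row.visit_id)),
            )
        )
    return obs


def write_observations(obs: Iterable[ActivityObservation], path: Union[str, Path]) -> None:
    rows = [
        {
            "visit_id": o.visit_id,
            "arm": o.arm.value,
            "visit_type": o.visit_type.value,
            "activity": o.activity.value,
            "cadre": o.cadre.value if o.cadre else "",
            "start_time": o.start.isoformat(),
            "end_time": o.end.isoformat(),
        }
        for o in obs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def activity_durations(log: Sequence[ActivityObservation]) -> pd.DataFrame:
    """Per-observation durations in (fractional) minutes.

    Returns a frame with columns visit_id, arm, visit_type, activity, cadre,
    minutes.  End-before-start is rejected at construction time; overlapping
    same-provider activities within a visit are rejected here.
    """
    rows = []
    for o in log:
        rows.append(
            {
                "visit_id": o.visit_id,
                "arm": o.arm.value,
                "visit_type": o.visit_type.value,
                "activity": o.activity.value,
                "cadre": o.cadre.value if o.cadre else None,
                "start": o.start,
                "end": o.end,
                "minutes": o.minutes,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["visit_id", "arm", "visit_type", "activity", "cadre", "minutes"]
        )
    for (visit, cadre), grp in df[df.cadre.notna()].groupby(["visit_id", "cadre"]):
        grp = grp.sort_values("start")
        prev_end = None
        for row in grp.itertuples(index=False):
            if prev_end is not None and row.start < prev_end:
                raise ValueError(f"visit {visit}: overlapping activities for cadre {cadre}")
            prev_end = row.end
    return df.drop(columns=["start", "end"])


def visit_totals(durations: pd.DataFrame) -> pd.DataFrame:
    """Per-visit provider-time totals in minutes (waiting excluded)."""
    if durations.empty:
        return pd.DataFrame(columns=["visit_id", "arm", "visit_type", "minutes"])
    keys = ["visit_id", "arm", "visit_type"]
    provider = durations[durations.activity != Activity.waiting.value]
    base = durations[keys].drop_duplicates()  # visits with only waiting still total 0
    sums = provider.groupby(keys, as_index=False)["minutes"].sum()
    return base.merge(sums, on=keys, how="left").fillna({"minutes": 0.0})


def summarize(
    log: Sequence[ActivityObservation],
    by: str = "arm",
    visit_type: Optional[VisitType] = None,
) -> pd.DataFrame:
    """Distributional summary of activity and per-visit total durations.

    Parameters
    ----------
    by : {"arm", "all"}
        Stratify by study arm or pool everything (used for enrollment visits,
        which follow the same procedure in both arms and are pooled).
    visit_type : optional
        Restrict to one visit type before summarizing.

    Returns one row per (stratum, activity) plus a ``total`` row per stratum
    with columns n, median, q1, q3, mean, sd (minutes, unrounded; use
    :func:`round_minutes` for display).  Quartiles use linear interpolation
    between order statistics; sd is the n-1 sample standard deviation (NaN
    for n < 2).
    """
    durations = activity_durations(log)
    if visit_type is not None:
        durations = durations[durations.visit_type == visit_type.value]
    if durations.empty:
        raise ValueError("no observations in the requested stratum")
    if by not in ("arm", "all"):
        raise ValueError(f"unknown stratum {by!r}")
    durations = durations.copy()
    durations["stratum"] = durations["arm"] if by == "arm" else "all"

    def _stats(values: np.ndarray) -> dict:
        return {
            "n": int(values.size),
            "median": float(np.median(values)),
            "q1": float(np.percentile(values, 25)),
            "q3": float(np.percentile(values, 75)),
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if values.size >= 2 else float("nan"),
        }

    rows = []
    for stratum, grp in durations.groupby("stratum"):
        provider = grp[grp.activity != Activity.waiting.value]
        for activity in Activity:
            vals = grp.loc[grp.activity == activity.value, "minutes"].to_numpy()
            if vals.size:
                rows.append({"stratum": stratum, "activity": activity.value, **_stats(vals)})
        totals = provider.groupby("visit_id")["minutes"].sum().to_numpy()
        if totals.size:
            rows.append({"stratum": stratum, "activity": "total", **_stats(totals)})
    return pd.DataFrame(rows)


def project_annual(per_visit_mean: float, visits_per_client_year: int) -> float:
    """Annual provider minutes per client: per-visit mean x annual visit count.

    The refill multiplier (4 for quarterly, 2 for semi-annual dispensing) is
    applied to the all-visit-types mean.  Linear in both arguments, so
    per-activity projections computed from unrounded means sum to the
    projected total.
    """
    if visits_per_client_year <= 0:
        raise ValueError("visits_per_client_year must be positive")
    if per_visit_mean < 0:
        raise ValueError("per_visit_mean must be non-negative")
    return per_visit_mean * visits_per_client_year


def personnel_cost_per_visit(
    durations: Mapping[Union[Activity, str], Real],
    salaries: Union[Sequence[CadreSalary], Mapping[Cadre, CadreSalary]],
    params: EconomicParams,
) -> MoneyAmount:
    """Wage-weighted provider cost of one visit.

    Sum over activities of (minutes / 60) x (cadre annual salary /
    annual work hours).  Waiting contributes nothing; any other activity
    without a salaried cadre is an error.
    """
    if not isinstance(salaries, Mapping):
        salaries = {s.cadre: s for s in salaries}
    total = Decimal(0)
    for activity, minutes in durations.items():
        activity = Activity(activity)
        if activity is Activity.waiting:
            continue
        cadre = ACTIVITY_CADRE[activity]
        if cadre not in salaries:
            raise KeyError(f"no salary available for cadre {cadre.value!r}")
        hourly = salaries[cadre].annual_salary.value / params.annual_work_hours
        total += Decimal(repr(float(minutes))) / Decimal(60) * hourly
    return MoneyAmount(value=total)
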