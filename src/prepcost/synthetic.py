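"""Synthetic study-data generator.

Generates observation logs, ledgers, and accruals with the statistical
structure the costing analysis assumes, so every pipeline stage is testable
without any external data.  Defaults emulate the study conditions: 22
time-and-motion observations (9 standard-of-care, 13 intervention, six of
them enrollment visits), per-activity visit durations with the published
means/SDs, and annual accruals of 304 visits / 913 client-months (SOC) and
340 visits / 2,039 client-months (intervention).

All randomness flows through an explicit integer seed (NumPy PCG64); the
same seed reproduces the same outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import Decimal
from typing import Literal, Mapping, Optional

import numpy as np

from . import fixtures
from .ledger import (
    Arm,
    ArmAccrual,
    CadreSalary,
    CostItem,
    Ledger,
    MoneyAmount,
    UnitPrice,
)
from .timemotion import (
    ACTIVITY_CADRE,
    Activity,
    ActivityObservation,
    PROVIDER_ACTIVITIES,
    VisitType,
)

__all__ = [
    "SynthConfig",
    "DEFAULT_REFILL_MEANS",
    "DEFAULT_REFILL_SDS",
    "DEFAULT_ENROLLMENT_MEANS",
    "generate_observation_log",
    "generate_accruals",
    "generate_ledger",
]

#: Mean per-activity refill-visit durations (minutes) by arm, study defaults.
DEFAULT_REFILL_MEANS: dict[Arm, dict[Activity, float]] = {
    Arm.soc: {
        Activity.counselling_hiv_testing: 27.0,
        Activity.clinical_examination: 17.0,
        Activity.laboratory_testing: 3.0,
        Activity.prep_dispensing: 7.0,
    },
    Arm.intervention: {
        Activity.counselling_hiv_testing: 32.0,
        Activity.clinical_examination: 18.0,
        Activity.laboratory_testing: 5.0,
        Activity.prep_dispensing: 21.0,
    },
}

DEFAULT_REFILL_SDS: dict[Arm, dict[Activity, float]] = {
    Arm.soc: {
        Activity.counselling_hiv_testing: 3.0,
        Activity.clinical_examination: 4.0,
        Activity.laboratory_testing: 1.0,
        Activity.prep_dispensing: 2.0,
    },
    Arm.intervention: {
        Activity.counselling_hiv_testing: 3.0,
        Activity.clinical_examination: 4.0,
        Activity.laboratory_testing: 2.0,
        Activity.prep_dispensing: 6.0,
    },
}

#: Enrollment procedures are identical in both arms, so one pooled mean set
#: (published medians used as means; IQR-scale spreads).
DEFAULT_ENROLLMENT_MEANS: dict[Activity, float] = {
    Activity.counselling_hiv_testing: 33.0,
    Activity.clinical_examination: 20.0,
    Activity.laboratory_testing: 5.0,
    Activity.prep_dispensing: 21.0,
}
DEFAULT_ENROLLMENT_SDS: dict[Activity, float] = {
    Activity.counselling_hiv_testing: 4.0,
    Activity.clinical_examination: 8.0,
    Activity.laboratory_testing: 2.0,
    Activity.prep_dispensing: 10.0,
}

#: Client waiting per visit (reported separately, never costed); not published,
#: set to a realistic clinic value.
WAITING_MEAN, WAITING_SD = 15.0, 5.0


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for the synthetic generators (seed is mandatory)."""

    seed: int
    n_visits_per_arm: Mapping[Arm, int] = field(
        default_factory=lambda: {Arm.soc: 9, Arm.intervention: 13}
    )
    n_enrollment_per_arm: Mapping[Arm, int] = field(
        default_factory=lambda: {Arm.soc: 1, Arm.intervention: 5}
    )
    activity_means: Mapping[Arm, Mapping[Activity, float]] = field(
        default_factory=lambda: DEFAULT_REFILL_MEANS
    )
    activity_sds: Mapping[Arm, Mapping[Activity, float]] = field(
        default_factory=lambda: DEFAULT_REFILL_SDS
    )
    enrollment_means: Mapping[Activity, float] = field(
        default_factory=lambda: DEFAULT_ENROLLMENT_MEANS
    )
    enrollment_sds: Mapping[Activity, float] = field(
        default_factory=lambda: DEFAULT_ENROLLMENT_SDS
    )
    duration_distribution: Literal["normal_truncated_at_zero", "lognormal"] = (
        "normal_truncated_at_zero"
    )
    include_waiting: bool = True
    ledger_template: str = "trial"

    def __post_init__(self):
        if self.duration_distribution not in ("normal_truncated_at_zero", "lognormal"):
            raise ValueError(f"unknown distribution {self.duration_distribution!r}")
        for arm, means in self.activity_means.items():
            for act, m in means.items():
                if m <= 0:
                    raise ValueError(f"mean for {arm}/{act} must be positive")
                if self.activity_sds[arm][act] < 0:
                    raise ValueError(f"sd for {arm}/{act} must be non-negative")


def _draw_duration(rng: np.random.Generator, mean: float, sd: float, law: str) -> float:
    """One duration in minutes; strictly non-negative, equal to mean at sd=0."""
    if sd == 0:
        return float(mean)
    if law == "lognormal":
        # moment-matched lognormal
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        return float(rng.lognormal(mu, np.sqrt(sigma2)))
    x = rng.normal(mean, sd)
    while x < 0:  # truncate by resampling
        x = rng.normal(mean, sd)
    return float(x)


def generate_observation_log(config: SynthConfig) -> list[ActivityObservation]:
    """Simulate a time-and-motion observation log.

    Each visit is a sequential, non-overlapping block of activities
    (counselling, examination, laboratory, dispensing) with an initial
    waiting period, starting from a morning clock time.  Durations follow
    the configured law; the same seed yields an identical log.
    """
    rng = np.random.default_rng(config.seed)
    log: list[ActivityObservation] = []
    for arm in (Arm.soc, Arm.intervention):
        n_total = config.n_visits_per_arm.get(arm, 0)
        n_enrol = min(config.n_enrollment_per_arm.get(arm, 0), n_total)
        for k in range(n_total):
            visit_type = VisitType.enrollment if k < n_enrol else VisitType.refill
            visit_id = f"{arm.value}-{k + 1:03d}"
            clock = datetime(2019, 7, 1, 9, 0) + timedelta(minutes=int(rng.integers(0, 180)))
            if config.include_waiting:
                wait = _draw_duration(rng, WAITING_MEAN, WAITING_SD, "normal_truncated_at_zero")
                log.append(
                    ActivityObservation(
                        visit_id=visit_id,
                        arm=arm,
                        visit_type=visit_type,
                        activity=Activity.waiting,
                        start=clock,
                        end=clock + timedelta(minutes=wait),
                    )
                )
                clock += timedelta(minutes=wait)
            for activity in PROVIDER_ACTIVITIES:
                if visit_type is VisitType.enrollment:
                    mean = config.enrollment_means[activity]
                    sd = config.enrollment_sds[activity]
                else:
                    mean = config.activity_means[arm][activity]
                    sd = config.activity_sds[arm][activity]
                minutes = _draw_duration(rng, mean, sd, config.duration_distribution)
                log.append(
                    ActivityObservation(
                        visit_id=visit_id,
                        arm=arm,
                        visit_type=visit_type,
                        activity=activity,
                        cadre=ACTIVITY_CADRE[activity],
                        start=clock,
                        end=clock + timedelta(minutes=minutes),
                    )
                )
                clock += timedelta(minutes=minutes)
    return log


def generate_accruals(
    visits_per_arm: Optional[Mapping[Arm, int]] = None,
    bottles_per_visit: Optional[Mapping[Arm, int]] = None,
) -> dict[Arm, ArmAccrual]:
    """Per-arm annual accruals.

    With no arguments, returns the study accruals exactly (304 visits /
    913 client-months SOC; 340 / 2,039 intervention).  Given visit counts,
    client-months are derived as visits x bottles-per-visit (3 for quarterly
    three-month dispensing, 6 for semi-annual six-month dispensing), so the
    bound months <= visits x bottles holds for derived accruals.
    """
    schedule = {Arm.soc: (4, 3), Arm.intervention: (2, 6)}
    if visits_per_arm is None:
        return {
            Arm.soc: ArmAccrual(
                arm=Arm.soc,
                annual_visits=304,
                prep_client_months=913,
                visits_per_client_year=4,
                bottles_per_visit=3,
            ),
            Arm.intervention: ArmAccrual(
                arm=Arm.intervention,
                annual_visits=340,
                prep_client_months=2039,
                visits_per_client_year=2,
                bottles_per_visit=6,
            ),
        }
    out = {}
    for arm, visits in visits_per_arm.items():
        vpy, bottles = schedule[arm]
        if bottles_per_visit is not None:
            bottles = bottles_per_visit[arm]
        out[arm] = ArmAccrual(
            arm=arm,
            annual_visits=visits,
            prep_client_months=visits * bottles,
            visits_per_client_year=vpy,
            bottles_per_visit=bottles,
        )
    return out


def generate_ledger(template: str = "trial", jitter: float = 0.0, seed: int = 0) -> Ledger:
    """A ledger shaped like the packaged fixtures, optionally perturbed.

    ``jitter`` applies independent multiplicative noise uniform on
    [1 - jitter, 1 + jitter] to every salary, unit price, and item amount
    (for property tests of monotonicity and scale behaviour).  Zero jitter
    returns the packaged fixture exactly.
    """
    if template not in ("trial", "moh", "moh_creatinine"):
        raise ValueError(f"unknown ledger template {template!r}")
    base = fixtures.load_fixture_ledger(template)
    if jitter == 0:
        return base
    if not (0 <= jitter < 1):
        raise ValueError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)

    def perturb(amount: MoneyAmount) -> MoneyAmount:
        factor = Decimal(repr(float(rng.uniform(1 - jitter, 1 + jitter))))
        return MoneyAmount(value=amount.value * factor, currency=amount.currency)

    return Ledger(
        scenario_tag=base.scenario_tag,
        economic_params=base.economic_params,
        salaries=[
            CadreSalary(
                cadre=s.cadre,
                annual_salary=perturb(s.annual_salary),
                scenario_tag=s.scenario_tag,
            )
            for s in base.salaries
        ],
        unit_prices=[UnitPrice(item=p.item, price=perturb(p.price)) for p in base.unit_prices],
        items=[replace_amount(i, perturb(i.amount)) for i in base.items],
    )


def replace_amount(item: CostItem, amount: MoneyAmount) -> CostItem:
    return item.model_copy(update={"amount": amount})
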