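"""Named scenario transformations and cross-scenario comparison tables.

A :class:`Scenario` rewrites a base ledger: swap the salary table (research
staff vs public-sector pay), add or remove line items (e.g. the twice-annual
serum creatinine test), or replace start-up fixed lines.  Comparison helpers
produce the arm-difference summary (absolute and percent, with the
standard-of-care unit cost as denominator) and per-category share breakdowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .engine import ArmCostReport, CATEGORY_ORDER
from .ledger import (
    Arm,
    Basis,
    Category,
    CostClass,
    CostItem,
    Ledger,
    MoneyAmount,
    round_cents,
    round_percent,
)

__all__ = [
    "Scenario",
    "ComparisonRow",
    "creatinine_addon",
    "apply_scenario",
    "compare_arms",
    "scenario_matrix",
]


@dataclass(frozen=True)
class Scenario:
    """A named transformation of a base ledger."""

    name: str
    salary_table: Optional[str] = None  # scenario_tag selecting the salary set
    added_items: tuple[CostItem, ...] = ()
    removed_items: tuple[str, ...] = ()
    startup_overrides: tuple[CostItem, ...] = ()

    def __post_init__(self):
        added = {i.name for i in self.added_items}
        if added & set(self.removed_items):
            raise ValueError("added and removed item sets must be disjoint")


def creatinine_addon(
    price_per_test: Decimal = Decimal("2.82"),
    tests_per_client_year: int = 2,
    collection_cost_per_visit: Decimal = Decimal("2.82"),
) -> Scenario:
    """Bi-annual serum creatinine testing add-on.

    Laboratory side: kit plus bench consumables per test, twice per
    client-year.  Clinic side: specimen collection and handling at each
    visit (nurse time and phlebotomy consumables), entered per visit.
    Defaults are the calibrated public-clinic values.
    """
    per_client_year = price_per_test * tests_per_client_year
    return Scenario(
        name="creatinine",
        added_items=(
            CostItem(
                name="creatinine testing (kit + consumables)",
                category=Category.laboratory,
                cost_class=CostClass.variable,
                amount=MoneyAmount(value=per_client_year),
                basis=Basis.per_client_year,
            ),
            CostItem(
                name="creatinine specimen collection per visit",
                category=Category.personnel_clinical,
                cost_class=CostClass.variable,
                amount=MoneyAmount(value=collection_cost_per_visit),
                basis=Basis.per_visit,
            ),
        ),
    )


def apply_scenario(base_ledger: Ledger, scenario: Scenario) -> Ledger:
    """Return a new ledger with the scenario applied; the base is untouched.

    Reapplying the same scenario is a no-op for the salary swap and item
    removals; item additions are applied once (an already-present added item
    of the same name is replaced, keeping the operation idempotent).
    """
    existing = {i.name for i in base_ledger.items}
    for name in scenario.removed_items:
        if name not in existing:
            raise KeyError(f"cannot remove nonexistent item {name!r}")
    if scenario.salary_table is not None:
        available = {s.scenario_tag for s in base_ledger.salaries}
        if scenario.salary_table not in available:
            raise KeyError(
                f"scenario {scenario.name!r}: no salaries tagged {scenario.salary_table!r}"
            )
    replaced = {i.name for i in scenario.added_items} | {
        i.name for i in scenario.startup_overrides
    }
    override_cats = {i.category for i in scenario.startup_overrides}
    items = [
        i
        for i in base_ledger.items
        if i.name not in scenario.removed_items
        and i.name not in replaced
        and i.category not in override_cats
    ]
    items.extend(scenario.startup_overrides)
    items.extend(scenario.added_items)
    return Ledger(
        scenario_tag=scenario.salary_table or base_ledger.scenario_tag,
        economic_params=base_ledger.economic_params,
        salaries=base_ledger.salaries,
        unit_prices=base_ledger.unit_prices,
        items=items,
    )


@dataclass(frozen=True)
class ComparisonRow:
    """Unit-cost comparison of the two arms under one scenario."""

    scenario: str
    soc_unit_cost: Decimal
    intervention_unit_cost: Decimal
    abs_difference: Decimal = dc_field(init=False)
    pct_difference: int = dc_field(init=False)

    def __post_init__(self):
        diff = round_cents(self.soc_unit_cost - self.intervention_unit_cost)
        object.__setattr__(self, "abs_difference", diff)
        pct = round_percent(diff / self.soc_unit_cost) if self.soc_unit_cost else 0
        object.__setattr__(self, "pct_difference", pct)


def compare_arms(soc_report: ArmCostReport, intervention_report: ArmCostReport) -> ComparisonRow:
    """Arm difference in cost per client-month (SOC minus intervention)."""
    if soc_report.scenario_tag != intervention_report.scenario_tag:
        raise ValueError(
            f"mismatched scenarios: {soc_report.scenario_tag!r} vs "
            f"{intervention_report.scenario_tag!r}"
        )
    if soc_report.arm is not Arm.soc or intervention_report.arm is not Arm.intervention:
        raise ValueError("reports passed in the wrong arm order")
    return ComparisonRow(
        scenario=soc_report.scenario_tag,
        soc_unit_cost=soc_report.unit_cost_total,
        intervention_unit_cost=intervention_report.unit_cost_total,
    )


def scenario_matrix(
    reports: Mapping[str, Mapping[Arm, ArmCostReport]],
    order: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-scenario summary and category share breakdown.

    Parameters
    ----------
    reports : mapping scenario name -> {arm: ArmCostReport}

    Returns
    -------
    summary : one row per scenario (unit costs, absolute and percent
        difference with SOC as denominator).
    shares : one row per (scenario, arm, category) with the category's
        percent of the arm total.
    """
    names = list(order) if order is not None else list(reports)
    summary_rows, share_rows = [], []
    for name in names:
        pair = reports[name]
        row = compare_arms(pair[Arm.soc], pair[Arm.intervention])
        summary_rows.append(
            {
                "scenario": name,
                "soc_unit_cost": float(row.soc_unit_cost),
                "intervention_unit_cost": float(row.intervention_unit_cost),
                "abs_difference": float(row.abs_difference),
                "pct_difference": row.pct_difference,
            }
        )
        for arm, report in pair.items():
            for cat in CATEGORY_ORDER:
                share_rows.append(
                    {
                        "scenario": name,
                        "arm": arm.value,
                        "category": cat.value,
                        "annual_cost": float(report.category_totals[cat]),
                        "pct_of_total": round_percent(report.shares[cat]),
                    }
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(share_rows)
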