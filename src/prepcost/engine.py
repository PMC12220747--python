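"""Core micro-costing arithmetic.

Turns a validated ledger plus per-arm accruals (and, optionally,
time-and-motion summaries) into per-arm annual cost reports: category totals,
fixed/variable subtotals, cost per client-month, and category shares.

Conventions
-----------
* One-off costs (capital, start-up, training) are annuitized over their
  useful life with the standard annuity factor ``(1 - (1+r)^-n) / r`` at the
  ledger discount rate; a straight-line (amount / life) alternative is a
  config switch.
* Variable accrual: per-visit lines scale with annual visits, drug lines with
  PrEP client-months, twice-annual lines (e.g. creatinine testing) with
  client-years = client-months / 12.
* Fixed lines entered per arm pass through; pooled fixed lines are allocated
  across arms in proportion to each arm's share of total PrEP visits, with
  the residual cent assigned to the larger arm.
* All arithmetic is exact ``Decimal``; category totals are rounded half-even
  to cents and subtotals/grand totals are sums of the rounded categories, so
  report additivity holds to the cent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping, Optional, Union

from .ledger import (
    Arm,
    ArmAccrual,
    Basis,
    Category,
    CostClass,
    CostItem,
    EconomicParams,
    FIXED_CATEGORIES,
    Ledger,
    MoneyAmount,
    PricedItem,
    VARIABLE_CATEGORIES,
    convert_to_usd,
    round_cents,
)

__all__ = [
    "CostingOptions",
    "AnnualizedItem",
    "ArmCostReport",
    "annuity_factor",
    "annualize",
    "variable_costs",
    "allocate_fixed",
    "unit_cost_per_client_month",
    "cost_shares",
    "build_arm_report",
]

#: Report row order mirroring the published cost tables.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.personnel_clinical,
    Category.prep_drugs,
    Category.laboratory,
    Category.recurrent_training,
    Category.supplies,
    Category.startup_microplanning,
    Category.personnel_supervision,
    Category.capital,
    Category.overhead,
    Category.startup_training,
)


@dataclass(frozen=True)
class CostingOptions:
    """Tunable engine conventions.

    straight_line_annualization
        Use amount / life instead of the discounted annuity factor.
    hivst_kits_per_visit
        Self-test kits dispensed at each intervention-arm visit (two kits
        cover the interim test between semi-annual visits).
    hivst_oral_fraction
        Share of kits that are oral-fluid (vs blood-based); the two products
        are randomized 1:1 in the study configuration.
    rapid_test_per_visit
        Provider-administered rapid HIV tests per clinic visit (both arms).
    """

    straight_line_annualization: bool = False
    hivst_kits_per_visit: int = 2
    hivst_oral_fraction: Decimal = Decimal("0.5")
    rapid_test_per_visit: int = 1


@dataclass(frozen=True)
class AnnualizedItem:
    source: CostItem
    annualized_amount: MoneyAmount


@dataclass
class ArmCostReport:
    """Annual cost report for one arm under one scenario."""

    arm: Arm
    scenario_tag: str
    prep_client_months: int
    annual_visits: int
    category_totals: dict[Category, Decimal]
    variable_subtotal: Decimal = field(init=False)
    fixed_subtotal: Decimal = field(init=False)
    grand_total: Decimal = field(init=False)
    unit_costs: dict[Category, Decimal] = field(init=False)
    unit_cost_total: Decimal = field(init=False)
    shares: dict[Category, Decimal] = field(init=False)

    def __post_init__(self):
        totals = {c: round_cents(self.category_totals.get(c, Decimal(0))) for c in CATEGORY_ORDER}
        self.category_totals = totals
        self.variable_subtotal = sum(totals[c] for c in CATEGORY_ORDER if c in VARIABLE_CATEGORIES)
        self.fixed_subtotal = sum(totals[c] for c in CATEGORY_ORDER if c in FIXED_CATEGORIES)
        self.grand_total = self.variable_subtotal + self.fixed_subtotal
        months = Decimal(self.prep_client_months)
        self.unit_costs = {c: round_cents(totals[c] / months) for c in CATEGORY_ORDER}
        self.unit_cost_total = unit_cost_per_client_month(
            self.grand_total, self.prep_client_months
        )
        self.shares = cost_shares(totals, self.grand_total)

    def to_dict(self) -> dict:
        return {
            "arm": self.arm.value,
            "scenario_tag": self.scenario_tag,
            "prep_client_months": self.prep_client_months,
            "annual_visits": self.annual_visits,
            "category_totals": {c.value: str(self.category_totals[c]) for c in CATEGORY_ORDER},
            "unit_costs": {c.value: str(self.unit_costs[c]) for c in CATEGORY_ORDER},
            "shares": {c.value: str(self.shares[c]) for c in CATEGORY_ORDER},
            "variable_subtotal": str(self.variable_subtotal),
            "fixed_subtotal": str(self.fixed_subtotal),
            "grand_total": str(self.grand_total),
            "unit_cost_total": str(self.unit_cost_total),
        }


def annuity_factor(discount_rate: Union[Decimal, float], life_years: int) -> Decimal:
    """Present-value annuity factor ``(1 - (1+r)^-n) / r``; exactly ``n`` at r=0."""
    if life_years < 1:
        raise ValueError("useful life must be at least one year")
    r = Decimal(repr(discount_rate)) if isinstance(discount_rate, float) else Decimal(discount_rate)
    if r < 0 or r >= 1:
        raise ValueError("discount rate must be in [0, 1)")
    if r == 0:
        return Decimal(life_years)
    return (1 - (1 + r) ** -life_years) / r


def annualize(
    item: CostItem, params: EconomicParams, options: CostingOptions = CostingOptions()
) -> AnnualizedItem:
    """Spread a one-off cost over its useful life; recurring items pass through."""
    if item.basis is not Basis.one_off:
        return AnnualizedItem(source=item, annualized_amount=item.amount)
    if item.useful_life_years is None:
        raise ValueError(f"item {item.name!r}: one_off without useful_life_years")
    amount = convert_to_usd(item.amount, params).value
    if options.straight_line_annualization:
        annual = amount / Decimal(item.useful_life_years)
    else:
        annual = amount / annuity_factor(params.discount_rate, item.useful_life_years)
    return AnnualizedItem(source=item, annualized_amount=MoneyAmount(value=annual))


def _usd(item: CostItem, params: EconomicParams) -> Decimal:
    return convert_to_usd(item.amount, params).value


def _accrue(item: CostItem, accrual: ArmAccrual, params: EconomicParams) -> Decimal:
    amount = _usd(item, params)
    if item.basis is Basis.per_year:
        return amount
    if item.basis is Basis.per_visit:
        return amount * accrual.annual_visits
    if item.basis is Basis.per_client_month:
        return amount * accrual.prep_client_months
    if item.basis is Basis.per_client_year:
        return amount * Decimal(accrual.prep_client_months) / Decimal(12)
    raise ValueError(f"item {item.name!r}: basis {item.basis.value} not valid here")


def _mean_hivst_kit_price(ledger: Ledger, options: CostingOptions) -> Decimal:
    oral = ledger.price(PricedItem.oraquick_hivst).value
    blood = ledger.price(PricedItem.atomo_hivst).value
    f = options.hivst_oral_fraction
    return f * oral + (1 - f) * blood


def variable_costs(
    ledger: Ledger,
    accrual: ArmAccrual,
    tam_cost_per_visit: Optional[MoneyAmount] = None,
    options: CostingOptions = CostingOptions(),
) -> dict[Category, Decimal]:
    """Unrounded annual totals for the five variable categories of one arm.

    Clinical personnel: ledger ``per_visit`` personnel lines take precedence
    (calibrated rates); otherwise the wage-weighted time-and-motion cost per
    visit must be supplied.  Laboratory adds price-list built-ins on top of
    ledger lines: one rapid HIV test per visit in both arms, plus
    ``hivst_kits_per_visit`` self-test kits (mean of the oral/blood prices at
    the randomization fraction) per intervention visit.
    """
    params = ledger.economic_params
    totals: dict[Category, Decimal] = {c: Decimal(0) for c in VARIABLE_CATEGORIES}
    for item in ledger.items_for(accrual.arm):
        if item.cost_class is not CostClass.variable:
            continue
        if item.basis is Basis.one_off:
            totals[item.category] += annualize(item, params, options).annualized_amount.value
        else:
            totals[item.category] += _accrue(item, accrual, params)

    has_personnel_lines = any(
        i.category is Category.personnel_clinical
        for i in ledger.items_for(accrual.arm, Category.personnel_clinical)
    )
    if not has_personnel_lines:
        if tam_cost_per_visit is None:
            raise ValueError(
                "no per-visit clinical personnel ledger lines and no "
                "time-and-motion cost supplied"
            )
        totals[Category.personnel_clinical] += (
            tam_cost_per_visit.value * accrual.annual_visits
        )

    # price-list built-ins (laboratory)
    rapid = ledger.price(PricedItem.determine_rapid_test).value
    lab = rapid * options.rapid_test_per_visit * accrual.annual_visits
    if accrual.arm is Arm.intervention and options.hivst_kits_per_visit:
        lab += (
            _mean_hivst_kit_price(ledger, options)
            * options.hivst_kits_per_visit
            * accrual.annual_visits
        )
    totals[Category.laboratory] += lab
    return totals


def fixed_costs(
    ledger: Ledger,
    accruals: Mapping[Arm, ArmAccrual],
    options: CostingOptions = CostingOptions(),
) -> dict[Arm, dict[Category, Decimal]]:
    """Per-arm annual totals for the five fixed categories.

    Arm-tagged lines accrue to their arm directly; untagged (pooled) lines
    are allocated by each arm's share of total PrEP visits.
    """
    params = ledger.economic_params
    per_arm: dict[Arm, dict[Category, Decimal]] = {
        arm: {c: Decimal(0) for c in FIXED_CATEGORIES} for arm in accruals
    }
    pooled: dict[Category, Decimal] = {c: Decimal(0) for c in FIXED_CATEGORIES}
    for item in ledger.items:
        if item.cost_class is not CostClass.fixed:
            continue
        annual = annualize(item, params, options).annualized_amount.value
        if item.arm is not None:
            if item.arm in per_arm:
                per_arm[item.arm][item.category] += annual
        else:
            pooled[item.category] += annual
    if any(v != 0 for v in pooled.values()):
        allocated = allocate_fixed(pooled, accruals)
        for arm, cats in allocated.items():
            for cat, amount in cats.items():
                per_arm[arm][cat] += amount
    return per_arm


def allocate_fixed(
    total_fixed_by_category: Mapping[Category, Decimal],
    accruals: Mapping[Arm, ArmAccrual],
) -> dict[Arm, dict[Category, Decimal]]:
    """Split pooled fixed category totals across arms by PrEP-visit share.

    Each category total is conserved to the cent; any residual cent from
    rounding is assigned to the arm with more visits.
    """
    total_visits = sum(a.annual_visits for a in accruals.values())
    if total_visits <= 0:
        raise ValueError("total visits across arms must be positive")
    arms = list(accruals)
    out: dict[Arm, dict[Category, Decimal]] = {arm: {} for arm in arms}
    larger = max(arms, key=lambda a: accruals[a].annual_visits)
    for category, total in total_fixed_by_category.items():
        total_c = round_cents(Decimal(total))
        assigned = Decimal(0)
        for arm in arms:
            share = Decimal(accruals[arm].annual_visits) / Decimal(total_visits)
            out[arm][category] = round_cents(total_c * share)
            assigned += out[arm][category]
        out[larger][category] += total_c - assigned
    return out


def unit_cost_per_client_month(grand_total: Union[Decimal, MoneyAmount], months: int) -> Decimal:
    """Average cost of one client-month of PrEP coverage (rounded to cents)."""
    if months <= 0:
        raise ValueError("prep_client_months must be positive")
    total = grand_total.value if isinstance(grand_total, MoneyAmount) else Decimal(grand_total)
    return round_cents(total / Decimal(months))


def cost_shares(
    category_totals: Mapping[Category, Decimal], grand_total: Decimal
) -> dict[Category, Decimal]:
    """Each category's fraction of the grand total (display as whole percent)."""
    if grand_total <= 0:
        raise ValueError("grand total must be positive to compute shares")
    return {c: Decimal(v) / Decimal(grand_total) for c, v in category_totals.items()}


def build_arm_report(
    ledger: Ledger,
    accrual: ArmAccrual,
    accruals: Mapping[Arm, ArmAccrual],
    tam_cost_per_visit: Optional[MoneyAmount] = None,
    scenario_tag: Optional[str] = None,
    options: CostingOptions = CostingOptions(),
) -> ArmCostReport:
    """Assemble the full ten-category annual cost report for one arm."""
    var = variable_costs(ledger, accrual, tam_cost_per_visit, options)
    fix = fixed_costs(ledger, accruals, options)[accrual.arm]
    return ArmCostReport(
        arm=accrual.arm,
        scenario_tag=scenario_tag or ledger.scenario_tag,
        prep_client_months=accrual.prep_client_months,
        annual_visits=accrual.annual_visits,
        category_totals={**var, **fix},
    )
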