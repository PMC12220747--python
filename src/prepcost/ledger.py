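"""Cost-input ledger: domain types, validation, and YAML round-tripping.

A ledger bundles everything needed to price one delivery scenario: economic
parameters (exchange, inflation and discount rates, working time), annual
salaries per health-worker cadre, unit prices for drugs and test kits, and
line items classified by cost category, fixed/variable class and accrual
basis.  Amounts are carried as exact :class:`decimal.Decimal` values and only
rounded (banker's rounding) at presentation/aggregation boundaries, so
cent-level table sums are reproducible without float drift.
"""

from __future__ import annotations

import enum
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Currency",
    "MoneyAmount",
    "Category",
    "CostClass",
    "Basis",
    "Arm",
    "Cadre",
    "PricedItem",
    "CostItem",
    "CadreSalary",
    "UnitPrice",
    "EconomicParams",
    "ArmAccrual",
    "Ledger",
    "FIXED_CATEGORIES",
    "VARIABLE_CATEGORIES",
    "TABLE1_EXCHANGE_RATE",
    "load_ledger",
    "write_ledger",
    "load_accruals",
    "convert_to_usd",
    "inflation_adjust",
    "round_cents",
    "round_percent",
]

CENT = Decimal("0.01")

#: Alternative printed 2019 exchange rate; the default ledger uses 105.50.
TABLE1_EXCHANGE_RATE = Decimal("105.35")


def round_cents(amount: Decimal) -> Decimal:
    """Round a currency amount to cents, half-even (banker's rounding)."""
    return amount.quantize(CENT, rounding=ROUND_HALF_EVEN)


def round_percent(fraction: Decimal) -> int:
    """Display rounding for cost shares: whole percent, half-up."""
    return int((Decimal(fraction) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


class Currency(str, enum.Enum):
    USD = "USD"
    KES = "KES"


class Arm(str, enum.Enum):
    """Study arm: quarterly standard of care vs six-month dispensing + HIVST."""

    soc = "soc"
    intervention = "intervention"


class Cadre(str, enum.Enum):
    hiv_testing_counsellor = "hiv_testing_counsellor"
    clinical_officer = "clinical_officer"
    nurse = "nurse"
    pharmacy_technologist = "pharmacy_technologist"


class PricedItem(str, enum.Enum):
    prep_30day = "prep_30day"
    oraquick_hivst = "oraquick_hivst"
    atomo_hivst = "atomo_hivst"
    determine_rapid_test = "determine_rapid_test"
    creatinine_test = "creatinine_test"


class Category(str, enum.Enum):
    """The ten cost-report row categories."""

    personnel_clinical = "personnel_clinical"
    prep_drugs = "prep_drugs"
    laboratory = "laboratory"
    recurrent_training = "recurrent_training"
    supplies = "supplies"
    startup_microplanning = "startup_microplanning"
    personnel_supervision = "personnel_supervision"
    capital = "capital"
    overhead = "overhead"
    startup_training = "startup_training"


FIXED_CATEGORIES = frozenset(
    {
        Category.startup_microplanning,
        Category.personnel_supervision,
        Category.capital,
        Category.overhead,
        Category.startup_training,
    }
)
VARIABLE_CATEGORIES = frozenset(set(Category) - FIXED_CATEGORIES)


class CostClass(str, enum.Enum):
    fixed = "fixed"
    variable = "variable"


class Basis(str, enum.Enum):
    """How a line item accrues over a year of delivery."""

    per_year = "per_year"
    per_visit = "per_visit"
    per_client_month = "per_client_month"
    per_client_year = "per_client_year"
    one_off = "one_off"


def _as_decimal(v) -> Decimal:
    if isinstance(v, Decimal):
        return v
    if isinstance(v, float):
        # YAML floats: recover the literal the author wrote (repr round-trips).
        return Decimal(repr(v))
    return Decimal(str(v))


class MoneyAmount(BaseModel):
    """A non-negative currency amount in USD or KES."""

    model_config = {"frozen": True}

    value: Decimal
    currency: Currency = Currency.USD

    @field_validator("value", mode="before")
    @classmethod
    def _coerce(cls, v):
        return _as_decimal(v)

    @field_validator("value")
    @classmethod
    def _nonneg(cls, v: Decimal) -> Decimal:
        if v < 0:
            raise ValueError("money amounts must be non-negative")
        return v

    def rounded(self) -> Decimal:
        return round_cents(self.value)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.rounded()} {self.currency.value}"


class CostItem(BaseModel):
    """One ledger line.

    ``arm`` restricts a line to one study arm; ``None`` means the line applies
    to every arm (variable bases) or is a pooled amount to be allocated across
    arms by visit share (fixed ``per_year``/``one_off`` lines).
    """

    name: str
    category: Category
    cost_class: CostClass
    amount: MoneyAmount
    basis: Basis
    arm: Optional[Arm] = None
    useful_life_years: Optional[int] = Field(default=None, ge=1, le=5)

    @model_validator(mode="after")
    def _check(self) -> "CostItem":
        expected = CostClass.fixed if self.category in FIXED_CATEGORIES else CostClass.variable
        if self.cost_class != expected:
            raise ValueError(
                f"item {self.name!r}: category {self.category.value} must be "
                f"{expected.value}, got {self.cost_class.value}"
            )
        if self.basis is Basis.one_off and self.useful_life_years is None:
            raise ValueError(f"item {self.name!r}: one_off items require useful_life_years")
        if self.basis is not Basis.one_off and self.useful_life_years is not None:
            raise ValueError(f"item {self.name!r}: useful_life_years only valid for one_off items")
        if self.cost_class is CostClass.fixed and self.basis in (
            Basis.per_visit,
            Basis.per_client_month,
            Basis.per_client_year,
        ):
            raise ValueError(f"item {self.name!r}: fixed costs cannot accrue {self.basis.value}")
        return self


class CadreSalary(BaseModel):
    cadre: Cadre
    annual_salary: MoneyAmount
    scenario_tag: str

    @field_validator("annual_salary")
    @classmethod
    def _positive(cls, v: MoneyAmount) -> MoneyAmount:
        if v.value <= 0:
            raise ValueError("annual_salary must be positive")
        return v


class UnitPrice(BaseModel):
    item: PricedItem
    price: MoneyAmount

    @field_validator("price")
    @classmethod
    def _positive(cls, v: MoneyAmount) -> MoneyAmount:
        if v.value <= 0:
            raise ValueError("price must be positive")
        return v


class EconomicParams(BaseModel):
    exchange_rate_kes_per_usd: Decimal = Decimal("105.50")
    inflation_rate: Decimal = Decimal("0.044")
    discount_rate: Decimal = Decimal("0.03")
    annual_work_hours: Decimal = Decimal("2080")
    weekdays_per_year: int = 231

    @field_validator(
        "exchange_rate_kes_per_usd", "inflation_rate", "discount_rate", "annual_work_hours",
        mode="before",
    )
    @classmethod
    def _coerce(cls, v):
        return _as_decimal(v)

    @model_validator(mode="after")
    def _check(self) -> "EconomicParams":
        if self.exchange_rate_kes_per_usd <= 0:
            raise ValueError("exchange rate must be positive")
        if not (0 <= self.discount_rate < 1):
            raise ValueError("discount_rate must be in [0, 1)")
        if not (0 <= self.inflation_rate < 1):
            raise ValueError("inflation_rate must be in [0, 1)")
        if self.annual_work_hours <= 0:
            raise ValueError("annual_work_hours must be positive")
        if self.weekdays_per_year <= 0:
            raise ValueError("weekdays_per_year must be positive")
        return self


class ArmAccrual(BaseModel):
    """Annual service volumes for one arm.

    Note: observed accruals may slightly exceed the visits x bottles product
    (clients occasionally receive extra refill coverage), so no hard bound is
    enforced between ``prep_client_months`` and ``annual_visits``.
    """

    arm: Arm
    annual_visits: int = Field(gt=0)
    prep_client_months: int = Field(gt=0)
    visits_per_client_year: int = Field(gt=0)
    bottles_per_visit: int = Field(gt=0)


class Ledger(BaseModel):
    """A complete, validated cost-input ledger for one scenario."""

    scenario_tag: str = "trial"
    economic_params: EconomicParams = EconomicParams()
    salaries: list[CadreSalary] = []
    unit_prices: list[UnitPrice] = []
    items: list[CostItem] = []

    @model_validator(mode="after")
    def _unique(self) -> "Ledger":
        seen: set[tuple] = set()
        for s in self.salaries:
            key = (s.cadre, s.scenario_tag)
            if key in seen:
                raise ValueError(f"duplicate salary for {s.cadre.value}/{s.scenario_tag}")
            seen.add(key)
        names = [i.name for i in self.items]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate item names: {sorted(dupes)}")
        return self

    # -- lookups ---------------------------------------------------------

    def salary(self, cadre: Cadre, scenario_tag: Optional[str] = None) -> CadreSalary:
        tag = scenario_tag or self.scenario_tag
        for s in self.salaries:
            if s.cadre is cadre and s.scenario_tag == tag:
                return s
        raise KeyError(f"no salary for cadre {cadre.value!r} under scenario {tag!r}")

    def price(self, item: Union[PricedItem, str]) -> MoneyAmount:
        item = PricedItem(item)
        for p in self.unit_prices:
            if p.item is item:
                return p.price
        raise KeyError(f"no unit price for {item.value!r}")

    def items_for(self, arm: Arm, category: Optional[Category] = None) -> list[CostItem]:
        """Lines applying to ``arm`` (arm-specific plus arm-agnostic)."""
        out = [i for i in self.items if i.arm in (None, arm)]
        if category is not None:
            out = [i for i in out if i.category is category]
        return out

    def item(self, name: str) -> CostItem:
        for i in self.items:
            if i.name == name:
                return i
        raise KeyError(f"no ledger item named {name!r}")


# -- currency arithmetic -------------------------------------------------


def convert_to_usd(amount: MoneyAmount, params: EconomicParams) -> MoneyAmount:
    """Convert a KES amount to USD at the ledger exchange rate.

    USD inputs pass through unchanged (idempotent); KES amounts are divided by
    the KES-per-USD rate and rounded half-even to cents.
    """
    if amount.currency is Currency.USD:
        return amount
    if amount.currency is Currency.KES:
        usd = round_cents(amount.value / params.exchange_rate_kes_per_usd)
        return MoneyAmount(value=usd, currency=Currency.USD)
    raise ValueError(f"unsupported currency: {amount.currency}")


def inflation_adjust(amount: MoneyAmount, rate: Decimal, years: int) -> MoneyAmount:
    """Compound an amount forward by ``years`` at annual ``rate``."""
    if years < 0:
        raise ValueError("years must be non-negative")
    factor = (Decimal(1) + _as_decimal(rate)) ** years
    return MoneyAmount(value=round_cents(amount.value * factor), currency=amount.currency)


# -- file I/O ------------------------------------------------------------


def _money_to_yaml(m: MoneyAmount) -> dict:
    return {"amount": str(m.value), "currency": m.currency.value}


def _money_from_yaml(node) -> dict:
    if isinstance(node, dict):
        return {"value": _as_decimal(node["amount"]), "currency": node.get("currency", "USD")}
    return {"value": _as_decimal(node), "currency": "USD"}


def load_ledger(path: Union[str, Path]) -> Ledger:
    """Read and validate a ledger YAML document (see ``data/ledger.schema.json``)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: ledger document must be a mapping")
    raw_items = doc.get("items") or []
    items = []
    for raw in raw_items:
        raw = dict(raw)
        raw["amount"] = _money_from_yaml(raw["amount"])
        items.append(raw)
    salaries = []
    for raw in doc.get("salaries") or []:
        raw = dict(raw)
        raw["annual_salary"] = _money_from_yaml(raw["annual_salary"])
        salaries.append(raw)
    prices = []
    for raw in doc.get("unit_prices") or []:
        raw = dict(raw)
        raw["price"] = _money_from_yaml(raw["price"])
        prices.append(raw)
    return Ledger(
        scenario_tag=doc.get("scenario_tag", "trial"),
        economic_params=doc.get("economic_params") or {},
        salaries=salaries,
        unit_prices=prices,
        items=items,
    )


def write_ledger(ledger: Ledger, path: Union[str, Path]) -> None:
    """Serialize a ledger back to YAML (content round-trips through load_ledger)."""
    ep = ledger.economic_params
    doc = {
        "scenario_tag": ledger.scenario_tag,
        "economic_params": {
            "exchange_rate_kes_per_usd": str(ep.exchange_rate_kes_per_usd),
            "inflation_rate": str(ep.inflation_rate),
            "discount_rate": str(ep.discount_rate),
            "annual_work_hours": str(ep.annual_work_hours),
            "weekdays_per_year": ep.weekdays_per_year,
        },
        "salaries": [
            {
                "cadre": s.cadre.value,
                "annual_salary": _money_to_yaml(s.annual_salary),
                "scenario_tag": s.scenario_tag,
            }
            for s in ledger.salaries
        ],
        "unit_prices": [
            {"item": p.item.value, "price": _money_to_yaml(p.price)} for p in ledger.unit_prices
        ],
        "items": [
            {
                "name": i.name,
                "category": i.category.value,
                "cost_class": i.cost_class.value,
                "amount": _money_to_yaml(i.amount),
                "basis": i.basis.value,
                **({"arm": i.arm.value} if i.arm else {}),
                **(
                    {"useful_life_years": i.useful_life_years}
                    if i.useful_life_years is not None
                    else {}
                ),
            }
            for i in ledger.items
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_accruals(path: Union[str, Path]) -> dict[Arm, ArmAccrual]:
    """Read per-arm accrual counts from a YAML document with an ``accruals`` list."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    rows: Iterable[dict] = doc["accruals"] if isinstance(doc, dict) else doc
    out = {}
    for raw in rows:
        acc = ArmAccrual(**raw)
        out[acc.arm] = acc
    if not out:
        raise ValueError(f"{path}: no accrual rows found")
    return out


def write_accruals(accruals: dict[Arm, ArmAccrual], path: Union[str, Path]) -> None:
    doc = {
        "accruals": [
            {
                "arm": a.arm.value,
                "annual_visits": a.annual_visits,
                "prep_client_months": a.prep_client_months,
                "visits_per_client_year": a.visits_per_client_year,
                "bottles_per_visit": a.bottles_per_visit,
            }
            for a in accruals.values()
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
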