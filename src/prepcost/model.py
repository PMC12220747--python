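"""Model/Results facade over the costing pipeline.

`PrEPDeliveryCostModel` is built from data (a ledger, per-arm accruals and,
optionally, a time-and-motion observation log); ``fit()`` runs the costing
and returns a `PrEPDeliveryCostResults` carrying per-arm cost reports, the
arm comparison, and a text ``summary()`` table.

    >>> model = PrEPDeliveryCostModel.from_fixture("trial")
    >>> res = model.fit()
    >>> res.comparison.abs_difference
    Decimal('7.77')
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .engine import (
    ArmCostReport,
    CATEGORY_ORDER,
    CostingOptions,
    build_arm_report,
)
from .fixtures import load_fixture_accruals, load_fixture_ledger
from .ledger import (
    Arm,
    ArmAccrual,
    Cadre,
    Category,
    Ledger,
    MoneyAmount,
    load_accruals,
    load_ledger,
    round_percent,
)
from .scenarios import ComparisonRow, Scenario, apply_scenario, compare_arms
from .timemotion import (
    Activity,
    ActivityObservation,
    personnel_cost_per_visit,
    read_observations,
    summarize,
)

__all__ = ["PrEPDeliveryCostModel", "PrEPDeliveryCostResults"]

_ROW_LABELS = {
    Category.personnel_clinical: "Personnel (clinical)",
    Category.prep_drugs: "PrEP drugs",
    Category.laboratory: "Laboratory testing",
    Category.recurrent_training: "Recurrent training",
    Category.supplies: "Supplies",
    Category.startup_microplanning: "Start-up microplanning",
    Category.personnel_supervision: "Personnel (supervision)",
    Category.capital: "Capital",
    Category.overhead: "Overhead",
    Category.startup_training: "Start-up training",
}


class PrEPDeliveryCostModel:
    """Annual payer-perspective cost of PrEP delivery, by arm.

    Parameters
    ----------
    ledger
        Validated cost-input ledger for one scenario.
    accruals
        Per-arm annual visit and client-month counts.
    observations
        Optional time-and-motion log.  Required when the ledger carries no
        calibrated per-visit clinical-personnel lines: the model then prices
        personnel time mechanistically as activity minutes x cadre wages.
    scenario
        Optional :class:`Scenario` transformation applied to the ledger
        before costing.
    """

    def __init__(
        self,
        ledger: Ledger,
        accruals: Mapping[Arm, ArmAccrual],
        observations: Optional[Sequence[ActivityObservation]] = None,
        scenario: Optional[Scenario] = None,
        options: CostingOptions = CostingOptions(),
    ):
        if Arm.soc not in accruals or Arm.intervention not in accruals:
            raise ValueError("accruals must cover both arms")
        self.ledger = apply_scenario(ledger, scenario) if scenario else ledger
        self.accruals = dict(accruals)
        self.observations = list(observations) if observations else None
        self.options = options

    @classmethod
    def from_files(
        cls,
        ledger_path: Union[str, Path],
        accruals_path: Union[str, Path],
        observations_path: Optional[Union[str, Path]] = None,
        scenario: Optional[Scenario] = None,
        options: CostingOptions = CostingOptions(),
    ) -> "PrEPDeliveryCostModel":
        obs = read_observations(observations_path) if observations_path else None
        return cls(
            ledger=load_ledger(ledger_path),
            accruals=load_accruals(accruals_path),
            observations=obs,
            scenario=scenario,
            options=options,
        )

    @classmethod
    def from_fixture(
        cls,
        name: str = "trial",
        scenario: Optional[Scenario] = None,
        options: CostingOptions = CostingOptions(),
    ) -> "PrEPDeliveryCostModel":
        """Build from a packaged scenario fixture (``trial``, ``moh``,
        ``moh_creatinine``) and the shared accrual fixture."""
        return cls(
            ledger=load_fixture_ledger(name),
            accruals=load_fixture_accruals(),
            scenario=scenario,
            options=options,
        )

    def _tam_cost(self, arm: Arm) -> Optional[MoneyAmount]:
        if self.observations is None:
            return None
        stats = summarize(self.observations, by="arm")
        rows = stats[(stats.stratum == arm.value) & (stats.activity != "total")]
        durations = {Activity(r.activity): r.mean for r in rows.itertuples(index=False)}
        salaries = {
            c: self.ledger.salary(c, self.ledger.scenario_tag) for c in Cadre
        }
        return personnel_cost_per_visit(durations, salaries, self.ledger.economic_params)

    def fit(self) -> "PrEPDeliveryCostResults":
        reports = {}
        for arm, accrual in self.accruals.items():
            reports[arm] = build_arm_report(
                self.ledger,
                accrual,
                self.accruals,
                tam_cost_per_visit=self._tam_cost(arm),
                options=self.options,
            )
        return PrEPDeliveryCostResults(model=self, arm_reports=reports)


class PrEPDeliveryCostResults:
    """Fitted costing results: per-arm reports, comparison, summary table."""

    def __init__(self, model: PrEPDeliveryCostModel, arm_reports: dict[Arm, ArmCostReport]):
        self.model = model
        self.arm_reports = arm_reports
        self.comparison: ComparisonRow = compare_arms(
            arm_reports[Arm.soc], arm_reports[Arm.intervention]
        )

    @property
    def unit_costs(self) -> dict[Arm, float]:
        return {arm: float(r.unit_cost_total) for arm, r in self.arm_reports.items()}

    def to_dict(self) -> dict:
        return {
            "scenario": self.model.ledger.scenario_tag,
            "arms": {arm.value: r.to_dict() for arm, r in self.arm_reports.items()},
            "comparison": {
                "soc_unit_cost": str(self.comparison.soc_unit_cost),
                "intervention_unit_cost": str(self.comparison.intervention_unit_cost),
                "abs_difference": str(self.comparison.abs_difference),
                "pct_difference": self.comparison.pct_difference,
            },
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable annual cost table (2019 USD)."""
        soc = self.arm_reports[Arm.soc]
        itv = self.arm_reports[Arm.intervention]
        w = 24
        lines = [
            f"PrEP delivery cost report — scenario: {self.model.ledger.scenario_tag}",
            "=" * 78,
            f"{'':{w}} {'Standard of care':>25} {'Six-month PrEP + HIVST':>26}",
            f"{'PrEP visits / months':{w}} {soc.annual_visits:>12}/{soc.prep_client_months:<12}"
            f" {itv.annual_visits:>12}/{itv.prep_client_months:<13}",
            "-" * 78,
            f"{'Category':{w}} {'annual':>12} {'$/cl-mo':>7} {'%':>4} {'annual':>13} {'$/cl-mo':>7} {'%':>4}",
        ]
        for cat in CATEGORY_ORDER:
            lines.append(
                f"{_ROW_LABELS[cat]:{w}} {soc.category_totals[cat]:>12} "
                f"{soc.unit_costs[cat]:>7} {round_percent(soc.shares[cat]):>3}% "
                f"{itv.category_totals[cat]:>13} {itv.unit_costs[cat]:>7} "
                f"{round_percent(itv.shares[cat]):>3}%"
            )
        lines += [
            "-" * 78,
            f"{'Variable subtotal':{w}} {soc.variable_subtotal:>12} {'':>12} "
            f"{itv.variable_subtotal:>13}",
            f"{'Fixed subtotal':{w}} {soc.fixed_subtotal:>12} {'':>12} {itv.fixed_subtotal:>13}",
            f"{'Total':{w}} {soc.grand_total:>12} {soc.unit_cost_total:>7} {'':>4} "
            f"{itv.grand_total:>13} {itv.unit_cost_total:>7}",
            "-" * 78,
            f"Cost difference per client-month: {self.comparison.abs_difference} "
            f"({self.comparison.pct_difference}% of standard of care)",
        ]
        return "\n".join(lines)

    def plot_shares(self, ax=None):
        """Stacked bar chart of category cost shares by arm (optional)."""
        import matplotlib.pyplot as plt  # deferred; plotting is optional

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        arms = [Arm.soc, Arm.intervention]
        bottom = [0.0, 0.0]
        for cat in CATEGORY_ORDER:
            vals = [float(self.arm_reports[a].shares[cat]) * 100 for a in arms]
            ax.bar(["SOC", "6-mo PrEP + HIVST"], vals, bottom=bottom, label=_ROW_LABELS[cat])
            bottom = [b + v for b, v in zip(bottom, vals)]
        ax.set_ylabel("% of total annual cost")
        ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1, 0.5))
        return ax
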