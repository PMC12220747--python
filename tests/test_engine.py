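"""Costing engine: annuitization, accrual, allocation, reports, oracles."""

from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepcost import (
    Arm,
    ArmAccrual,
    Basis,
    Category,
    CostClass,
    CostItem,
    CostingOptions,
    EconomicParams,
    Ledger,
    MoneyAmount,
    PricedItem,
    allocate_fixed,
    annuity_factor,
    annualize,
    build_arm_report,
    cost_shares,
    unit_cost_per_client_month,
)
from prepcost.engine import CATEGORY_ORDER
from prepcost.ledger import FIXED_CATEGORIES, round_cents


def _accrual(arm, visits, months):
    return ArmAccrual(
        arm=arm,
        annual_visits=visits,
        prep_client_months=months,
        visits_per_client_year=4 if arm is Arm.soc else 2,
        bottles_per_visit=3 if arm is Arm.soc else 6,
    )


class TestAnnuity:
    @pytest.mark.parametrize(
        "rate, life, expected",
        [(0.0, 5, "5"), (0.03, 1, "0.970874"), (0.03, 5, "4.579707")],
    )
    def test_closed_form(self, rate, life, expected):
        assert float(annuity_factor(rate, life)) == pytest.approx(float(expected), abs=5e-7)

    def test_zero_rate_limit_is_continuous(self):
        assert float(annuity_factor(1e-12, 5)) == pytest.approx(5.0, abs=1e-6)

    def test_life_below_one_year_rejected(self):
        with pytest.raises(ValueError):
            annuity_factor(0.03, 0)

    @given(
        rate=st.floats(min_value=0.001, max_value=0.5),
        life=st.integers(min_value=1, max_value=5),
    )
    @settings(deadline=None, max_examples=50)
    def test_factor_bounded_by_life_and_positive(self, rate, life):
        af = float(annuity_factor(rate, life))
        assert 0 < af <= life

    def test_one_off_annualized_amount_never_below_straight_line(self):
        """Discounting spreads cost over fewer effective years than life."""
        params = EconomicParams()
        item = CostItem(
            name="exam table",
            category=Category.capital,
            cost_class=CostClass.fixed,
            amount=MoneyAmount(value=Decimal("100")),
            basis=Basis.one_off,
            useful_life_years=5,
        )
        annual = annualize(item, params).annualized_amount.value
        assert annual >= Decimal("100") / 5
        assert round_cents(annual) == Decimal("21.84")

    def test_one_year_no_discount_pass_through(self):
        params = EconomicParams(discount_rate=Decimal("0"))
        item = CostItem(
            name="training",
            category=Category.startup_training,
            cost_class=CostClass.fixed,
            amount=MoneyAmount(value=Decimal("100")),
            basis=Basis.one_off,
            useful_life_years=1,
        )
        assert annualize(item, params).annualized_amount.value == Decimal("100")

    def test_recurring_items_pass_through_unchanged(self):
        item = CostItem(
            name="rent",
            category=Category.overhead,
            cost_class=CostClass.fixed,
            amount=MoneyAmount(value=Decimal("500")),
            basis=Basis.per_year,
        )
        assert annualize(item, EconomicParams()).annualized_amount.value == Decimal("500")


class TestAllocateFixed:
    def test_visit_share_split(self):
        accruals = {
            Arm.soc: _accrual(Arm.soc, 304, 913),
            Arm.intervention: _accrual(Arm.intervention, 340, 2039),
        }
        out = allocate_fixed({Category.overhead: Decimal("1000")}, accruals)
        assert out[Arm.soc][Category.overhead] == Decimal("472.05")
        assert out[Arm.intervention][Category.overhead] == Decimal("527.95")

    def test_single_arm_receives_everything(self):
        accruals = {Arm.soc: _accrual(Arm.soc, 304, 913)}
        out = allocate_fixed({Category.capital: Decimal("123.45")}, accruals)
        assert out[Arm.soc][Category.capital] == Decimal("123.45")

    def test_equal_visits_split_in_half(self):
        accruals = {
            Arm.soc: _accrual(Arm.soc, 100, 300),
            Arm.intervention: _accrual(Arm.intervention, 100, 600),
        }
        out = allocate_fixed({Category.overhead: Decimal("99.98")}, accruals)
        assert out[Arm.soc][Category.overhead] == out[Arm.intervention][Category.overhead]

    @given(
        total=st.decimals(min_value="0.01", max_value="100000", places=2),
        v1=st.integers(min_value=1, max_value=5000),
        v2=st.integers(min_value=1, max_value=5000),
    )
    @settings(deadline=None, max_examples=100)
    def test_each_category_total_conserved_to_the_cent(self, total, v1, v2):
        accruals = {
            Arm.soc: _accrual(Arm.soc, v1, 3 * v1),
            Arm.intervention: _accrual(Arm.intervention, v2, 6 * v2),
        }
        out = allocate_fixed({Category.capital: total}, accruals)
        assert (
            out[Arm.soc][Category.capital] + out[Arm.intervention][Category.capital] == total
        )

    def test_zero_total_visits_rejected(self):
        with pytest.raises(ValueError):
            allocate_fixed({Category.capital: Decimal("1")}, {})


class TestUnitCostAndShares:
    @pytest.mark.parametrize(
        "total, months, expected",
        [("23284.74", 913, "25.50"), ("36144.35", 2039, "17.73"), ("100.00", 100, "1.00")],
    )
    def test_unit_cost_per_client_month(self, total, months, expected):
        assert unit_cost_per_client_month(Decimal(total), months) == Decimal(expected)

    def test_zero_months_rejected(self):
        with pytest.raises(ValueError):
            unit_cost_per_client_month(Decimal("1"), 0)

    def test_unit_cost_strictly_decreases_with_client_months(self, trial_results):
        total = trial_results.arm_reports[Arm.soc].grand_total
        costs = [unit_cost_per_client_month(total, m) for m in (500, 913, 1500, 2039, 5000)]
        assert all(a > b for a, b in zip(costs, costs[1:]))

    def test_share_examples(self):
        shares = cost_shares(
            {Category.personnel_clinical: Decimal("7539.81")}, Decimal("23284.74")
        )
        from prepcost.ledger import round_percent

        assert round_percent(shares[Category.personnel_clinical]) == 32
        shares = cost_shares({Category.prep_drugs: Decimal("14486.20")}, Decimal("36144.35"))
        assert round_percent(shares[Category.prep_drugs]) == 40

    def test_single_category_ledger_share_is_100_percent(self):
        shares = cost_shares({Category.supplies: Decimal("5")}, Decimal("5"))
        assert shares[Category.supplies] == 1

    def test_zero_total_share_rejected(self):
        with pytest.raises(ValueError):
            cost_shares({Category.supplies: Decimal("0")}, Decimal("0"))


class TestArmReports:
    def test_additivity_to_the_cent(self, trial_results, moh_results):
        for results in (trial_results, moh_results):
            for report in results.arm_reports.values():
                assert (
                    sum(report.category_totals[c] for c in CATEGORY_ORDER)
                    == report.variable_subtotal + report.fixed_subtotal
                    == report.grand_total
                )

    def test_unit_cost_inverse_check(self, trial_results):
        # unit cost x client-months recovers the grand total within half a
        # cent per client-month
        for report in trial_results.arm_reports.values():
            recovered = report.unit_cost_total * report.prep_client_months
            assert abs(recovered - report.grand_total) <= Decimal("0.005") * report.prep_client_months

    def test_shares_sum_to_one(self, trial_results, moh_creatinine_results):
        for results in (trial_results, moh_creatinine_results):
            for report in results.arm_reports.values():
                assert abs(sum(report.shares.values()) - 1) < Decimal("0.005")

    def test_visit_driven_categories_scale_with_accrual(self, trial_ledger):
        from prepcost.engine import variable_costs

        tiny = variable_costs(trial_ledger, _accrual(Arm.soc, 1, 1))
        double = variable_costs(trial_ledger, _accrual(Arm.soc, 2, 2))
        # per-visit and per-month categories scale linearly; per-year lines don't
        assert tiny[Category.personnel_clinical] == Decimal("24.8020")
        assert double[Category.personnel_clinical] == 2 * tiny[Category.personnel_clinical]
        assert double[Category.recurrent_training] == tiny[Category.recurrent_training]

    def test_missing_unit_price_is_an_error(self, trial_ledger, soc_accrual, accruals):
        stripped = trial_ledger.model_copy(
            update={
                "unit_prices": [
                    p for p in trial_ledger.unit_prices
                    if p.item is not PricedItem.determine_rapid_test
                ]
            }
        )
        with pytest.raises(KeyError, match="determine"):
            build_arm_report(stripped, soc_accrual, accruals)


class TestBruteForceOracle:
    """Item-by-item float summation (no vectorization, no Decimal) must agree
    with the engine to the cent on small ledgers."""

    @staticmethod
    def _oracle(ledger, accrual, accruals, kits_per_visit=2):
        visits = accrual.annual_visits
        months = accrual.prep_client_months
        total_visits = sum(a.annual_visits for a in accruals.values())
        cats = {c: 0.0 for c in CATEGORY_ORDER}
        for item in ledger.items:
            amt = float(item.amount.value)
            if item.basis is Basis.one_off:
                r, n = float(ledger.economic_params.discount_rate), item.useful_life_years
                annual = amt / ((1 - (1 + r) ** -n) / r if r else n)
            elif item.basis is Basis.per_visit:
                annual = amt * visits
            elif item.basis is Basis.per_client_month:
                annual = amt * months
            elif item.basis is Basis.per_client_year:
                annual = amt * months / 12
            else:
                annual = amt
            if item.cost_class is CostClass.fixed:
                if item.arm is None:
                    annual *= visits / total_visits
                elif item.arm is not accrual.arm:
                    continue
            elif item.arm not in (None, accrual.arm):
                continue
            cats[item.category] += annual
        cats[Category.laboratory] += float(ledger.price("determine_rapid_test").value) * visits
        if accrual.arm is Arm.intervention:
            mean_kit = (
                float(ledger.price("oraquick_hivst").value)
                + float(ledger.price("atomo_hivst").value)
            ) / 2
            cats[Category.laboratory] += mean_kit * kits_per_visit * visits
        return cats

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("arm", [Arm.soc, Arm.intervention])
    def test_engine_matches_brute_force_on_jittered_ledgers(self, seed, arm, accruals):
        from prepcost import generate_ledger

        ledger = generate_ledger("trial", jitter=0.1, seed=seed)
        assert len(ledger.items) == 20
        report = build_arm_report(ledger, accruals[arm], accruals)
        expected = self._oracle(ledger, accruals[arm], accruals)
        for cat in CATEGORY_ORDER:
            assert float(report.category_totals[cat]) == pytest.approx(
                expected[cat], abs=0.011
            ), cat
        assert float(report.grand_total) == pytest.approx(sum(expected.values()), abs=0.06)

    def test_engine_matches_brute_force_on_fixture(self, trial_ledger, accruals):
        for arm in (Arm.soc, Arm.intervention):
            report = build_arm_report(trial_ledger, accruals[arm], accruals)
            expected = self._oracle(trial_ledger, accruals[arm], accruals)
            assert float(report.grand_total) == pytest.approx(sum(expected.values()), abs=0.06)

    def test_pooled_fixed_lines_are_allocated_by_visit_share(self, trial_ledger, accruals):
        pooled = trial_ledger.model_copy(
            update={
                "items": [
                    i if i.cost_class is CostClass.variable else
                    i.model_copy(update={"arm": None})
                    for i in trial_ledger.items
                ]
            }
        )
        for arm in (Arm.soc, Arm.intervention):
            report = build_arm_report(pooled, accruals[arm], accruals)
            expected = self._oracle(pooled, accruals[arm], accruals)
            for cat in FIXED_CATEGORIES:
                assert float(report.category_totals[cat]) == pytest.approx(
                    expected[cat], abs=0.011
                )
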