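# Methods

## Model

`prepcost` implements bottom-up (activity-based / ingredients) micro-costing
of clinic-based PrEP delivery from the payer perspective, over a one-year
horizon, in 2019 USD. Two delivery arms are costed: quarterly three-month
dispensing (SOC) and semi-annual six-month dispensing with two interim HIV
self-test kits per visit (intervention). The target quantity per arm is the
average cost per client-month of PrEP dispensed,

    unit_cost = (variable costs + fixed costs, annual) / prep_client_months,

with costs decomposed into ten categories: five variable (clinical
personnel, PrEP drugs, laboratory testing, recurrent training, supplies)
and five fixed (start-up microplanning, supervision personnel, capital,
overhead, start-up training).

Accrual rules (all exact-decimal arithmetic):

* per-visit lines × annual visits; per-client-month lines × client-months;
  per-client-year lines × client-months/12; per-year lines pass through;
* one-off lines are annuitized by `amount / a(r, n)` with annuity factor
  `a(r, n) = (1 − (1+r)^−n)/r` (exactly `n` at `r = 0`), discount rate 3%/yr,
  useful life 1–5 years (5 for capital, 1 for training). A straight-line
  `amount/n` convention is available as `CostingOptions(straight_line_annualization=True)`;
* laboratory built-ins: one provider-administered rapid HIV test per visit
  in both arms ($0.83), plus two self-test kits per intervention visit at
  the mean of the oral-fluid ($4.27) and blood-based ($6.17) kit prices
  (products randomized 1:1; both the kit count and the mix are
  `CostingOptions` fields);
* fixed lines tagged to an arm accrue directly; untagged fixed lines are
  pooled and allocated by each arm's share of total PrEP visits (304/644 vs
  340/644 in the study configuration), with the residual cent assigned to
  the larger arm;
* KES amounts are converted at 105.50 KES/USD (the alternative printed
  rate, 105.35, ships as `TABLE1_EXCHANGE_RATE`); amounts are carried as
  exact decimals and rounded half-even to cents only at category level, so
  subtotal/total additivity holds to the cent by construction.

Time-and-motion analysis: per-activity durations are end − start in
fractional minutes; waiting is reported but excluded from provider totals
and never costed (payer perspective). Summaries report median/IQR (linear
interpolation between order statistics) and mean/SD (n−1); display rounding
is half-up to whole minutes. Annual projection multiplies the all-visit-type
per-visit mean by the arm's annual visit count (4 or 2). The wage-weighted
personnel cost of a visit is Σ over activities of (minutes/60) × (cadre
annual salary / 2,080 annual work hours).

## Parameters that matter

| parameter | default | unit | notes |
|---|---|---|---|
| discount rate | 0.03 | /yr | annuitization of one-off costs |
| inflation rate | 0.044 | /yr | applied only to pre-2019 amounts; fixture amounts are already inflation-adjusted |
| annual work hours | 2,080 | h | wage denominator (231 weekdays/yr also recorded) |
| visits per client-year | 4 (SOC), 2 (intervention) | visits | annual projection multiplier |
| bottles per visit | 3 (SOC), 6 (intervention) | bottles | links visits to client-months for derived accruals |
| HIVST kits per visit | 2 | kits | intervention arm only |
| accruals | 304/913, 340/2,039 | visits / client-months | study volumes; 2,952 client-months total |

## Calibrated fixture values

The shipped ledgers reproduce the published cost tables to the cent, which
requires three families of calibrated values because the underlying expense
reports are not public:

* **Per-visit clinical personnel rates** (e.g. $24.8020/visit, SOC trial).
  The published personnel totals are several times larger than the product
  of observed activity minutes and hourly wages — they evidently include
  indirect and non-contact staff time that the source does not itemize — so
  the fixtures carry back-solved per-visit rates. Ledgers without such lines
  use the mechanistic wage × observed-minutes route (this is how the
  monotone salary-response and synthetic end-to-end tests work).
* **Laboratory consumable residuals** per visit, on top of the rapid-test
  and HIVST built-ins.
* **Procurement-inclusive drug prices** per arm ($7.1711610 and $7.1045611
  per client-month vs the $6.75 ex-works bottle price), since procurement,
  warehousing and distribution mark-ups are included but not printed —
  and the two arms' published drug totals imply slightly different rates.

Supervision is entered arm-specifically rather than pooled: the published
per-arm supervision rows imply a ~0.49 SOC share, incompatible with the
0.472 visit-share rule that fits the other four fixed categories to ~0.1%.
The visit-share allocation property is therefore asserted (at 0.5%) for the
four categories that follow it.

The public-clinic ("MOH") scenario without creatinine testing has no
published category breakdown, only unit costs ($14.76 / $11.94). Its fixture
equals the published with-creatinine table minus a creatinine add-on modeled
as $2.82 per test (kit $2.51 + bench consumables) twice per client-year plus
$2.82 per visit for specimen collection and handling; the two rates are
solved from the published with/without unit-cost pairs (a per-test-only model
cannot fit both arms). Applying `creatinine_addon()` to the base MOH ledger
reproduces the with-creatinine table to the cent.

## Synthetic data

`generate_observation_log` emulates the observation protocol: per visit, an
initial waiting period then counselling, examination, laboratory and
dispensing in sequence, with non-overlapping timestamps. Durations default
to a normal truncated at zero (resampling) with the published refill
means/SDs per arm — SOC 27/17/3/7 min (total 54), intervention 32/18/5/21
(total 76) — and pooled enrollment means 33/20/5/21; a moment-matched
lognormal is available for robustness checks. Default sample sizes mirror
the study (9 + 13 visits, 6 enrollments). Waiting time (mean 15, SD 5 min)
and enrollment SDs are not published and are set to realistic values; they
never enter costs. All draws flow through an explicit NumPy PCG64 seed.

What the generator does **not** emulate: correlation of durations within a
visit or provider, day-of-week/queueing effects, inter-observer error, and
client retention or discontinuation dynamics. Passing tests therefore
demonstrate correctness of the costing arithmetic and statistical summaries
under the stated distributional assumptions, not robustness of the published
estimates to real-world clinic heterogeneity.

## Numerical choices

* Money: `decimal.Decimal` throughout (28-digit context); half-even (banker's)
  rounding to cents at category/report boundaries; shares displayed half-up
  as whole percents; durations displayed half-up as whole minutes.
* Arm comparison: difference = SOC − intervention unit cost, percent
  difference uses the SOC unit cost as denominator.
* Fixed-allocation residual cent goes to the arm with more visits.
* Degenerate inputs: zero-rate annuity is the exact `n`-year limit (continuous
  to within 1e−6 at r = 1e−12); one-observation strata report median = mean
  with an undefined SD; a visit with only waiting has zero provider time;
  empty strata, zero client-months, zero total visits and all-zero ledgers
  raise rather than return NaNs.
* Problem sizes: tests and the acceptance script run the full study-size
  ledgers (20 items, 644 visits, 2,952 client-months) and synthetic logs of
  up to 500 visits per arm; the whole suite completes in well under a minute.

## Known limitations

* Client-perspective costs (travel, time off work), pregnancy/STI testing,
  cost-effectiveness and budget-impact modelling are out of scope.
* The calibrated per-visit personnel rates absorb whatever indirect-time
  convention produced the published personnel totals; they should be
  re-derived, not reused, for other settings.
* Accrued client-months may slightly exceed visits × bottles (the study's
  own SOC volumes do: 913 > 304 × 3), so that bound is enforced only for
  accruals derived from visit counts.
* Published medians/IQRs are not exactly recoverable without the raw
  observation logs; they are validated through synthetic parameter recovery
  (each mean within 3 SE at n = 500/arm), not exact assertion.
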