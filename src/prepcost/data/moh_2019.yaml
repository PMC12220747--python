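# Projected public-clinic (Ministry of Health) delivery scenario without
# serum creatinine testing, 2019 USD.  The published category table covers
# the with-creatinine variant; these base amounts are that table minus the
# calibrated creatinine add-on (kit + consumables 2.82/test twice per
# client-year; specimen collection 2.82/visit), and reproduce the published
# without-creatinine unit costs of 14.76 / 11.94 per client-month.
scenario_tag: moh
economic_params:
  exchange_rate_kes_per_usd: "105.50"
  inflation_rate: "0.044"
  discount_rate: "0.03"
  annual_work_hours: "2080"
  weekdays_per_year: 231
salaries:
  - {cadre: hiv_testing_counsellor, annual_salary: {amount: "9365", currency: USD}, scenario_tag: trial}
  - {cadre: clinical_officer, annual_salary: {amount: "10841", currency: USD}, scenario_tag: trial}
  - {cadre: nurse, annual_salary: {amount: "9984", currency: USD}, scenario_tag: trial}
  - {cadre: pharmacy_technologist, annual_salary: {amount: "10085", currency: USD}, scenario_tag: trial}
  - {cadre: hiv_testing_counsellor, annual_salary: {amount: "3226", currency: USD}, scenario_tag: moh}
  - {cadre: clinical_officer, annual_salary: {amount: "7290", currency: USD}, scenario_tag: moh}
  - {cadre: nurse, annual_salary: {amount: "6101", currency: USD}, scenario_tag: moh}
  - {cadre: pharmacy_technologist, annual_salary: {amount: "6001", currency: USD}, scenario_tag: moh}
unit_prices:
  - {item: prep_30day, price: {amount: "6.75", currency: USD}}
  - {item: oraquick_hivst, price: {amount: "4.27", currency: USD}}
  - {item: atomo_hivst, price: {amount: "6.17", currency: USD}}
  - {item: determine_rapid_test, price: {amount: "0.83", currency: USD}}
  - {item: creatinine_test, price: {amount: "2.51", currency: USD}}
items:
  # variable
  - name: clinical personnel time per visit (soc, calibrated)
    category: personnel_clinical
    cost_class: variable
    amount: {amount: "12.50066", currency: USD}
    basis: per_visit
    arm: soc
  - name: clinical personnel time per visit (intervention, calibrated)
    category: personnel_clinical
    cost_class: variable
    amount: {amount: "9.49215", currency: USD}
    basis: per_visit
    arm: intervention
  - name: PrEP 30-day bottle, procurement-inclusive (soc)
    category: prep_drugs
    cost_class: variable
    amount: {amount: "7.1711610", currency: USD}
    basis: per_client_month
    arm: soc
  - name: PrEP 30-day bottle, procurement-inclusive (intervention)
    category: prep_drugs
    cost_class: variable
    amount: {amount: "7.1045611", currency: USD}
    basis: per_client_month
    arm: intervention
  - name: laboratory consumables per visit (soc, residual)
    category: laboratory
    cost_class: variable
    amount: {amount: "3.20901", currency: USD}
    basis: per_visit
    arm: soc
  - name: laboratory consumables per visit (intervention, residual)
    category: laboratory
    cost_class: variable
    amount: {amount: "2.38171", currency: USD}
    basis: per_visit
    arm: intervention
  - name: recurrent refresher training (soc)
    category: recurrent_training
    cost_class: variable
    amount: {amount: "89.24", currency: USD}
    basis: per_year
    arm: soc
  - name: recurrent refresher training (intervention)
    category: recurrent_training
    cost_class: variable
    amount: {amount: "99.60", currency: USD}
    basis: per_year
    arm: intervention
  - name: clinic supplies (soc)
    category: supplies
    cost_class: variable
    amount: {amount: "376.32", currency: USD}
    basis: per_year
    arm: soc
  - name: clinic supplies (intervention)
    category: supplies
    cost_class: variable
    amount: {amount: "324.26", currency: USD}
    basis: per_year
    arm: intervention
  # fixed (annualized, arm-specific)
  - name: start-up microplanning (soc)
    category: startup_microplanning
    cost_class: fixed
    amount: {amount: "79.31", currency: USD}
    basis: per_year
    arm: soc
  - name: start-up microplanning (intervention)
    category: startup_microplanning
    cost_class: fixed
    amount: {amount: "88.53", currency: USD}
    basis: per_year
    arm: intervention
  - name: supervision personnel (soc)
    category: personnel_supervision
    cost_class: fixed
    amount: {amount: "277.32", currency: USD}
    basis: per_year
    arm: soc
  - name: supervision personnel (intervention)
    category: personnel_supervision
    cost_class: fixed
    amount: {amount: "274.56", currency: USD}
    basis: per_year
    arm: intervention
  - name: capital and equipment (soc)
    category: capital
    cost_class: fixed
    amount: {amount: "375.06", currency: USD}
    basis: per_year
    arm: soc
  - name: capital and equipment (intervention)
    category: capital
    cost_class: fixed
    amount: {amount: "418.64", currency: USD}
    basis: per_year
    arm: intervention
  - name: overheads (soc)
    category: overhead
    cost_class: fixed
    amount: {amount: "468.96", currency: USD}
    basis: per_year
    arm: soc
  - name: overheads (intervention)
    category: overhead
    cost_class: fixed
    amount: {amount: "523.45", currency: USD}
    basis: per_year
    arm: intervention
  - name: start-up training (soc)
    category: startup_training
    cost_class: fixed
    amount: {amount: "235.35", currency: USD}
    basis: per_year
    arm: soc
  - name: start-up training (intervention)
    category: startup_training
    cost_class: fixed
    amount: {amount: "262.70", currency: USD}
    basis: per_year
    arm: intervention
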