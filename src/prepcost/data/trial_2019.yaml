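# As-implemented (research clinic) delivery scenario, 2019 USD.
# Per-visit personnel rates, laboratory consumable residuals and
# procurement-inclusive drug prices are calibrated to the published annual
# category totals (see package docs); list prices appear under unit_prices.
scenario_tag: trial
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
    amount: {amount: "24.8020", currency: USD}
    basis: per_visit
    arm: soc
  - name: clinical personnel time per visit (intervention, calibrated)
    category: personnel_clinical
    cost_class: variable
    amount: {amount: "22.8674", currency: USD}
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
    amount: {amount: "5.13352", currency: USD}
    basis: per_visit
    arm: soc
  - name: laboratory consumables per visit (intervention, residual)
    category: laboratory
    cost_class: variable
    amount: {amount: "5.71227", currency: USD}
    basis: per_visit
    arm: intervention
  - name: recurrent refresher training (soc)
    category: recurrent_training
    cost_class: variable
    amount: {amount: "2398.93", currency: USD}
    basis: per_year
    arm: soc
  - name: recurrent refresher training (intervention)
    category: recurrent_training
    cost_class: variable
    amount: {amount: "2677.64", currency: USD}
    basis: per_year
    arm: intervention
  - name: clinic supplies (soc)
    category: supplies
    cost_class: variable
    amount: {amount: "315.98", currency: USD}
    basis: per_year
    arm: soc
  - name: clinic supplies (intervention)
    category: supplies
    cost_class: variable
    amount: {amount: "308.13", currency: USD}
    basis: per_year
    arm: intervention
  # fixed (annualized, arm-specific)
  - name: start-up microplanning (soc)
    category: startup_microplanning
    cost_class: fixed
    amount: {amount: "2013.09", currency: USD}
    basis: per_year
    arm: soc
  - name: start-up microplanning (intervention)
    category: startup_microplanning
    cost_class: fixed
    amount: {amount: "2246.98", currency: USD}
    basis: per_year
    arm: intervention
  - name: supervision personnel (soc)
    category: personnel_supervision
    cost_class: fixed
    amount: {amount: "1035.62", currency: USD}
    basis: per_year
    arm: soc
  - name: supervision personnel (intervention)
    category: personnel_supervision
    cost_class: fixed
    amount: {amount: "1067.04", currency: USD}
    basis: per_year
    arm: intervention
  - name: capital and equipment (soc)
    category: capital
    cost_class: fixed
    amount: {amount: "707.62", currency: USD}
    basis: per_year
    arm: soc
  - name: capital and equipment (intervention)
    category: capital
    cost_class: fixed
    amount: {amount: "789.83", currency: USD}
    basis: per_year
    arm: intervention
  - name: overheads (soc)
    category: overhead
    cost_class: fixed
    amount: {amount: "580.01", currency: USD}
    basis: per_year
    arm: soc
  - name: overheads (intervention)
    category: overhead
    cost_class: fixed
    amount: {amount: "647.40", currency: USD}
    basis: per_year
    arm: intervention
  - name: start-up training (soc)
    category: startup_training
    cost_class: fixed
    amount: {amount: "333.50", currency: USD}
    basis: per_year
    arm: soc
  - name: start-up training (intervention)
    category: startup_training
    cost_class: fixed
    amount: {amount: "372.24", currency: USD}
    basis: per_year
    arm: intervention
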