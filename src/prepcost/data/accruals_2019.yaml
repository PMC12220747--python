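# Annual PrEP service volumes by arm (644 clinic visits and 2,952 dispensed
# client-months in total over the costed year).
accruals:
  - arm: soc
    annual_visits: 304
    prep_client_months: 913
    visits_per_client_year: 4
    bottles_per_visit: 3
  - arm: intervention
    annual_visits: 340
    prep_client_months: 2039
    visits_per_client_year: 2
    bottles_per_visit: 6
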