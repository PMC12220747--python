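{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "prepcost ledger document",
  "type": "object",
  "required": ["economic_params", "salaries", "unit_prices", "items"],
  "properties": {
    "scenario_tag": {"type": "string"},
    "economic_params": {
      "type": "object",
      "properties": {
        "exchange_rate_kes_per_usd": {"$ref": "#/$defs/decimal"},
        "inflation_rate": {"$ref": "#/$defs/decimal"},
        "discount_rate": {"$ref": "#/$defs/decimal"},
        "annual_work_hours": {"$ref": "#/$defs/decimal"},
        "weekdays_per_year": {"type": "integer", "minimum": 1}
      }
    },
    "salaries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["cadre", "annual_salary", "scenario_tag"],
        "properties": {
          "cadre": {
            "enum": ["hiv_testing_counsellor", "clinical_officer", "nurse", "pharmacy_technologist"]
          },
          "annual_salary": {"$ref": "#/$defs/money"},
          "scenario_tag": {"type": "string"}
        }
      }
    },
    "unit_prices": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["item", "price"],
        "properties": {
          "item": {
            "enum": ["prep_30day", "oraquick_hivst", "atomo_hivst", "determine_rapid_test", "creatinine_test"]
          },
          "price": {"$ref": "#/$defs/money"}
        }
      }
    },
    "items": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "category", "cost_class", "amount", "basis"],
        "properties": {
          "name": {"type": "string"},
          "category": {
            "enum": [
              "personnel_clinical", "prep_drugs", "laboratory", "recurrent_training",
              "supplies", "startup_microplanning", "personnel_supervision", "capital",
              "overhead", "startup_training"
            ]
          },
          "cost_class": {"enum": ["fixed", "variable"]},
          "amount": {"$ref": "#/$defs/money"},
          "basis": {"enum": ["per_year", "per_visit", "per_client_month", "per_client_year", "one_off"]},
          "arm": {"enum": ["soc", "intervention"]},
          "useful_life_years": {"type": "integer", "minimum": 1, "maximum": 5}
        }
      }
    }
  },
  "$defs": {
    "decimal": {"type": ["string", "number"]},
    "money": {
      "type": "object",
      "required": ["amount"],
      "properties": {
        "amount": {"type": ["string", "number"], "description": "decimal amount; quote to preserve precision"},
        "currency": {"enum": ["USD", "KES"], "default": "USD"}
      }
    }
  }
}
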