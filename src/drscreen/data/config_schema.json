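{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "drscreen configuration document",
  "type": "object",
  "required": ["settings", "mortality", "parameters"],
  "properties": {
    "settings": {
      "type": "object",
      "properties": {
        "start_age": {"type": "integer", "minimum": 0},
        "n_cycles": {"type": "integer", "minimum": 1},
        "discount_rate": {"type": "number", "minimum": 0},
        "discount_effects": {"type": "boolean"},
        "half_cycle": {"type": "boolean"},
        "gdp_per_capita": {"type": "number", "exclusiveMinimum": 0},
        "exchange_rate_cny_per_usd": {"type": "number", "exclusiveMinimum": 0},
        "component_shares": {
          "type": "object",
          "additionalProperties": {
            "type": "array",
            "items": {"type": "number", "minimum": 0},
            "minItems": 3,
            "maxItems": 3
          }
        }
      }
    },
    "mortality": {
      "type": "object",
      "required": ["ages", "probs"],
      "properties": {
        "ages": {"type": "array", "items": {"type": "number"}},
        "probs": {
          "type": "array",
          "items": {"type": "number", "minimum": 0, "exclusiveMaximum": 1}
        }
      }
    },
    "parameters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "base", "low", "high"],
        "properties": {
          "name": {"type": "string"},
          "base": {"type": "number"},
          "low": {"type": "number"},
          "high": {"type": "number"},
          "dist": {"enum": ["beta", "gamma", "lognormal", "fixed"]},
          "units": {"type": "string"},
          "provenance": {
            "enum": ["paper-text", "supplement-placeholder", "derived"]
          }
        }
      }
    }
  }
}
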