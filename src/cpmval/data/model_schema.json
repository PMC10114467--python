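{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "https://example.org/cpmval/model_schema.json",
 "title": "cpmval model-definition file",
 "description": "Declarative description of a multinomial/binomial logistic prediction model or an additive risk score. Cross-field invariants (alias uniqueness, age-band coverage, coefficient/term arity) are enforced programmatically on load, beyond what this schema can express.",
 "type": "object",
 "required": ["name", "type"],
 "properties": {
  "name": {"type": "string"},
  "type": {"enum": ["multinomial", "binomial", "risk_score"]},
  "provenance": {"type": "string"},
  "categories": {"type": "array", "items": {"type": "string"}, "minItems": 2},
  "reference": {"type": "string"},
  "terms": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["variable"],
    "properties": {
     "variable": {"type": "string"},
     "transform": {"enum": ["identity", "log", "indicator", "banded"]},
     "level": {},
     "bands": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["age"],
       "properties": {
        "age": {"$ref": "#/$defs/interval"},
        "value": {"$ref": "#/$defs/interval"},
        "output": {"type": "number"}
       }
      }
     }
    }
   }
  },
  "coefficients": {
   "type": "object",
   "additionalProperties": {
    "type": "object",
    "required": ["intercept", "betas"],
    "properties": {
     "intercept": {"type": "number"},
     "betas": {"type": "array", "items": {"type": "number"}}
    }
   }
  },
  "items": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["variable"],
    "properties": {
     "variable": {"type": "string"},
     "points": {"type": "object", "additionalProperties": {"type": "integer", "minimum": 0}},
     "bands": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["age", "intervals"],
       "properties": {
        "age": {"$ref": "#/$defs/interval"},
        "intervals": {
         "type": "array",
         "items": {
          "type": "object",
          "required": ["value", "points"],
          "properties": {
           "value": {"$ref": "#/$defs/interval"},
           "points": {"type": "integer", "minimum": 0}
          }
         }
        }
       }
      }
     }
    }
   }
  },
  "cutoffs": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "op", "value"],
    "properties": {
     "name": {"type": "string"},
     "op": {"enum": ["<=", "<", ">=", ">"]},
     "value": {"type": "number"}
    }
   }
  },
  "age_range": {"$ref": "#/$defs/interval"},
  "age_band_unit": {"enum": ["years", "months"]},
  "schema_ref": {
   "type": ["object", "null"],
   "properties": {
    "variables": {
     "type": "array",
     "items": {
      "type": "object",
      "required": ["name"],
      "properties": {
       "name": {"type": "string"},
       "kind": {"enum": ["binary", "continuous", "categorical"]},
       "units": {"type": "string"},
       "non_deviant_default": {},
       "allowed_range": {"type": ["array", "null"]},
       "aliases": {"type": "array", "items": {"type": "string"}}
      }
     }
    }
   }
  }
 },
 "$defs": {
  "interval": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
 }
}
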