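{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/ccdl/query.schema.json",
  "title": "CCDL feasibility query",
  "description": "Clinical Cohort Definition Language: inclusion criteria in conjunctive normal form, exclusion criteria in disjunctive normal form, combined as inclusion AND NOT exclusion.",
  "type": "object",
  "additionalProperties": false,
  "required": ["version", "inclusionCriteria"],
  "properties": {
    "version": {"type": "string", "minLength": 1, "const": "1.0"},
    "display": {"type": "string"},
    "inclusionCriteria": {
      "type": "array",
      "minItems": 1,
      "items": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/criterion"}}
    },
    "exclusionCriteria": {
      "type": "array",
      "items": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/criterion"}}
    }
  },
  "$defs": {
    "termCode": {
      "type": "object",
      "additionalProperties": false,
      "required": ["system", "code"],
      "properties": {
        "system": {"type": "string", "minLength": 1},
        "code": {"type": "string", "minLength": 1},
        "version": {"type": "string"},
        "display": {"type": "string"}
      }
    },
    "unit": {
      "type": "object",
      "additionalProperties": false,
      "required": ["code"],
      "properties": {
        "code": {"type": "string", "minLength": 1, "description": "UCUM unit code"},
        "display": {"type": "string"}
      }
    },
    "conceptFilter": {
      "type": "object",
      "additionalProperties": false,
      "required": ["type", "selectedConcepts"],
      "properties": {
        "type": {"const": "concept"},
        "selectedConcepts": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/termCode"}}
      }
    },
    "quantityComparatorFilter": {
      "type": "object",
      "additionalProperties": false,
      "required": ["type", "comparator", "value"],
      "properties": {
        "type": {"const": "quantity-comparator"},
        "comparator": {"enum": ["eq", "ne", "lt", "le", "gt", "ge"]},
        "value": {"type": "number"},
        "unit": {"$ref": "#/$defs/unit"}
      }
    },
    "quantityRangeFilter": {
      "type": "object",
      "additionalProperties": false,
      "required": ["type", "minValue", "maxValue"],
      "properties": {
        "type": {"const": "quantity-range"},
        "minValue": {"type": "number"},
        "maxValue": {"type": "number"},
        "unit": {"$ref": "#/$defs/unit"}
      }
    },
    "referenceFilter": {
      "type": "object",
      "additionalProperties": false,
      "required": ["type", "selectedConcepts"],
      "properties": {
        "type": {"const": "reference"},
        "selectedConcepts": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/termCode"}}
      }
    },
    "valueFilter": {
      "oneOf": [
        {"$ref": "#/$defs/conceptFilter"},
        {"$ref": "#/$defs/quantityComparatorFilter"},
        {"$ref": "#/$defs/quantityRangeFilter"}
      ]
    },
    "attributeFilter": {
      "description": "attributeCode plus the members of one filter variant (concept, quantity-comparator, quantity-range, reference), flat.",
      "allOf": [
        {
          "type": "object",
          "required": ["attributeCode", "type"],
          "properties": {"attributeCode": {"$ref": "#/$defs/termCode"}}
        },
        {
          "oneOf": [
            {
              "type": "object",
              "properties": {
                "attributeCode": true,
                "type": {"const": "concept"},
                "selectedConcepts": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/termCode"}}
              },
              "required": ["selectedConcepts"],
              "additionalProperties": false
            },
            {
              "type": "object",
              "properties": {
                "attributeCode": true,
                "type": {"const": "quantity-comparator"},
                "comparator": {"enum": ["eq", "ne", "lt", "le", "gt", "ge"]},
                "value": {"type": "number"},
                "unit": {"$ref": "#/$defs/unit"}
              },
              "required": ["comparator", "value"],
              "additionalProperties": false
            },
            {
              "type": "object",
              "properties": {
                "attributeCode": true,
                "type": {"const": "quantity-range"},
                "minValue": {"type": "number"},
                "maxValue": {"type": "number"},
                "unit": {"$ref": "#/$defs/unit"}
              },
              "required": ["minValue", "maxValue"],
              "additionalProperties": false
            },
            {
              "type": "object",
              "properties": {
                "attributeCode": true,
                "type": {"const": "reference"},
                "selectedConcepts": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/termCode"}}
              },
              "required": ["selectedConcepts"],
              "additionalProperties": false
            }
          ]
        }
      ]
    },
    "timeRestriction": {
      "type": "object",
      "additionalProperties": false,
      "minProperties": 1,
      "properties": {
        "afterDate": {"type": "string", "format": "date"},
        "beforeDate": {"type": "string", "format": "date"}
      }
    },
    "criterion": {
      "type": "object",
      "additionalProperties": false,
      "required": ["termCodes"],
      "properties": {
        "context": {"$ref": "#/$defs/termCode"},
        "termCodes": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/termCode"}},
        "valueFilter": {"$ref": "#/$defs/valueFilter"},
        "attributeFilters": {"type": "array", "items": {"$ref": "#/$defs/attributeFilter"}},
        "timeRestriction": {"$ref": "#/$defs/timeRestriction"}
      }
    }
  }
}
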