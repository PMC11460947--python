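{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "seedwind/diagnosis.schema.json",
  "title": "TaxonDiagnosis",
  "description": "Serialised taxon diagnosis: numeric trait ranges and categorical characters for a winged-ovule taxon.",
  "type": "object",
  "required": ["taxon", "numeric_traits", "categorical_traits"],
  "properties": {
    "taxon": {"type": "string", "minLength": 1},
    "numeric_traits": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "min", "max", "units"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "min": {"type": "number"},
          "max": {"type": "number"},
          "units": {"enum": ["mm", "fraction", "degrees", "count"]},
          "inclusive_min": {"type": "boolean", "default": true},
          "approximate": {"type": "boolean", "default": false}
        },
        "additionalProperties": false
      }
    },
    "categorical_traits": {
      "type": "object",
      "required": ["wing_count"],
      "properties": {
        "wing_count": {"type": "integer", "minimum": 1},
        "cupule": {"enum": ["present", "absent", "unknown"]},
        "attachment": {"enum": ["terminal", "unknown"]},
        "wing_folding": {"enum": ["inward-abaxial", "flat", "unknown"]},
        "distal_wing_curvature": {"enum": ["outward", "inward", "straight", "unknown"]}
      }
    }
  },
  "additionalProperties": false
}
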