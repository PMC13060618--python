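{
  "$defs": {
    "CoverageInfo": {
      "properties": {
        "gaussian_iam": {
          "minimum": 0,
          "title": "Gaussian Iam",
          "type": "integer"
        },
        "multipolar": {
          "minimum": 0,
          "title": "Multipolar",
          "type": "integer"
        },
        "multipolar_coverage": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Multipolar Coverage",
          "type": "number"
        },
        "n_atoms": {
          "minimum": 0,
          "title": "N Atoms",
          "type": "integer"
        },
        "spherical_slater": {
          "minimum": 0,
          "title": "Spherical Slater",
          "type": "integer"
        }
      },
      "required": [
        "n_atoms",
        "multipolar",
        "spherical_slater",
        "gaussian_iam",
        "multipolar_coverage"
      ],
      "title": "CoverageInfo",
      "type": "object"
    }
  },
  "properties": {
    "bank_path": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Bank Path"
    },
    "command": {
      "title": "Command",
      "type": "string"
    },
    "coverage": {
      "anyOf": [
        {
          "$ref": "#/$defs/CoverageInfo"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "d_min": {
      "anyOf": [
        {
          "exclusiveMinimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "D Min"
    },
    "extra": {
      "additionalProperties": true,
      "default": {},
      "title": "Extra",
      "type": "object"
    },
    "mode": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mode"
    },
    "model_path": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Model Path"
    },
    "outputs": {
      "default": [],
      "items": {
        "type": "string"
      },
      "title": "Outputs",
      "type": "array"
    },
    "radiation": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Radiation"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "table_dialect": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Table Dialect"
    }
  },
  "required": [
    "command"
  ],
  "title": "RunManifest",
  "type": "object"
}
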