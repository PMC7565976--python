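{
  "$defs": {
    "FitReport": {
      "properties": {
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "covariate_effects": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Covariate Effects",
          "type": "object"
        },
        "eff_mean": {
          "title": "Eff Mean",
          "type": "number"
        },
        "gamma": {
          "title": "Gamma",
          "type": "number"
        },
        "k_growth_mean": {
          "title": "K Growth Mean",
          "type": "number"
        },
        "loglik": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Loglik"
        },
        "loglik_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Loglik Se"
        },
        "n_animals": {
          "title": "N Animals",
          "type": "integer"
        },
        "n_obs": {
          "title": "N Obs",
          "type": "integer"
        },
        "omega_eff": {
          "title": "Omega Eff",
          "type": "number"
        },
        "omega_k": {
          "title": "Omega K",
          "type": "number"
        },
        "omega_vmax": {
          "title": "Omega Vmax",
          "type": "number"
        },
        "sigma_add": {
          "title": "Sigma Add",
          "type": "number"
        },
        "sigma_prop": {
          "title": "Sigma Prop",
          "type": "number"
        },
        "v_max_mean": {
          "title": "V Max Mean",
          "type": "number"
        }
      },
      "required": [
        "k_growth_mean",
        "omega_k",
        "v_max_mean",
        "omega_vmax",
        "eff_mean",
        "omega_eff",
        "gamma",
        "sigma_prop",
        "sigma_add",
        "covariate_effects",
        "converged",
        "n_animals",
        "n_obs"
      ],
      "title": "FitReport",
      "type": "object"
    },
    "HillReport": {
      "properties": {
        "ec50": {
          "title": "Ec50",
          "type": "number"
        },
        "hill_n": {
          "title": "Hill N",
          "type": "number"
        },
        "n_points": {
          "title": "N Points",
          "type": "integer"
        },
        "residual_sse": {
          "title": "Residual Sse",
          "type": "number"
        },
        "top": {
          "title": "Top",
          "type": "number"
        }
      },
      "required": [
        "ec50",
        "hill_n",
        "top",
        "residual_sse",
        "n_points"
      ],
      "title": "HillReport",
      "type": "object"
    },
    "LRTReport": {
      "properties": {
        "arms": {
          "items": {
            "type": "string"
          },
          "title": "Arms",
          "type": "array"
        },
        "df": {
          "title": "Df",
          "type": "integer"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "parameter": {
          "title": "Parameter",
          "type": "string"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        }
      },
      "required": [
        "parameter",
        "arms",
        "statistic",
        "df",
        "p_value"
      ],
      "title": "LRTReport",
      "type": "object"
    },
    "SurvivalReport": {
      "properties": {
        "group_a": {
          "title": "Group A",
          "type": "string"
        },
        "group_b": {
          "title": "Group B",
          "type": "string"
        },
        "method": {
          "title": "Method",
          "type": "string"
        },
        "n_a": {
          "title": "N A",
          "type": "integer"
        },
        "n_b": {
          "title": "N B",
          "type": "integer"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "statistic": {
          "title": "Statistic",
          "type": "number"
        }
      },
      "required": [
        "group_a",
        "group_b",
        "statistic",
        "p_value",
        "n_a",
        "n_b",
        "method"
      ],
      "title": "SurvivalReport",
      "type": "object"
    }
  },
  "description": "Top-level pipeline report; serialized as sorted-key JSON.",
  "properties": {
    "fit": {
      "anyOf": [
        {
          "$ref": "#/$defs/FitReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "hill": {
      "anyOf": [
        {
          "$ref": "#/$defs/HillReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "lrt": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/LRTReport"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Lrt"
    },
    "outputs": {
      "additionalProperties": {
        "type": "string"
      },
      "default": {},
      "title": "Outputs",
      "type": "object"
    },
    "scenario": {
      "title": "Scenario",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "survival": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/SurvivalReport"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Survival"
    },
    "version": {
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "scenario",
    "seed",
    "version"
  ],
  "title": "Report",
  "type": "object"
}
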