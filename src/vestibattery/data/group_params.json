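{
  "group_sizes": {"PPPD": 92, "CDA": 44, "UVH": 31, "UD": 37, "OTHER": 27},
  "items": {
    "age": {
      "kind": "integer", "range": [0, 110], "block": "demographics",
      "groups": {
        "PPPD": {"mean": 48.3, "sd": 15.2, "n": 92},
        "CDA": {"mean": 42.4, "sd": 18.9, "n": 44},
        "UVH": {"mean": 63.5, "sd": 13.3, "n": 31},
        "UD": {"mean": 60.2, "sd": 19.7, "n": 37}
      }
    },
    "HADS_anxiety": {
      "kind": "integer", "range": [0, 21], "block": "hads",
      "groups": {
        "PPPD": {"mean": 9.18, "sd": 4.70, "n": 87},
        "CDA": {"mean": 11.15, "sd": 5.89, "n": 34},
        "UVH": {"mean": 6.04, "sd": 3.85, "n": 25},
        "UD": {"mean": 6.19, "sd": 3.53, "n": 28}
      }
    },
    "HADS_depression": {
      "kind": "integer", "range": [0, 21], "block": "hads",
      "groups": {
        "PPPD": {"mean": 8.31, "sd": 4.18, "n": 87},
        "CDA": {"mean": 8.88, "sd": 3.12, "n": 34},
        "UVH": {"mean": 7.76, "sd": 3.93, "n": 25},
        "UD": {"mean": 6.75, "sd": 3.64, "n": 28}
      }
    },
    "DHI_physical": {
      "kind": "even_integer", "range": [0, 28], "block": "dhi",
      "groups": {
        "PPPD": {"mean": 15.75, "sd": 6.00, "n": 87},
        "CDA": {"mean": 12.29, "sd": 6.79, "n": 34},
        "UVH": {"mean": 12.08, "sd": 5.97, "n": 26},
        "UD": {"mean": 10.00, "sd": 5.42, "n": 28}
      }
    },
    "DHI_emotional": {
      "kind": "even_integer", "range": [0, 36], "block": "dhi",
      "groups": {
        "PPPD": {"mean": 19.36, "sd": 8.22, "n": 87},
        "CDA": {"mean": 17.29, "sd": 8.75, "n": 34},
        "UVH": {"mean": 14.85, "sd": 6.48, "n": 26},
        "UD": {"mean": 14.43, "sd": 8.19, "n": 28}
      }
    },
    "DHI_functional": {
      "kind": "even_integer", "range": [0, 36], "block": "dhi",
      "groups": {
        "PPPD": {"mean": 19.26, "sd": 9.50, "n": 87},
        "CDA": {"mean": 17.94, "sd": 9.31, "n": 34},
        "UVH": {"mean": 14.08, "sd": 8.49, "n": 26},
        "UD": {"mean": 11.64, "sd": 8.96, "n": 28}
      }
    },
    "NPQ_upright": {
      "kind": "integer", "range": [0, 24], "block": "npq",
      "groups": {
        "PPPD": {"mean": 11.86, "sd": 5.78, "n": 77},
        "CDA": {"mean": 10.05, "sd": 6.89, "n": 20},
        "UVH": {"mean": 7.13, "sd": 5.11, "n": 15},
        "UD": {"mean": 9.07, "sd": 5.69, "n": 15}
      }
    },
    "NPQ_movement": {
      "kind": "integer", "range": [0, 24], "block": "npq",
      "groups": {
        "PPPD": {"mean": 12.94, "sd": 4.84, "n": 77},
        "CDA": {"mean": 10.95, "sd": 6.06, "n": 20},
        "UVH": {"mean": 7.40, "sd": 4.12, "n": 15},
        "UD": {"mean": 8.93, "sd": 5.43, "n": 15}
      }
    },
    "NPQ_visual": {
      "kind": "integer", "range": [0, 24], "block": "npq",
      "groups": {
        "PPPD": {"mean": 13.05, "sd": 5.21, "n": 77},
        "CDA": {"mean": 9.90, "sd": 6.94, "n": 20},
        "UVH": {"mean": 5.27, "sd": 4.08, "n": 15},
        "UD": {"mean": 6.20, "sd": 4.78, "n": 15}
      }
    },
    "CP_percent": {
      "kind": "continuous", "range": [0, 100], "block": "caloric",
      "groups": {
        "PPPD": {"mean": 20.17, "sd": 19.59, "n": 83},
        "CDA": {"mean": 16.57, "sd": 22.82, "n": 34},
        "UVH": {"mean": 51.81, "sd": 32.38, "n": 23},
        "UD": {"mean": 14.94, "sd": 15.25, "n": 30}
      }
    },
    "DP_percent": {
      "kind": "continuous", "range": [0, 100], "block": "caloric",
      "groups": {
        "PPPD": {"mean": 15.20, "sd": 14.55, "n": 83},
        "CDA": {"mean": 10.17, "sd": 11.98, "n": 34},
        "UVH": {"mean": 17.98, "sd": 14.54, "n": 23},
        "UD": {"mean": 15.53, "sd": 11.53, "n": 30}
      }
    },
    "cvemp_iaar": {
      "kind": "continuous", "range": [-100, 100], "block": "cvemp",
      "groups": {
        "PPPD": {"mean": 5.52, "sd": 33.87, "n": 89},
        "CDA": {"mean": 10.56, "sd": 34.44, "n": 43},
        "UVH": {"mean": 20.69, "sd": 38.70, "n": 24},
        "UD": {"mean": 1.62, "sd": 46.80, "n": 28}
      }
    },
    "ovemp_iaar": {
      "kind": "continuous", "range": [-100, 100], "block": "ovemp",
      "groups": {
        "PPPD": {"mean": -1.30, "sd": 31.92, "n": 91},
        "CDA": {"mean": -4.13, "sd": 25.38, "n": 43},
        "UVH": {"mean": -1.27, "sd": 44.20, "n": 24},
        "UD": {"mean": -5.12, "sd": 38.37, "n": 28}
      }
    },
    "foam_ratio": {
      "kind": "continuous", "range": [0.1, 15], "block": "posturography",
      "groups": {
        "PPPD": {"mean": 2.05, "sd": 0.61, "n": 85},
        "CDA": {"mean": 1.95, "sd": 0.53, "n": 35},
        "UVH": {"mean": 2.40, "sd": 1.29, "n": 23},
        "UD": {"mean": 2.18, "sd": 0.64, "n": 30}
      }
    },
    "romberg_ratio_foam": {
      "kind": "continuous", "range": [0.1, 25], "block": "posturography",
      "groups": {
        "PPPD": {"mean": 1.85, "sd": 0.59, "n": 85},
        "CDA": {"mean": 1.82, "sd": 0.55, "n": 35},
        "UVH": {"mean": 2.00, "sd": 0.64, "n": 23},
        "UD": {"mean": 2.51, "sd": 3.40, "n": 30}
      }
    },
    "vor_dp_percent": {
      "kind": "continuous", "range": [-100, 100], "block": "rotatory",
      "groups": {
        "PPPD": {"mean": 3.85, "sd": 17.79, "n": 87},
        "CDA": {"mean": -1.69, "sd": 15.85, "n": 41},
        "UVH": {"mean": 1.66, "sd": 25.75, "n": 28},
        "UD": {"mean": -0.50, "sd": 14.07, "n": 36}
      }
    }
  },
  "derived_totals": {
    "HADS_total": {
      "components": ["HADS_anxiety", "HADS_depression"],
      "targets": {
        "PPPD": {"mean": 17.49, "sd": 7.98, "n": 87},
        "CDA": {"mean": 19.2, "sd": 6.61, "n": 34},
        "UVH": {"mean": 13.80, "sd": 7.26, "n": 25},
        "UD": {"mean": 13.04, "sd": 5.99, "n": 28}
      }
    },
    "DHI_total": {
      "components": ["DHI_physical", "DHI_emotional", "DHI_functional"],
      "targets": {
        "PPPD": {"mean": 54.37, "sd": 20.80, "n": 87},
        "CDA": {"mean": 44.82, "sd": 21.56, "n": 34},
        "UVH": {"mean": 41.00, "sd": 17.29, "n": 26},
        "UD": {"mean": 36.07, "sd": 19.76, "n": 28}
      }
    },
    "NPQ_total": {
      "components": ["NPQ_upright", "NPQ_movement", "NPQ_visual"],
      "targets": {
        "PPPD": {"mean": 37.70, "sd": 13.51, "n": 77},
        "CDA": {"mean": 30.90, "sd": 18.00, "n": 20},
        "UVH": {"mean": 19.80, "sd": 9.95, "n": 15},
        "UD": {"mean": 24.20, "sd": 14.90, "n": 15}
      }
    }
  },
  "vhit": {
    "subcohort_sizes": {"PPPD": 56, "UVH": 6},
    "gain_range": [0.01, 2.0],
    "gain_better": {
      "PPPD": {"mean": 0.98, "sd": 1.53},
      "UVH": {"mean": 0.89, "sd": 0.36}
    },
    "gain_worse": {
      "PPPD": {"mean": 0.82, "sd": 0.19},
      "UVH": {"mean": 0.67, "sd": 0.31}
    },
    "cus_rate": {"PPPD": 0.017857142857142856, "UVH": 0.5},
    "low_gain_rate": {"PPPD": 0.125, "UVH": 0.3333333333333333},
    "low_gain_threshold": 0.6
  },
  "caloric_total": {"mean": 60.0, "sd": 20.0, "range": [5.0, 150.0]},
  "other_stratum": {"age_mean": 52.0, "age_sd": 20.0, "age_range": [10, 90]}
}
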