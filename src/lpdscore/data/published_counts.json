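{
  "_provenance": "Hand-transcribed summary counts for the published 125-patient ocular adnexal LPD cohort (54 RFH / 28 ALH / 43 MALToma) from the source clinical study; per-subject data were not available, so only the printed group-level counts, means, SDs and ranges are stored.",
  "groups": ["RFH", "ALH", "MALToma"],
  "n": {"RFH": 54, "ALH": 28, "MALToma": 43},
  "age": {
    "RFH": {"mean": 55.92, "sd": 12.85, "min": 13, "max": 82},
    "ALH": {"mean": 60.44, "sd": 12.99, "min": 23, "max": 77},
    "MALToma": {"mean": 64.95, "sd": 12.16, "min": 35, "max": 93}
  },
  "duration_months_range": {
    "RFH": [0.5, 360],
    "ALH": [1, 120],
    "MALToma": [1, 240]
  },
  "sex": {
    "female": {"RFH": 28, "ALH": 9, "MALToma": 9},
    "male": {"RFH": 26, "ALH": 19, "MALToma": 34}
  },
  "laterality": {
    "unilateral": {"RFH": 32, "ALH": 24, "MALToma": 38},
    "bilateral": {"RFH": 22, "ALH": 4, "MALToma": 5}
  },
  "sites": {
    "orbital_soft_tissue": {"RFH": 32, "ALH": 25, "MALToma": 41},
    "conjunctiva": {"RFH": 0, "ALH": 2, "MALToma": 8},
    "lachrymal_gland": {"RFH": 31, "ALH": 8, "MALToma": 6},
    "extraocular_muscle": {"RFH": 14, "ALH": 11, "MALToma": 12},
    "other": {"RFH": 5, "ALH": 2, "MALToma": 2}
  },
  "symptoms": {
    "periorbital_swelling": {"RFH": 40, "ALH": 22, "MALToma": 35},
    "proptosis": {"RFH": 46, "ALH": 22, "MALToma": 37},
    "impaired_vision": {"RFH": 3, "ALH": 1, "MALToma": 8},
    "epiphora": {"RFH": 2, "ALH": 1, "MALToma": 4},
    "pain": {"RFH": 1, "ALH": 1, "MALToma": 1},
    "motility_impairment": {"RFH": 4, "ALH": 0, "MALToma": 10},
    "ptosis": {"RFH": 2, "ALH": 1, "MALToma": 5}
  },
  "overall": {
    "total_n": 125,
    "orbital_soft_tissue_any": 98,
    "multi_compartment": 59,
    "periorbital_swelling": 97,
    "proptosis": 105
  },
  "clonality": {
    "tested": {"RFH": 35, "ALH": 17, "MALToma": 21},
    "clonal": {"RFH": 0, "ALH": 8, "MALToma": 18},
    "qc_failed_total": 52
  },
  "printed_p": {
    "age": {"overall": "0.002", "RFH&ALH": "0.199", "RFH&MALToma": "< 0.001", "ALH&MALToma": "0.065"},
    "sex": {"overall": "0.006", "RFH&ALH": "0.089", "RFH&MALToma": "0.002", "ALH&MALToma": "0.289"},
    "duration": {"overall": "0.028", "RFH&ALH": "0.027", "RFH&MALToma": "0.025", "ALH&MALToma": "0.812"},
    "laterality": {"overall": "0.001", "RFH&ALH": "0.015", "RFH&MALToma": "0.001", "ALH&MALToma": "0.732"},
    "orbital_soft_tissue": {"overall": "< 0.001", "RFH&ALH": "0.005", "RFH&MALToma": "< 0.001", "ALH&MALToma": "0.376"},
    "conjunctiva": {"overall": "0.004", "RFH&ALH": "0.114", "RFH&MALToma": "0.001", "ALH&MALToma": "0.296"},
    "lachrymal_gland": {"overall": "< 0.001", "RFH&ALH": "0.013", "RFH&MALToma": "< 0.001", "ALH&MALToma": "0.130"},
    "extraocular_muscle": {"overall": "0.434", "RFH&ALH": "0.213", "RFH&MALToma": "0.827", "ALH&MALToma": "0.317"},
    "other": {"overall": "0.166", "RFH&ALH": "0.06", "RFH&MALToma": "0.326", "ALH&MALToma": "0.327"},
    "periorbital_swelling": {"overall": "0.685", "RFH&ALH": "0.653", "RFH&MALToma": "0.392", "ALH&MALToma": "0.770"},
    "proptosis": {"overall": "0.683", "RFH&ALH": "0.593", "RFH&MALToma": "0.905", "ALH&MALToma": "0.521"},
    "impaired_vision": {"overall": "0.051", "RFH&ALH": "1.00", "RFH&MALToma": "0.057", "ALH&MALToma": "0.078"},
    "epiphora": {"overall": "0.449", "RFH&ALH": "1.00", "RFH&MALToma": "0.401", "ALH&MALToma": "0.642"},
    "pain": {"overall": "0.896", "RFH&ALH": "1.00", "RFH&MALToma": "1.00", "ALH&MALToma": "1.00"},
    "motility_impairment": {"overall": "0.002", "RFH&ALH": "0.294", "RFH&MALToma": "0.041", "ALH&MALToma": "0.005"},
    "ptosis": {"overall": "0.245", "RFH&ALH": "1.00", "RFH&MALToma": "0.236", "ALH&MALToma": "0.392"}
  }
}
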