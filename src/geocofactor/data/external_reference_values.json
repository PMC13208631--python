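{
  "_comment": "Literature annotation values for the full-scale Fe/Ni study. These depend on external data (the complete Mineral Evolution Database export and the curated 181-structure Protein Data Bank set) and are NOT computed by this package at desk scale. They are shipped as flagged reference annotations only.",
  "computed_by_package": false,
  "requires_external_data": [
    "Mineral Evolution Database occurrence export",
    "curated Fe/Ni Protein Data Bank structure set (181 structures)"
  ],
  "values": {
    "pc1_explained_variance_percent": 77.1,
    "cysteine_welch_p_shared_family": 1.19e-08,
    "cysteine_welch_p_global": 3.73e-03,
    "n_curated_structures": 181,
    "fe_occurrence_fraction_wmee_cv_below_0.3_percent": 66.4,
    "ni_occurrence_fraction_wmee_cv_below_0.3_percent": 99.3
  }
}
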