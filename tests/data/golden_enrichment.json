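{
  "config_hash": "58d7b1d12910124b",
  "covariate": "log10-length",
  "direction": "tfbs-on-rna",
  "factors": {
    "ctcf": {
      "counts": {
        "a_rna_tfbs": 4,
        "b_rna_only": 3,
        "c_tfbs_only": 2,
        "crude_odds_ratio": 2.0,
        "d_neither": 3,
        "factor": "ctcf",
        "n_nonrna": 5,
        "n_rna": 7,
        "pct_nonrna_tfbs": 40.0,
        "pct_rna_tfbs": 57.142857142857146
      },
      "enrichment": {
        "beta": 1.6670478507848843,
        "ci_high": 111.145931677201,
        "ci_low": 0.25239793341757705,
        "covariate": "log10-length",
        "n_obs": 12,
        "odds_ratio": 5.296508610688436,
        "p_wald": 0.2830706228150289,
        "se_beta": 1.5529857624226724
      },
      "gene_list_sizes": {
        "neither": 3,
        "rna_and_tfbs": 4,
        "rna_only": 3,
        "tfbs_only": 3
      },
      "permutation": {
        "n_failed": 22,
        "n_perm": 28,
        "p_perm": 0.2413793103448276,
        "p_perm_report": "0.241",
        "r_lower": 6,
        "seed": 17
      }
    }
  },
  "n_nonrna_pirs": 5,
  "n_pirs": 12,
  "n_rna_pirs": 7,
  "seed": 17,
  "version": "0.1.0"
}
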