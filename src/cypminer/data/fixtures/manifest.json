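{
  "table2.tsv": {
    "rows": 126,
    "sum_n_p450": 2643,
    "sum_n_fragments": 129,
    "max_n_p450": 35,
    "min_n_p450": 10,
    "sha256": "4ba4165c8b2d84a429a6b3a35cd36c4e76f169c2608f632c8607dcc887b5452c"
  },
  "table3.tsv": {
    "rows": 103,
    "n_families": 45,
    "sum_family_counts": 2643,
    "sum_subfamily_counts": 2643,
    "n_subfamilies": 103,
    "sha256": "49ac713d6b68c7188405791c3b8cc0932fdb075ef47ed747834f24c56a7c7b12"
  },
  "table4.tsv": {
    "rows": 151,
    "n_types": 18,
    "sum_p450_counts": 1236,
    "sha256": "d50c8f5879715956ac6a91a79c4b5564fdf4bb6ce02c574a7c8bdb08e61cc8e7"
  }
}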