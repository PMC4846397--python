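{
  "alleles": {
    "Q23": {
      "categories": {
        "long": 150,
        "mid": 84,
        "short": 60
      },
      "n_dropped_rows": 0,
      "n_pass_filter": 442,
      "n_psms": 489,
      "n_self_links": 0,
      "n_site_pairs": 294
    },
    "Q46": {
      "categories": {
        "long": 136,
        "mid": 106,
        "short": 56
      },
      "n_dropped_rows": 0,
      "n_pass_filter": 464,
      "n_psms": 513,
      "n_self_links": 0,
      "n_site_pairs": 298
    },
    "Q78": {
      "categories": {
        "long": 137,
        "mid": 102,
        "short": 58
      },
      "n_dropped_rows": 0,
      "n_pass_filter": 507,
      "n_psms": 581,
      "n_self_links": 0,
      "n_site_pairs": 297
    }
  },
  "cd": {
    "helicity_trend": {
      "intercept": -19712.578494,
      "monotone": true,
      "n": 3,
      "slope": -70.796247,
      "slope_stderr": 0.280923,
      "spearman_rho": -1.0
    },
    "melt": {
      "irreversibility_index": 4688.901023,
      "onset_C": 45.0,
      "span_C": [
        45.0,
        65.0
      ]
    },
    "mre222_vs_polyq": [
      [
        23,
        -21335.702071
      ],
      [
        46,
        -22978.12638
      ],
      [
        78,
        -25230.955396
      ]
    ]
  },
  "config_hash": "709600ae24ccf28e",
  "domain_pair_counts": {
    "Q23": {
      "CTD-I": {
        "CTD-I": 24,
        "CTD-II": 0,
        "NTD-I": 24,
        "NTD-II": 40,
        "UCD": 0
      },
      "CTD-II": {
        "CTD-I": 48,
        "CTD-II": 30,
        "NTD-I": 54,
        "NTD-II": 37,
        "UCD": 0
      },
      "NTD-I": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 20,
        "NTD-II": 0,
        "UCD": 0
      },
      "NTD-II": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 4,
        "NTD-II": 12,
        "UCD": 0
      },
      "UCD": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 0,
        "NTD-II": 0,
        "UCD": 1
      }
    },
    "Q46": {
      "CTD-I": {
        "CTD-I": 26,
        "CTD-II": 0,
        "NTD-I": 12,
        "NTD-II": 45,
        "UCD": 0
      },
      "CTD-II": {
        "CTD-I": 57,
        "CTD-II": 35,
        "NTD-I": 37,
        "NTD-II": 43,
        "UCD": 0
      },
      "NTD-I": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 19,
        "NTD-II": 0,
        "UCD": 0
      },
      "NTD-II": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 8,
        "NTD-II": 15,
        "UCD": 0
      },
      "UCD": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 0,
        "NTD-II": 0,
        "UCD": 1
      }
    },
    "Q78": {
      "CTD-I": {
        "CTD-I": 23,
        "CTD-II": 0,
        "NTD-I": 11,
        "NTD-II": 50,
        "UCD": 0
      },
      "CTD-II": {
        "CTD-I": 50,
        "CTD-II": 40,
        "NTD-I": 23,
        "NTD-II": 57,
        "UCD": 0
      },
      "NTD-I": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 25,
        "NTD-II": 0,
        "UCD": 0
      },
      "NTD-II": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 6,
        "NTD-II": 12,
        "UCD": 0
      },
      "UCD": {
        "CTD-I": 0,
        "CTD-II": 0,
        "NTD-I": 0,
        "NTD-II": 0,
        "UCD": 0
      }
    }
  },
  "geometry": {
    "cavity_fraction": 0.5033,
    "cavity_percent": 50,
    "dimensions_A": [
      115.0
    ],
    "molecular_weight_Da": 348000.0,
    "outer_volume_A3": 861829.0,
    "shape": "sphere",
    "vm_observed_A3_per_Da": 2.4765,
    "vm_protein_A3_per_Da": 1.23
  },
  "httxl_version": "0.1.0",
  "library_versions": {
    "numpy": "2.4.6",
    "pandas": "2.3.3"
  },
  "pairwise": [
    {
      "allele_i": "Q23",
      "allele_j": "Q46",
      "n_shared": 123,
      "n_unique_i": 171,
      "n_unique_j": 175
    },
    {
      "allele_i": "Q23",
      "allele_j": "Q78",
      "n_shared": 101,
      "n_unique_i": 193,
      "n_unique_j": 196
    },
    {
      "allele_i": "Q46",
      "allele_j": "Q78",
      "n_shared": 129,
      "n_unique_i": 169,
      "n_unique_j": 168
    }
  ],
  "partition": {
    "detected_ucd_intervals": [
      [
        1814,
        2284
      ]
    ],
    "segments": [
      {
        "end": 500,
        "name": "NTD-I",
        "start": 1
      },
      {
        "end": 1219,
        "name": "NTD-II",
        "start": 501
      },
      {
        "end": 1813,
        "name": "CTD-I",
        "start": 1220
      },
      {
        "end": 2284,
        "name": "UCD",
        "start": 1814
      },
      {
        "end": 3144,
        "name": "CTD-II",
        "start": 2285
      }
    ]
  },
  "seed": 42,
  "simulation_truth": {
    "Q23": {
      "n_decoys": 38,
      "n_true_detected": 298,
      "n_within_cutoff": 446
    },
    "Q46": {
      "n_decoys": 35,
      "n_true_detected": 304,
      "n_within_cutoff": 422
    },
    "Q78": {
      "n_decoys": 55,
      "n_true_detected": 301,
      "n_within_cutoff": 437
    }
  }
}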