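{
  "clade_supports": {
    "B10|I03": {
      "au": 100.0,
      "bp": 100.0
    },
    "B10|I03|N15|T29|ZH26": {
      "au": 100.0,
      "bp": 100.0
    },
    "N15|T29": {
      "au": 100.0,
      "bp": 100.0
    },
    "N15|T29|ZH26": {
      "au": 100.0,
      "bp": 100.0
    }
  },
  "config": {
    "band": 10,
    "bootstrap_B": 1000,
    "bootstrap_scales": [
      0.5,
      0.6,
      0.7,
      0.8,
      0.9,
      1.0,
      1.1,
      1.2,
      1.3,
      1.4
    ],
    "dispersed_repeat_count": 20,
    "divergence_my": 1.0,
    "exon_length": [
      100,
      500
    ],
    "exons_per_gene": [
      2,
      6
    ],
    "false_per_100kb": 1.0,
    "genome_length": 5000000,
    "inversion_min_size": 10000,
    "inversion_size_range": [
      12000,
      30000
    ],
    "k": 21,
    "map_jump_penalty": 1.5,
    "map_match_reward": 1.0,
    "map_min_size": 1000,
    "map_sizing_tol_bp": 100,
    "map_sizing_tol_rel": 0.02,
    "map_skip_penalty": 0.25,
    "max_gap": 50000,
    "max_size": 50000,
    "min_cluster_match": 100,
    "min_locus_gap": 2000,
    "min_match": 500,
    "min_size": 50,
    "miss_prob": 0.1,
    "motif": "CACGAG",
    "n_chroms": 2,
    "n_genes": 600,
    "rate_per_branch": 40.0,
    "schema_version": 1,
    "seed": 3,
    "sizing_cv": 0.005,
    "sv_size_range": [
      50,
      10000
    ],
    "tandem_array_count": 260,
    "tol": 3,
    "tree_branches": [
      [
        "REF",
        "anc",
        1.0
      ],
      [
        "anc",
        "p1",
        1.0
      ],
      [
        "anc",
        "p2",
        1.0
      ],
      [
        "p1",
        "B10",
        1.0
      ],
      [
        "p1",
        "I03",
        1.0
      ],
      [
        "p2",
        "ZH26",
        2.0
      ],
      [
        "p2",
        "p3",
        1.0
      ],
      [
        "p3",
        "N15",
        1.0
      ],
      [
        "p3",
        "T29",
        1.0
      ]
    ],
    "tree_root": "REF",
    "type_weights": {
      "deletion": 0.3,
      "insertion": 0.3,
      "inversion": 0.06,
      "repeat_contraction": 0.085,
      "repeat_expansion": 0.085,
      "tandem_contraction": 0.085,
      "tandem_expansion": 0.085
    }
  },
  "exon_per_class_bp": {
    "deletion": 57128,
    "insertion": 44758,
    "tandem_expansion": 1139
  },
  "exon_per_class_count": {
    "deletion": 49,
    "insertion": 13,
    "tandem_expansion": 7
  },
  "exon_per_line": {
    "B10": 43,
    "I03": 36,
    "N15": 35,
    "T29": 47,
    "ZH26": 56
  },
  "newick": "((B10:0.237931,I03:0.237931)[100.0/100.0]:0.162488,((N15:0.197368,T29:0.197368)[100.0/100.0]:0.126919,ZH26:0.324288)[100.0/100.0]:0.0761318)[100.0/100.0];",
  "per_line_counts": {
    "B10": {
      "deletion": 39,
      "insertion": 26,
      "inversion": 11,
      "repeat_contraction": 7,
      "repeat_expansion": 16,
      "tandem_contraction": 9,
      "tandem_expansion": 9
    },
    "I03": {
      "deletion": 33,
      "insertion": 23,
      "inversion": 11,
      "repeat_contraction": 5,
      "repeat_expansion": 15,
      "tandem_contraction": 7,
      "tandem_expansion": 10
    },
    "N15": {
      "deletion": 47,
      "insertion": 43,
      "inversion": 7,
      "repeat_contraction": 15,
      "repeat_expansion": 18,
      "tandem_contraction": 9,
      "tandem_expansion": 15
    },
    "T29": {
      "deletion": 47,
      "insertion": 41,
      "inversion": 6,
      "repeat_contraction": 13,
      "repeat_expansion": 19,
      "tandem_contraction": 10,
      "tandem_expansion": 15
    },
    "ZH26": {
      "deletion": 44,
      "insertion": 43,
      "inversion": 10,
      "repeat_contraction": 15,
      "repeat_expansion": 20,
      "tandem_contraction": 14,
      "tandem_expansion": 13
    }
  },
  "per_line_optical_counts": {
    "B10": {
      "deletion": 20,
      "insertion": 13
    },
    "I03": {
      "deletion": 16,
      "insertion": 12
    },
    "N15": {
      "deletion": 16,
      "insertion": 22
    },
    "T29": {
      "deletion": 18,
      "insertion": 26
    },
    "ZH26": {
      "deletion": 21,
      "insertion": 29
    }
  },
  "per_line_validated": {
    "B10": 29,
    "I03": 25,
    "N15": 43,
    "T29": 49,
    "ZH26": 47
  },
  "rate": {
    "divergence_my": 1.0,
    "genome_mb": 5.13673,
    "rate": 13.335332010831793,
    "sv_count": 137
  },
  "recovery": {
    "f1": 1.0,
    "max_indel_breakpoint_error": 0,
    "n_truth": 369,
    "optical_detected": 114,
    "optical_eligible": 114,
    "optical_recovery_ge2kb": 1.0,
    "precision": 1.0,
    "recall": 1.0
  },
  "shared_in_all": 44,
  "sharing_pairwise": {
    "B10": {
      "B10": 100.0,
      "I03": 64.957,
      "N15": 37.607,
      "T29": 37.607,
      "ZH26": 37.607
    },
    "I03": {
      "B10": 73.077,
      "I03": 100.0,
      "N15": 42.308,
      "T29": 42.308,
      "ZH26": 42.308
    },
    "N15": {
      "B10": 28.571,
      "I03": 28.571,
      "N15": 100.0,
      "T29": 74.675,
      "ZH26": 52.597
    },
    "T29": {
      "B10": 29.139,
      "I03": 29.139,
      "N15": 76.159,
      "T29": 100.0,
      "ZH26": 53.642
    },
    "ZH26": {
      "B10": 27.673,
      "I03": 27.673,
      "N15": 50.943,
      "T29": 50.943,
      "ZH26": 100.0
    }
  }
}
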