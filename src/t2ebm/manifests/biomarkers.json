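{
  "_comment": "Direction flags for the cognitive EBM panel. higher_is_worse=true means larger raw values indicate more abnormality (e.g. completion times, anxiety/depression scores); false means larger values indicate better performance and the column is negated during harmonization.",
  "cognitive_panel": {
    "MMSE": {"higher_is_worse": false},
    "MoCA": {"higher_is_worse": false},
    "TMT_A": {"higher_is_worse": true},
    "TMT_B": {"higher_is_worse": true},
    "SAS": {"higher_is_worse": true},
    "SDS": {"higher_is_worse": true},
    "CVLT_PC1": {"higher_is_worse": false},
    "CVLT_PC2": {"higher_is_worse": false},
    "CVLT_PC3": {"higher_is_worse": false},
    "CVLT_PC4": {"higher_is_worse": false},
    "STROOP_PC1": {"higher_is_worse": false},
    "STROOP_PC2": {"higher_is_worse": false},
    "WCST_PC1": {"higher_is_worse": false},
    "WCST_PC2": {"higher_is_worse": false},
    "WCST_PC3": {"higher_is_worse": false},
    "WCST_PC4": {"higher_is_worse": false}
  },
  "gmv_panel_direction": {"higher_is_worse": false}
}
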