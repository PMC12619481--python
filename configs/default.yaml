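# Default pipeline configuration: simulate the study-sized cohort and run
# the complete analysis. Override any key here or via CLI flags.
out_dir: results/full_run
seed: 0
simulate: true
n_patients: 119
n_controls: 87
bootstrap_B: 100
em_restarts: 5
composite_weighting: eigenvalue
include_mood_scales: true
run_gmv: true
gmv_bootstrap_B: 0
tiv_correction: true
figures: false
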