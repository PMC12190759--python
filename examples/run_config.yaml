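input_mode: simulate
cell_table_path: null
panel_path: null
out_dir: runs
seed: 1
sim: {}
alpha: 0.05
min_matched: 20
triage_k: 5
lesion_radius_um: 200.0
pseudocount: 1.0
n_modules: 2
grouping_fraction: random_intercept
grouping_size: fixed_sample
grouping_pc1: random_intercept
size_scale: log
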