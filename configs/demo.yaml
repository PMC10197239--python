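# Demo run on the packaged synthetic consortium (generated at run time).
outdir: phicmap_demo_out
synthetic_seed: 0
synthetic_n_pairs: 1000000
synthetic_n_read_pairs: 100000
bin_size: 5000
insulation_window: 5
border_min_prominence: 0.2
max_shift: 20000
t_domain: 1.5
t_loop: 2.0
t_depletion: 0.67
induction_fold_threshold: 10.0
edge_window: 500
read_length: 35
seed: 0
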