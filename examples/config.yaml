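# Desk-scale synthetic run: a 27-LGA state on a 15x15 grid of 5 km pixels,
# five modelled years, conflict-driven dropout of 21 LGAs.
out_dir: geovax_run
seed: 1
years: [2014, 2018]
grid: {n_rows: 15, n_cols: 15, cell_size: 5.0}
n_covariates: 6
n_states: 1
lgas_per_state: 27
n_clusters: 150
children_per_cluster: 20
n_conflict_lgas: 21
conflict_dropout_prob: 1.0
conflict_event_rate: 10.0
vif_threshold: 5.0
stacking_folds: 5
n_draws: 250          # production-style runs use 1000
raking_mode: mean
percentiles: [2.5, 97.5]
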