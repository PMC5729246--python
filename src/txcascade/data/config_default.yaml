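# "paper-replica-synthetic": end-to-end synthetic replica of the cascade
# analysis at desk scale.  Data are generated from the burden model at the
# packaged training-set estimates, both models are fitted bottom-up on the
# training circuits, and the test set is predicted with Monte Carlo bands.
name: paper-replica-synthetic
out_dir: results/workflow
master_seed: null        # must be supplied (config or --seed); never defaults
stages: [simulate, fit, predict, report]
truth_model: BM
truth_column: BM_training
n_replicates: 3
cv: 0.10
include_plate: false
n_bootstrap_nbm: 100
n_bootstrap_bm: 20
n_prediction_draws: 100
sensitivity_cv: 0.25
sensitivity_target: delta
sensitivity_circuits: [X_rep_Tr]
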