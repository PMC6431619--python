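# Default synthetic-study configuration.
# One exactly-specified landmark (anchor_time): duration and outcome are
# generated from the person's history features at that time, so fitting
# with grid = [anchor_time] targets the *_true parameters below.
n_individuals: 5000
seed: 0
action_rate: 0.15        # mean actions per second
rate_log_sd: 1.3         # person-level rate heterogeneity (log scale)
p_reset: 0.1
p_simple: 0.7
anchor_time: 60.0        # seconds
feature_names: [const, I_votat, N_over_t, S_pos]
b1_true: [0.3, 0.5, -1.0, 0.7]
b2_true: [4.8, -0.8, -1.4, -0.2]
sigma_true: 0.7
initial_config: [0, 0, 0]
slider_values: [-2, -1, 0, 1, 2]
continue_after_anchor: true
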