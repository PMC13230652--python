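# Smoke-test configuration for the ordinal coverage study: a reduced
# reliability grid and cohort size that finish in seconds while still
# showing nominal coverage for the scale-corrected approach.
item_kind: ordinal
n: 50000
reliability_grid: [0.1, 0.5, 0.9]
level: 0.95
seed: 1
calib_n: 50000
calib_tol: 0.01
n_items: 10
n_categories: 6
scale_mean: 50.0
scale_sd: 10.0
scale_label: T
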