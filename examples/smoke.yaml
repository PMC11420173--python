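# Desk-scale smoke run: synthetic 10-class task, GN30-capacity genome,
# 10 generations. Completes in seconds on one CPU.
n_classes: 10
image_side: 12
n_train: 2000
n_test: 1000
noise_sd: 0.5
n_hidden: 32
weight_gnet_hidden: [30, 10]
bias_gnet_hidden: [5]
outer_iterations: 10
image_budget: 2000
gnet_epochs: 2
lam: 20.0
pnet_lr: 0.05
gnet_lr: 0.001
master_seed: 0
output_dir: run_output
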