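[run]
stages = generate-counts, run-de, summaries, compare
seed = 0
out_dir = mbwsim_run
log_level = INFO

[network]
sigma_a = 0.05
sigma_i = 0.2
rho_a = 1.0
rho_i = 1.0
mu_a = 1.0
mu_i = 1.5
kappa = 0.2
n_coop = 2.0
D_a = 0.25
D_i = 12.5
f_knockdown = 1.0

[domain]
rows = 96
cols = 64
h = 1.0
guide_fraction = 0.3333333333333333

[pattern]
genotype = F1
t_end = 150.0
noise_amplitude = 0.01
level_threshold = 0.5
cv_uniform = 0.05

[generate]
preset = fig5c
n_per_group = 3
alpha = 0.05
depth_sigma = 0.1
n_background = 2000
panel_seed = 0

[de]
lfc_threshold = 1.0
padj_threshold = 0.05
shrinkage_weight = 0.3

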