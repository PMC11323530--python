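# Reference simulation design: 8 clusters, 5 periods, balanced covariate,
# 15% control-arm outcome prevalence, increasing secular trend, simple
# exchangeable correlation (ICC 0.1).  Effect sizes given as odds ratios.
n_clusters: 8
n_periods: 5
cluster_size: 20
theta0: -1.7346010553881064   # log(0.15 / 0.85)
gammas: [0.0, 0.1, 0.2, 0.3, 0.4]
theta1_or: 1.68               # overall treatment effect
theta2_or: 1.5                # covariate main effect
theta3_or: 1.5                # treatment-by-covariate interaction (HTE)
prevalence: 0.5
icc: 0.1
cac: 1.0
sig_level: 0.05
test: wald_z
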