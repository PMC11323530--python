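# Goals-of-care disparity trial: 8 oncology practices, 5 periods, 15
# patients per practice-period, one third minority patients, no secular
# trend, nested exchangeable correlation (ICC 0.1, CAC 0.8).
# Control rates: 35% (non-minority), 15% (minority).  The intervention is
# hypothesized to lift them to 40% and 30% — interaction odds ratio 1.96.
n_clusters: 8
n_periods: 5
cluster_size: 15
theta0: -0.6190392084062235   # log(0.35 / 0.65)
gammas: [0.0, 0.0, 0.0, 0.0, 0.0]
theta1_or: 1.24
theta2_or: 0.33
theta3_or: 1.96
prevalence: 0.333333333333333
icc: 0.1
cac: 0.8
test: wald_t                  # t with I - 4 = 4 df: few clusters
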