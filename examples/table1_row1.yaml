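# First normal-distribution coverage row: X ~ N(0,1) vs Y ~ N(mu, 0.5)
# with mu solved so the true Youden Index is 0.4; m = 20 and three
# diseased-group sizes.  Published full-scale reference (5000 replicates,
# B = 500): BAC 0.898 (0.370), NP 0.933 (0.481), NPAC 0.994 (0.512) at n=20.
# n_sims is set to 500 here so the row runs in seconds; raise it to 5000
# to reproduce the reference values to Monte-Carlo accuracy.
seed: 1
n_sims: 500
B: 500
alpha: 0.05
methods: [NP, NPAC, BAC]
cells:
  - non_diseased: {family: normal, mean: 0, variance: 1}
    diseased: {family: normal, variance: 0.5, target_j: 0.4, free: normal_mean}
    sizes: [[20, 20], [20, 40], [20, 60]]
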