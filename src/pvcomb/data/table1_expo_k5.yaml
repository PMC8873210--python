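# One cell-block of the null calibration grid: AR(1) correlation,
# rho = 0.5, k = 5, left-sided p-values, all four robust tests.
# n_replicates is kept small here for a quick run; the published table
# uses 1e6.
spec:
  model: expo
  k: 5
  parameter: 0.5
n_replicates: 100000
alphas: [0.05, 0.01, 0.001, 0.0001]
seed: 0
tests: [CCT, MinP, MCM, CMC]
sides: [left]
minp_mode: sidak
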