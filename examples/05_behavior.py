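"""Go/NoGo behavior: performance indices, their correlation with the
sign-tracking bias, and the evidence for a null.

Run:  python examples/05_behavior.py
"""

import numpy as np

import neurotopo as nt

# the design's a-priori sample size: one-sided rho=0.4, alpha=.05, power=.90
n_req = nt.required_n_correlation(rho=0.4, alpha=0.05, power=0.90)
print(f"a-priori sample size for the correlation design: {n_req} participants")

# simulate that sample with NO true bias-behavior coupling
rng = np.random.default_rng(2)
bias = rng.normal(0.1, 0.1, n_req)
schedule = nt.build_gng_schedule(seed=2)               # 800 trials, 60% Go
trials = nt.simulate_gng_behavior(bias, schedule, mean_rt=300.0,
                                  commission_rate=0.05, seed=2)

perf = nt.gng_performance_table(trials)
print(f"commission error rate: {perf['commission_error_rate'].mean():.3f} "
      f"+/- {perf['commission_error_rate'].std():.3f}")
print(f"mean correct RT: {perf['mean_rt_correct'].mean():.0f} "
      f"+/- {perf['mean_rt_correct'].std():.0f} ms")

# H2a-style analysis: MAD outlier exclusion, Pearson r, JZS Bayes factor
rep = nt.bias_performance_correlation(perf, bias, "commission_error_rate",
                                      alternative="one_sided_pos")
print(f"bias vs commission errors: r = {rep.r:+.3f}, t[{rep.df}] = "
      f"{rep.t_stat:.2f}, p = {rep.p_value:.3f}, BF01 = {rep.bf01:.2f} "
      f"(n = {rep.n} after outlier exclusion)")
print("BF01 > 3 would be positive evidence that the bias does not relate "
      "to commission errors; here the data were generated with no coupling.")

# split-half reliability of the indices (odd vs even trials, Spearman-Brown)
rel = nt.split_half_reliability(trials, index="rt")
print(f"split-half reliability of mean RT: {rel.corrected:.2f}")
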