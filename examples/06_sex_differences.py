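"""Bootstrap between-sex differences in trajectory parameters.

Each replicate resamples participants within sex and refits both
trajectories; the 2.5%/97.5% quantiles of the women-minus-men parameter
differences give percentile confidence intervals.  An interval excluding
zero is read as a significant difference (no p-values).
"""

import warnings

import cogspan as cs

cfg = cs.default_config(n_per_sex=6000, seed=87)
cohort = cs.generate_cohort(cfg)
Y = cs.compute_domain_scores(cs.zscore_tests(cohort), cfg.weights)

acfg = cs.AnalysisConfig(mode="unmatched", n_bootstrap=200, seed=87)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    results = cs.bootstrap_differences(cohort, Y, acfg)

print(f"{'domain':10s} {'parameter':17s} {'women':>8s} {'men':>8s} "
      f"{'diff':>8s}  95% CI           sig")
for r in results:
    if r.ci is None:
        print(f"{r.domain:10s} {r.parameter:17s} "
              f"{'--':>8s} {'--':>8s} {'--':>8s}  undefined")
        continue
    print(f"{r.domain:10s} {r.parameter:17s} {r.value_women:8.3f} "
          f"{r.value_men:8.3f} {r.point_difference:8.3f}  "
          f"({r.ci[0]:7.3f}, {r.ci[1]:7.3f})  {'*' if r.significant else ''}")
print("\nWith the default (study-like) trajectories, the significant "
      "differences concern working-memory peak score (men higher) and the "
      "reasoning domain (women begin declining earlier, men decline "
      "faster); women's reasoning has no increasing segment, so that "
      "comparison is undefined.")
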