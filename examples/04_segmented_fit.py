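"""Fit a broken-line age trajectory to one domain score.

BIC chooses the number of breakpoints, Davies' test checks that any
slope change is real, and the peak/slope summaries describe the rise to
and decline from peak performance.
"""

import warnings

import cogspan as cs

cfg = cs.default_config(n_per_sex=13444, seed=55)
cohort = cs.generate_cohort(cfg)
Y = cs.compute_domain_scores(cs.zscore_tests(cohort), cfg.weights)

women = (cohort.data.sex == "female").to_numpy()
age = cohort.data.age.to_numpy()[women]
wm = Y["wm"].to_numpy()[women]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit, bic_table = cs.select_n_breakpoints(age, wm, max_breakpoints=3)
    stat, p = cs.davies_test(age, wm)
peak = cs.peak_from_fit(fit)
inc = cs.side_slope(fit, peak, "left")
dec = cs.side_slope(fit, peak, "right")

print("BIC table:", [(r["n_breakpoints"], round(r["bic"], 1))
                     for r in bic_table])
print(f"selected {fit.n_breakpoints} breakpoint(s) at "
      f"{[round(p_, 2) for p_ in fit.psi]} "
      f"(SE {[round(s, 2) for s in fit.psi_se]})")
print(f"Davies' test for a slope change: M={stat:.1f}, p={p:.2e}")
print(f"peak age {peak.peak_age:.2f}, fitted peak score "
      f"{peak.peak_score:+.3f}")
print(f"increasing slope {inc.value:+.4f}/yr, "
      f"decreasing slope {dec.value:+.4f}/yr")
print("\nWomen's working memory rises to a peak near age 20-21, then "
      "declines ~0.02 SD/yr to age 69 (generator truth: breakpoint 20.42, "
      "slopes +0.036/-0.023; composite scoring attenuates slopes slightly "
      "toward zero).")
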