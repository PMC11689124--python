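"""Stage/sex mixed-effects comparison on a simulated metric table.

Simulates a phase-like metric for 10 + 10 participants across the three CO2
stages with injected stage effects (hypocapnia +0.38 rad, hypercapnia -0.28
rad versus eucapnia), fits the random-intercept model and prints the fixed
effects with their likelihood-ratio test, plus the a-priori sample size the
design arithmetic gives.
"""

import numpy as np

import cardiotfa as ct

rng = np.random.default_rng(5)
table = ct.simulate_metric_table(
    rng, stage_effects={"hypocapnia": 0.38, "hypercapnia": -0.28}
)
res = ct.fit_stage_sex_lme(table)

print("fixed effects (vs eucapnia / female reference):")
for term in ("beta_hypocapnia", "beta_hypercapnia", "beta_sex_male"):
    lo, hi = res.ci95[term]
    print(f"  {term:18s} {getattr(res, term):+.3f}  "
          f"95% CI [{lo:+.3f}, {hi:+.3f}]  P = {res.p_values[term]:.3g}")
print(f"likelihood-ratio test vs null (chi2, df 3): P = {res.lr_p:.3g}")

n = ct.required_sample_size(ct.PowerSpec(f_squared=0.35, alpha=0.05,
                                         power=0.80, tails="one"))
print(f"\na-priori sample size (f2 = 0.35, alpha = 0.05, power = 0.80, "
      f"one-tailed): n = {n}")
print(
    "\nThe stage betas recover the injected ordering (hypocapnia above, \n"
    "hypercapnia below eucapnia) and the LR test rejects the no-fixed-effects\n"
    "null decisively; the sex coefficient is consistent with zero, as injected."
)
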