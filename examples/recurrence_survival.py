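"""Score-survival association in primary versus recurrent disease.

Generates matched primary/recurrent survival arms where the signature
score is coupled to overall survival (Gaussian copula, rho = -0.9) in
the recurrent arm only, then runs the per-stage Spearman correlation, a
univariate Cox model, and the bootstrap-balanced Wilcoxon comparison for
unequal group sizes.
"""

import numpy as np

from margin_profiler import recurrence, synthetic
from margin_profiler.io_core import SurvivalCohort

cohort, score = synthetic.generate_survival_cohort(rho_recurrent=-0.9, seed=0)

corr = recurrence.survival_correlation(score, cohort)
print("Spearman score vs overall survival by stage:")
print(corr.round(3).to_string())

table = cohort.table.copy()
table["score"] = score
rec = SurvivalCohort(table[table["stage"] == "recurrent"])
cox = recurrence.cox_regression(rec, ["score"])[0]
print(f"\nrecurrent-arm Cox: HR {cox.hazard_ratio:.2f} "
      f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f}, p = {cox.pval:.3g})")

rng = np.random.default_rng(0)
small = rng.normal(2.0, 1.0, 13)
large = rng.normal(0.0, 1.0, 154)
bw = recurrence.bootstrap_wilcox(small, large, B=1000, seed=0)
print(f"\nbootstrap-Wilcoxon (n = 13 vs 154, +2 SD shift): mean p = {bw.mean_p:.2e}, "
      f"range [{bw.p_range[0]:.2e}, {bw.p_range[1]:.2e}]")
print()
print("The negative Spearman rho and HR > 1 appear only in the recurrent arm,")
print("where high signature scores were planted to shorten survival.")
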