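"""The 6 x 3 mixed repeated-measures ANOVA with Greenhouse-Geisser correction.

ERD/S values (one per participant x ROI x condition) are analysed with
within-subject factors ROI (FL, FR, CL, CR, PL, PR) and Condition (BOTH,
LEFT, RIGHT) and between-subject factors Handedness and Sex. Degrees of
freedom of every within-subject test are multiplied by the Greenhouse-Geisser
epsilon estimated from that stratum's covariance, and post-hoc pairwise
comparisons use Tukey's studentized-range correction.

Here the table is drawn from a known model with a fixed per-ROI shift, so
the ROI main effect should come out clearly significant.
"""

import numpy as np

from mubeta import emmeans, mixed_rm_anova, posthoc_for_effect, simulate_long_design

table = simulate_long_design(7, seed=42, roi_effect=np.array([4, 4, -6, -5, 2, 3]))
result = mixed_rm_anova(table)

cols = ["effect", "F", "df1_gg", "df2_gg", "epsilon", "p_gg"]
print(result.effects[cols].round(4).to_string(index=False))

print("\nEstimated marginal means for ROI (ERD/S %):")
print(emmeans(result, "ROI").round(3).to_string(index=False))

print("\nTukey-corrected pairwise comparisons (5 smallest p):")
ph = posthoc_for_effect(result, "ROI").sort_values("p_tukey")
print(ph.head(5).round(4).to_string(index=False))
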