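"""The split-plot statistics pipeline on a small synthetic data set.

Builds a balanced two-group repeated-measures table with a known group-by-
time interaction, runs the mixed ANOVA with Greenhouse-Geisser correction,
and follows up with Bonferroni-corrected independent-sample t tests.
"""

import numpy as np
import pandas as pd

from avoidsim.stats import bonferroni_ttests, mixed_anova

rng = np.random.default_rng(0)
rows = []
for group, slope in (("control", 0.0), ("treated", 0.4)):
    for subject in range(8):
        baseline = rng.normal()
        for session in range(1, 7):
            y = baseline + slope * session + rng.normal(scale=0.8)
            rows.append((f"{group}{subject}", group, session, y))
data = pd.DataFrame(rows, columns=["subj", "group", "session", "score"])

table = mixed_anova(data, "score", within="session", subject="subj",
                    between=["group"])
print(f"Greenhouse-Geisser epsilon = {table.epsilon:.3f} "
      "(within-effect dfs are multiplied by this)\n")
for res in table.effects:
    print(f"{res.effect:15s} F({res.df1_corr:.2f}, {res.df2_corr:.2f}) = "
          f"{res.F:7.3f}   p = {res.p:.4g}   eta_p2 = {res.eta_p2:.3f}")

final = data[data.session == 6]
[follow] = bonferroni_ttests([
    ("treated vs control at session 6",
     final[final.group == "treated"].score.to_numpy(),
     final[final.group == "control"].score.to_numpy()),
], family_size=2)
print(f"\nfollow-up {follow.name}: t({follow.df}) = {follow.t:.3f}, "
      f"p_adj = {follow.p_adjusted:.4g}, r = {follow.r:.2f}")
print("r is the point-biserial effect size sqrt(t^2 / (t^2 + df)).")
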