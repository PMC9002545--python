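"""Within-subject statistics on a synthetic study, plus the reference
percent-change summary.

Per channel the three conditions are compared by repeated-measures ANOVA
(F with df (2, n-1)x(c-1), partial eta squared) with Bonferroni post hoc
tests; per region, a one-sample Wilks' Lambda test on the six
within-subject difference scores (2 contrasts x 3 channels) — with 15
subjects its F has df (6, 9).  Finally the published group-mean fractal
dimensions are summarised as percent change from the eyes-open baseline.
"""

import numpy as np

from vreeg import (
    PairedDesign,
    SyntheticStudyConfig,
    bonferroni_posthoc,
    build_fd_table,
    build_power_table,
    gen_study,
    percent_change,
    preprocess,
    rm_anova,
    wilks_one_sample,
)
from vreeg.synth import REFERENCE_FD

segments = [preprocess(s) for s in gen_study(SyntheticStudyConfig(seed=1))]
power = build_power_table(segments)
fd = build_fd_table(segments)

alpha_pz = power[(power["band"] == "alpha") & (power["channel"] == "Pz")]
wide = alpha_pz.pivot_table(index="subject", columns="condition", values="value")[
    ["EO", "2D", "3D"]
]
res = rm_anova(PairedDesign(values=wide.to_numpy()))
print(f"alpha @ Pz: F({res.df1:.0f}, {res.df2:.0f}) = {res.statistic:.2f}, "
      f"p = {res.p:.4f}, partial eta^2 = {res.effect_size:.2f}")
for pw in bonferroni_posthoc(PairedDesign(values=wide.to_numpy())):
    print(f"  {pw.pair[0]:>2s} vs {pw.pair[1]:2s}: t = {pw.t:6.2f}, "
          f"adjusted p = {pw.p_adjusted:.4f}{' *' if pw.significant else ''}")

diffs = []
for ch in ("P3", "Pz", "P4"):
    w = fd[fd["channel"] == ch].pivot_table(
        index="subject", columns="condition", values="fd"
    )
    diffs += [w["2D"] - w["EO"], w["3D"] - w["EO"]]
res = wilks_one_sample(np.column_stack(diffs))
print(f"\nparietal FD, one-sample multivariate test: Wilks' Lambda = "
      f"{res.statistic:.2f}, df ({res.df1:.0f}, {res.df2:.0f}), p = {res.p:.4f}")

pct_2d = np.mean([percent_change(eo, d2) for eo, d2, _ in REFERENCE_FD.values()])
pct_3d = np.mean([percent_change(eo, d3) for eo, _, d3 in REFERENCE_FD.values()])
print(f"\nreference FD percent change from EO across the nine sites: "
      f"2D {pct_2d:.2f}%, 3D {pct_3d:.2f}%")
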