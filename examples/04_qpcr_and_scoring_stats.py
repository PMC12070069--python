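"""Supporting statistics: scoring percentages, ΔΔCt fold change, Welch test.

Worked examples with closed-form answers: 67 affected of 74 embryos is 90.5%;
a treated group whose ΔCt drops by one cycle corresponds to a 2-fold increase.
"""

import pandas as pd

import hcrprof as hp

score = hp.score_phenotypes([hp.ScoringRecord("Klf2MO", "zic1", 74, 67)])
row = score.iloc[0]
print(f"scoring: {row.percent_affected:.1f}% affected "
      f"(95% Wilson CI {row.ci_low:.1f}-{row.ci_high:.1f}%, n={row.n_scored})")

rows = []
for rep in range(3):
    rows += [("control", rep, "ODC", 20.0), ("control", rep, "krt12.4", 25.0),
             ("treated", rep, "ODC", 20.0), ("treated", rep, "krt12.4", 24.0)]
ct = pd.DataFrame(rows, columns=["sample_group", "replicate", "gene", "ct"])
ddct = hp.ddct_fold_change(ct).iloc[0]
print(f"qPCR: ddCt = {ddct.ddct:+.1f} -> fold change {ddct.fold_change:.1f} "
      "(one cycle earlier = twice the transcript)")

expr = pd.DataFrame({
    "gene": ["klf2"] * 6,
    "group": ["blastula"] * 3 + ["crest"] * 3,
    "value": [310.0, 270.0, 295.0, 120.0, 135.0, 128.0],
})
test = hp.fold_change_test(expr).iloc[0]
print(f"expression: fold change {test.fold_change:.2f}, "
      f"Welch t = {test.t_statistic:.2f}, two-sided p = {test.p_value:.4f}")
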