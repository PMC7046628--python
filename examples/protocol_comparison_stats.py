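"""Group statistics across protocols: Kruskal–Wallis + Dunn vs ANOVA + Tukey.

Builds per-sample decay-depth values for three protocols (one clearly
better), runs the size-metric test family, and writes the report artifacts
(summary, per-metric and pairwise CSVs).
"""

import numpy as np
import pandas as pd

from spheroquant import build_report, compare_groups

rng = np.random.default_rng(0)
d50 = {
    "PBS": rng.normal(90, 6, 8),
    "ScaleS": rng.normal(120, 6, 8),
    "Glycerol": rng.normal(125, 6, 8),
}
comparison = compare_groups(d50, metric_kind="size", metric_name="d50_um")

print(f"test: {comparison.test_used}, omnibus p = {comparison.p_value:.2e}")
for _, row in comparison.pairwise.iterrows():
    flag = "*" if row["p_adj"] < comparison.alpha else " "
    print(f"  {row['group1']:9s} vs {row['group2']:9s} adj. p = {row['p_adj']:.4f} {flag}")

rows = [dict(sample_id=f"{p}_{i}", protocol=p, channel="DAPI",
             metric_name="d50_um", value=v, units="um")
        for p, vals in d50.items() for i, v in enumerate(vals)]
build_report(pd.DataFrame(rows), [comparison], "spheroquant_report")
print("report written to spheroquant_report/ (summary.csv, pairwise_stats.csv)")
# Size-type metrics use the non-parametric Kruskal-Wallis family with
# Dunn's Bonferroni-adjusted pairwise comparisons at alpha = 0.05.
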