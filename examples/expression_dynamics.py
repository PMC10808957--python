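"""Expression dynamic-range analysis on simulated RNA-seq counts.

Part 1 plants differential expression only: negative-binomial counts for
4 WT and 4 KO replicates with 2,214 up- and 1,717 down-regulated genes at
|log2FC| = 2, classified by Welch's t at p < 0.05 and |log2FC| > 1.
Part 2 plants dynamic-range compression only (KO log-means shrunk toward
the library-preserving center by gamma = 0.8) and shows how it surfaces
in decile bin proportions and the within-sample variance F test.
Keeping the effects separate makes each recovered number attributable to
its planted parameter; real data mixes both, and their variance effects
partially cancel.
"""

import numpy as np

from chromshift import (
    CountsSpec,
    SimSpec,
    bin_proportions,
    classify_de,
    cpm_normalize,
    de_frame,
    decile_bins,
    detected_genes,
    expression_variance_test,
    make_counts,
    percent_excess,
    quintile_fc_distribution,
)

# --- part 1: planted differential expression -------------------------------
sim = make_counts(SimSpec(seed=0, counts=CountsSpec(ko_only=300)))
matrix = cpm_normalize(sim.table, group_of=sim.group_of)

print("detected genes per group:", detected_genes(matrix))

results = classify_de(matrix)
df = de_frame(results).join(sim.truth)
rec_up = ((df["de_class"] == "up") & (df["true_class"] == "up")).sum()
rec_down = ((df["de_class"] == "down") & (df["true_class"] == "down")).sum()
print(f"DE calls: {(df['de_class'] == 'up').sum()} up / "
      f"{(df['de_class'] == 'down').sum()} down "
      f"(recovered {rec_up}/2214 planted up, {rec_down}/1717 planted down)")
print(f"up-vs-down percent excess of recovered genes: "
      f"{percent_excess(rec_up, rec_down):.0f}% (planted arithmetic: 29%)")

quintiles = quintile_fc_distribution(matrix, results)
print("\nmedian log2FC per WT expression quintile:")
print(quintiles[["n", "median_log2fc"]].round(3))
print("(the shared negative offset is CPM composition: more up- than down-"
      "regulation inflates the KO library; the low-to-high downward trend is "
      "what quintile-resolved fold changes expose)")

# --- part 2: planted dynamic-range compression ------------------------------
gamma = 0.8
sim2 = make_counts(SimSpec(seed=0, counts=CountsSpec(
    de_up=0, de_down=0, compression_gamma=gamma)))
matrix2 = cpm_normalize(sim2.table, group_of=sim2.group_of)

assignment = decile_bins(matrix2, reference_group="WT", K=10)
props = bin_proportions(assignment, matrix2)
wt_cols = [s for s in matrix2.sample_ids if s.startswith("WT")]
ko_cols = [s for s in matrix2.sample_ids if s.startswith("KO")]
print(f"\nper-bin share of detected genes under gamma = {gamma} "
      "(bin 1 = lowest WT decile):")
print("  WT:", np.round(props[wt_cols].mean(axis=1).values, 3))
print("  KO:", np.round(props[ko_cols].mean(axis=1).values, 3))
print("(KO depleted in bins 1 and 10, enriched in the middle: compression)")

var_ko, var_wt, F, p = expression_variance_test(matrix2, "KO_1", "WT_1")
print(f"\nwithin-sample variance: KO {var_ko:.2f} vs WT {var_wt:.2f}, "
      f"F = {F:.3f}, p = {p:.3g}")
print(f"(gamma^2 = {gamma**2:.2f}; measurement noise and the detection floor "
      "pull the observed ratio above it)")
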