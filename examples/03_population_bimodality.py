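"""Detect the membrane-arrested (bimodal) phenotype in a small cohort.

Generates 12 homogeneous ("WT-like") and 12 bimodal ("MUT-like",
half of the vesicles on the plasma-membrane shell) cells, runs the full
pipeline and compares scaled distance distributions at the population level.
"""

from dataclasses import replace

import vesidist as vd

base = vd.SyntheticCellSpec()
wt = replace(base, spatial_model="uniform_ball", group="WT")
mut = replace(base, spatial_model="bimodal", membrane_weight=0.5, group="MUT")

cells = vd.generate_population(wt, 12, jitter=0.2, seed=11)
cells += vd.generate_population(mut, 12, jitter=0.2, seed=12)
results, _ = vd.analyze_stacks([stack for stack, _ in cells])
summary = vd.pca_distributions(vd.summarize(results))

for group in ("WT", "MUT"):
    peaks = vd.detect_peaks(summary.mean_curves[group], summary.bin_edges)
    frac = summary.membrane_fractions[summary.labels == group].mean()
    print(f"{group}: mean membrane fraction (s > 1.2) = {frac:.3f}, "
          f"mean-curve peaks at s = {[float(round(p, 2)) for p in peaks]}")
acc = vd.pc1_sign_accuracy(summary, "WT", "MUT")
print(f"PC1 majority-sign accuracy: {acc:.0%} "
      f"(PC1 explains {summary.pca_explained[0]:.0%} of variance)")
print()
print("The MUT mean curve carries a second mode near s = 1.3 (vesicles at the")
print("plasma membrane) that the WT curve lacks; the membrane fraction and the")
print("first principal component both separate the groups.")
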