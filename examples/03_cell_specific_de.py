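"""Forward deconvolution: cell-type-specific differential expression.

Plants a 5-fold up-regulation of 80 genes in CD8 T cells of the case
group, fits the mixing model within each group (csSAM-style), estimates
one-tailed FDR curves by label permutation and reports the calls at the
permissive 30% FDR cutoff.  Run at a low-noise setting so the planted
signal is comfortably detectable.
"""

import numpy as np

import bloodmix as bm
import bloodmix.simulate as sm

_, truth = bm.simulate_panel(K=7, p=1200, markers_per_type=12, replicates=3, seed=21)
alpha = sm.blood_dirichlet_alpha(list(truth.profiles.index), concentration=10.0)
X, design, mix_truth = bm.simulate_mixtures(
    truth.profiles, n_per_group=24,
    dirichlet_alpha={"NR": alpha, "AR": alpha},
    de_spec=[("CD8 T cells", 80, 5.0, "up")],
    noise_cv=0.05, seed=22,
)
spiked = {g for g, ct, d, f in mix_truth.spiked}

retained = bm.detectability_filter(mix_truth.true_W)
print(f"cell types retained by the 75% detectability rule: {len(retained)} of 7")

result = bm.permutation_fdr(X, mix_truth.true_W, design, n_perm=100,
                            fdr_target=0.30, seed=23)
print(f"{'cell type':<14} {'up calls':>9} {'down calls':>11}")
for ct in retained:
    print(f"{ct:<14} {len(result.calls[('up', ct)]):>9} "
          f"{len(result.calls[('down', ct)]):>11}")

calls = set(result.calls[("up", "CD8 T cells")])
recall = len(calls & spiked) / len(spiked)
precision = len(calls & spiked) / max(len(calls), 1)
print(f"\nCD8 up-calls recover {recall:.0%} of the 80 planted genes "
      f"(precision {precision:.0%}) at FDR <= 0.30.")

fit = bm.cs_fit(X, mix_truth.true_W, design)
ranked = bm.ranking_statistic(fit)["CD8 T cells"]
top_planted = sum(g in spiked for g in ranked.index[:20])
print(f"{top_planted} of the top 20 genes by signal-to-noise statistic are planted; "
      "the ranked list is what would be exported for pre-ranked GSEA.")
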