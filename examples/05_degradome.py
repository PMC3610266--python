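"""Targeted mRNA degradation: the per-gene degradation index (DI) from paired
full-length and fragment libraries, and class-level stability enrichment."""

import numpy as np
from scipy import stats

from switchtome import SimConfig, degradome, simulate

cfg = SimConfig(seed=42)
bundle = simulate(cfg, with_coverage=False)
truth = bundle["truth"]

table = degradome.degradation_index(bundle["long_counts"],
                                    bundle["frag_counts"])
sub = table.at_timepoint(cfg.switch_timepoint)
sub = sub[~sub["masked"]]
rho = stats.spearmanr(sub["relative_DI"],
                      -np.log2(truth.rates.loc[sub.index,
                                               cfg.switch_timepoint]))[0]
print(f"DI computed for {len(sub)} genes passing the minimum-count filter; "
      f"Spearman vs true (hidden) degradation rates: {rho:.2f}")

shift = degradome.global_degradation_shift(table, 40.0, cfg.switch_timepoint)
print(f"median DI shifts {shift['delta_median_DI']:+.2f} log2 units at the "
      "switch — broadly accelerated degradation")

cmap = {c: list(truth.genes.index[truth.genes["category"] == c])
        for c in cfg.class_degradation_log2}
for r in degradome.stability_class_enrichment(table, cmap,
                                              cfg.switch_timepoint):
    direction = "more stable" if r.fold > 1 else "degraded faster"
    print(f"  {r.label:<40s} {r.fold:.2f}-fold ({direction}), q={r.q:.2g}")
print("Relative DI separates the targeted classes (ribosome-related "
      "destabilized, transcription factors protected) from the bulk.")
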