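# switchtome

Analysis of transcriptome topography across a bacterial **metabolic switch** —
the transition in actinomycete batch culture between primary growth and
secondary metabolism, marked by growth arrest and a global rearrangement of
the transcriptome.

The package is written for bacterial transcriptomics at genome scale: it
consumes strand-specific coverage tracks and per-gene count tables from a
time-course RNA-seq experiment over a circular chromosome (for example
*Saccharopolyspora erythraea*, the erythromycin producer), together with a
matched set of small-RNA *fragment* libraries capturing degradation products,
and quantifies

* **pervasive transcription** — the fraction of the genome represented per
  strand, and a saturation diagnostic (singly-covered positions);
* **replichore strand bias** — per-bin leading-strand preference
  P = (L − G)/(L + G), with leading/lagging assignment from the replication
  origin and terminus;
* **macro-region alternation** — log2 enrichment
  E_r,t = log2(mean_r / mean_genome) of the core and non-core chromosomal
  macro-regions over time, with detection of the sign flip at the switch, and
  induction of the paralogous transposon clusters at the region borders
  (rank-sum and permutation tests);
* **expression programs** — upper-quartile-scaled RPKM, the prominently
  expressed gene set (top half by maximal expression), the fraction of genes
  changing > 2-fold across the switch, Pearson complete-linkage clustering
  into exponential / transitional / stationary phase programs, and Fisher
  exact functional-category enrichment with Benjamini–Hochberg correction;
* **the bottleneck** — mRNA concentration (top-q share and Gini), category
  suppression folds across the switch, and a paired t-test for ribonuclease
  induction;
* **targeted degradation** — the per-gene **degradation index**
  DI = log2[(F + c)/N_F] − log2[(S + c)/N_S], where F/S are full-length and
  fragment counts and N their library totals; lower DI = faster degradation.
  Median-centered relative DI classifies genes as faster / neutral / slower
  and drives class-level stability enrichment and browser tracks.

A **synthetic-data generator** (`switchtome.synthetic_data`) emulates the
statistical structure of such an experiment — log-normal expression sampled
through a negative-binomial count model, reciprocal region-locked phase
programs, a global mRNA bottleneck and ribonuclease induction at the switch,
class-targeted degradation rates, antisense leakage with a 3′ bias, and
planted intergenic ncRNAs — and exposes the ground truth, so every statistic
can be validated by parameter recovery.

## Worked example

```python
from switchtome import SimConfig, simulate, programs, bottleneck

cfg = SimConfig(seed=42)                      # the default study conditions
bundle = simulate(cfg, with_coverage=False)
expr = programs.normalize_expression(bundle["long_counts"], bundle["genes"])

fc = programs.switch_fold_changes(expr, 40.0, cfg.switch_timepoint)
conc = bottleneck.expression_concentration(expr, 40.0, q=0.01)
rnases = [g.gene_id for g in bundle["genes"] if g.has_flag("ribonuclease")]
ind = bottleneck.induction_test(expr, rnases, 40.0, cfg.switch_timepoint)

print(f"changed at switch: {100*fc['changed_fraction']:.1f}% of prominent genes")
print(f"top 1% of genes carry {100*conc.share:.1f}% of total mRNA")
print(f"ribonucleases induced: {ind.n_induced}/{ind.n}, p = {ind.p:.2g}")
```

prints

```
changed at switch: 57.7% of prominent genes
top 1% of genes carry 34.6% of total mRNA
ribonucleases induced: 23/24, p = 5.1e-11
```

meaning: the switch re-programs a majority of the actively expressed genes,
the transcriptome is strongly concentrated in a few dominant messages, and
the ribonuclease complement is induced essentially in unison at the switch —
the machinery behind the degradation-mediated bottleneck.

The `examples/` directory holds one short script per capability
(simulation, genome topography, phase programs, bottleneck, degradome, full
pipeline); each prints its numbers with a line of interpretation.

## Command line

```bash
switchtome simulate --outdir sim/ --seed 42      # writes inputs + pipeline.yaml
switchtome run-all  --config sim/pipeline.yaml   # topography → programs →
                                                 # bottleneck → degradome
switchtome report   sim/results                  # print the summary table
```

Stages are also individually invocable (`switchtome topography|programs|
bottleneck|degradome`).  `run-all` writes a `summary.tsv` of headline
statistics and a `manifest.json` hashing every output; a rerun with the same
config and seed reproduces every file byte for byte.  The YAML schema is the
field set of `switchtome.pipeline.PipelineConfig` (paths: `annotation`,
`regions`, `flags`, `long_counts`, `frag_counts`, `coverage_dir`, `outdir`;
parameters: `switch_timepoint`, `pre_timepoint`, `bin_size`, `border_window`,
`n_perm`, `seed`, `fc_threshold`, `epsilon`, `top_fraction`,
`suppression_category`, `stability_classes`, `ncrna_*`).

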