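# Methods

This note documents the models and procedures implemented in `switchtome`,
the assumptions behind them, the synthetic study conditions used for
validation, and the numerical choices a user should know about.

## Coordinate model

All internal coordinates are 0-based half-open on a single chromosome,
circular by default.  An interval with `start > end` wraps the origin; all
interval arithmetic (slicing, summing, midpoints, lengths) handles the wrap,
and format conversion happens only at I/O boundaries (GFF3 is 1-based
inclusive, with origin-wrapping genes written with `end > genome_length` as
is conventional for circular replicons; BED and bedGraph are 0-based
half-open).  The replication terminus defaults to `origin + L/2` when not
annotated — replichore symmetry is the standard null for a bacterial
chromosome.  Rotating the whole coordinate system (genes, coverage,
partition, origin) by a bin multiple leaves every statistic unchanged; this
is enforced by test.

rRNA-flagged genes are excluded from all expression statistics.  Besides the
usual normalization argument there is a quantitative one: residual rRNA at
~50× the median gene dominates a macro-region mean to the point of
inverting it, so the region-enrichment statistic also excludes bins
overlapping rRNA genes.

## Normalization

Expression is RPKM (reads per kilobase per million aligned reads) followed by
between-library upper-quartile scaling: each library is divided by its upper
quartile of nonzero values over the geometric mean of those quartiles.
Upper-quartile scaling equalizes relative composition, which means two things
worth remembering: a genuinely global change in mRNA amount is *invisible* in
normalized expression (it survives only in raw counts when library depth
tracks the pool), and at sharply lower depth the nonzero set shrinks from the
bottom, biasing the quartile slightly upward (~0.2 log2 units at the
bottleneck timepoint under default conditions).  Both effects are real
properties of the estimator, not artifacts to be corrected, and the
bottleneck statistics therefore report raw-count and normalized folds side by
side.

## Genome-scale statistics

* **Transcribed fraction**: per-position thresholds on pooled per-base
  coverage; `either_strand` uses plus OR minus ≥ min_cov, `unstranded` the
  strand sum.  The singleton fraction (positions at exactly 1× among
  expressed positions) is a saturation diagnostic.
* **Strand preference**: per bin, leading coverage L is plus-strand on
  replichore 1 and minus-strand on replichore 2; P = (L − G)/(L + G) ∈
  [−1, 1], NaN where the bin is silent.
* **Region enrichment**: E_{r,t} = log2(mean bin expression in region r /
  genome-wide mean), bins of 10 kb by default (configurable; the statistic is
  stable under refinement when coverage is piecewise constant).  A switch is
  declared when sign(E_noncore) ≥ +ε at every pre-switch timepoint and
  ≤ −ε from the switch on (or the mirror pattern); ε = 0.2 log2 units
  separates genuine alternation from binning noise at the default depth.
* **Border induction**: the statistic is the median log2 fold-change
  (switch vs pre) of transposon-flagged genes within 5 kb of a region
  border.  Because the field does not agree on a single test for such a
  set, two p-values are reported: a one-sided rank-sum against all other
  genes, and a label-permutation p (exhaustive enumeration when the number
  of subsets is ≤ 2×10⁵, Monte-Carlo otherwise, reported with the
  (1+hits)/(1+n) correction).
* **Antisense fraction**: antisense over total base coverage within gene
  bodies, pooled across libraries, plus the same ratio per relative-position
  decile oriented 5′→3′ per gene.
* **Intergenic ncRNA candidates**: per strand, maximal runs of positions
  with no same-strand gene and normalized coverage ≥ 1 per million in at
  least one long library; runs closer than 20 bp merge; lengths outside
  [50, 1000] nt are dropped; a candidate is "supported" when pooled fragment
  coverage spans ≥ 50% of it.  Note that with a same-strand-only exclusion
  rule, antisense transcription opposite highly expressed genes also
  qualifies, so candidate counts include antisense shadows; the planted
  elements are recovered on top of that background (≥ 80% of well-expressed
  planted ncRNAs in the recovery test).

## Phase programs

Profiles of prominently expressed genes (top half by maximal normalized
expression, ties broken by gene id) are mean-centered and clustered by
agglomerative complete linkage under Pearson distance (1 − r); the tree is
cut into three groups by default.  Each cluster's phase is the phase of its
centroid's argmax timepoint (pre-switch → exponential, switch →
transitional, post → stationary).  The centroid is the per-timepoint
**median** of standardized member profiles: any coherent cluster recruits
noise profiles that correlate with it by chance, and those share a spurious
peak at the step timepoint that biases a mean centroid; the median follows
the coherent majority.  Zero-variance profiles are excluded and reported.

Fold changes use log2((post + c)/(pre + c)) with c = 0.5 RPKM — a symmetric
pseudocount that shrinks low-expression fold changes.  Category enrichment
is one-sided Fisher exact (hypergeometric upper tail) with
Benjamini–Hochberg adjustment across tested categories; fold enrichment is
the set rate over the universe rate.

## Bottleneck statistics

Concentration is the share of total normalized mRNA in the top ⌈q·n⌉ genes
plus the Gini coefficient of the expression vector.  Category suppression is
the ratio of summed signal (pre over at-switch), reported for raw counts and
normalized expression, with the per-pre-timepoint maximum for "up to"
statements and an explicit flag for zero denominators.

The induction test is a paired t-test on log2(normalized expression + 0.5)
between two timepoints over a flagged set.  By default the paired
differences are centered on the genome-wide median shift, i.e. the test asks
whether the flagged set moves *relative to the transcriptome*.  This choice
is what keeps the test calibrated: the between-library normalization factor
is shared by all genes, so uncentered differences contain a common noise
component whose variance (at the default one-ribonuclease-per-80-genes rate)
is about 0.4× the per-gene sampling variance regardless of scale, inflating
the t statistic.  Uncentered median fold and induced-gene counts are still
reported, and zero-variance differences return a degenerate flag rather than
p = 0.  The default p is two-sided; one-sided is a flag.

## Degradation index

DI_{g,t} = log2[(F_{g,t} + c)/N^F_t] − log2[(S_{g,t} + c)/N^S_t] with
c = 0.5, where F/S are full-length/fragment counts and N the library totals
recorded in the table metadata.  Genes with F < 10 are masked —
classification at near-zero expression is unstable.  Relative DI is
median-centered per timepoint over unmasked genes (|median| < 1e-9 by
construction); classes use ±1 log2 unit thresholds.  Gene length does not
enter: it cancels under the assumption that fragment capture is
length-proportional.  Class-level stability uses fold =
2^(mean relative DI of class − mean of complement) with a two-sided
rank-sum p (DI distributions are heavy-tailed at low counts, so a t-test is
not used), BH-adjusted.  Fragment reads are pre-filtered to 20–50 nt lying
fully within sense-strand transcribed regions of the matched long library;
the filter is idempotent and reports per-rule discard counts.

## The synthetic study conditions

The generator emulates a 2 Mb circular chromosome (a scaled-down
actinomycete genome) carrying 2000 non-overlapping genes (gamma-distributed
lengths, mean 900 bp), split 50/50 into core and non-core macro-regions, with
20 transposon genes placed by construction in two 10 kb blocks straddling
the region borders, 24 ribonucleases (1 per 80 genes, capped), 4 rRNA genes
at 50× expression, and 40 planted intergenic ncRNAs.  Seven timepoints
(28–93 h) span the switch at 51 h.  Randomness is two-level: structural
draws and count sampling use independent sub-seeds so counts can be
resampled over fixed structure.

Base expression is log-normal with σ = 1.35 (natural log), chosen so the
analytic top-1% mRNA share of the expression mixture is 0.278.  Counts are
negative-binomial (variance m + 0.1 m²; the zero-dispersion limit is the
rounded expectation) with one global scaling constant calibrated so the
first timepoint's expected total is 10⁶ reads; later totals track the true
mRNA pool, so the bottleneck (×0.4 at the switch) is visible in raw column
sums, as it is when sequencing a fixed culture volume.  Coverage spreads
each gene's sampled reads deterministically: 97% uniformly on the sense
strand, 3% antisense with a linear-doubling 3′ bias discretized to deciles.

The switch rearrangement is **reciprocal and mass-symmetric**: a fraction w
of non-core genes follows the pre-switch program (log2 offset +h before the
switch, −h from it), the same fraction of core genes the mirrored
post-switch program (with a further +0.5 log2 completion one timepoint after
the switch), and (w, h) are solved at configuration time so that (i) the
non-core region's log2-enrichment swing equals the injected −2 exactly in
expectation — mass symmetry keeps the genome mean and the upper-quartile
factors stable, which is what makes the injection recoverable — and (ii)
the expected fraction of prominent genes changing > 2-fold is the 0.6
target, accounting for the prominence-selection bias of swinging genes
(normal-mixture quantile math) and the fold-threshold false-positive rate
implied by the NB dispersion.  At the defaults this gives w ≈ 0.295,
h ≈ 2.95.  Flagged genes stay out of the programs; transposons (+3 log2) and
ribonucleases (+2 log2) are induced at the switch timepoint only.

Degradation rates are per-gene log-normal (σ = 1.25 log2 units — a broad,
continuous stability spectrum, without which rank-based recovery of rates
would be dominated by ties), times class factors from the switch on
(ribosome-related 4× faster, transcription factors 2× slower; the
configuration map is expressed as log2 relative *stability*, i.e. expected
relative DI), times a global 2× acceleration at the switch.  Fragment
libraries (40, 51, 93 h) are multinomial with totals scaling with the
relative fragment pool against a rate-of-one baseline while the recorded
library size stays nominal — the convention that lets genuinely global rate
shifts remain visible in DI.

What the generator does **not** emulate: sequencing error and GC bias,
read-level sampling (coverage is spread deterministically, so
saturation-type statistics are cleaner than in real data), operon structure
(genes are independent units), correlation between functional category and
program membership (category enrichment of phases is null by design —
machinery is validated by oracles, not by recovering biology), narrowing of
expression concentration during the bottleneck, and 5′-phosphate library
chemistry.  Passing recovery tests therefore demonstrates estimator
correctness under the declared statistical structure, not performance on
real libraries.

## Validation design

Five layers, all in `tests/` and runnable on one CPU in ~30 s:

1. **Oracles** — Fisher p against exact integer-arithmetic hypergeometric
   tails on all 2×2 tables with total ≤ 50; permutation p against exhaustive
   subset enumeration on ≤ 20-gene instances; complete linkage against an
   O(n³) re-derivation on ≤ 8-gene toys.
2. **Closed forms** — DI, RPKM, and top-share spot values.
3. **Recovery** at the default conditions (fixed seed): the −2 non-core
   swing within ±0.4 with the switch detected; Spearman ≥ 0.9 between
   relative DI and true rates; ≥ 90% phase assignment accuracy for program
   genes; ≥ 80% of ribonucleases induced; changed fraction within ±5
   percentage points of the 0.6 target; antisense within ±0.5 points of 3%
   with a rising 3′ profile.
4. **Calibration** — 1000-replicate nulls (flat generator; for class
   stability the class is redrawn per replicate, since per-gene rate
   heterogeneity is structural and a fixed class has a fixed true offset):
   Kolmogorov–Smirnov uniformity of p-values at p > 0.01.
5. **Determinism** — bedGraph round-trip identity, byte-identical end-to-end
   reruns, coordinate-shift invariance.

Problem sizes are chosen for desk-scale runtimes: the full default
simulation (2 Mb, 2000 genes, 7 × 10⁶-read libraries) takes a few seconds;
null calibrations run on an 800-gene flat genome.

## Known limitations

* The upper-quartile estimator's zero-truncation bias at sharply lower depth
  (≈ +0.2 log2 at the bottleneck timepoint) propagates into normalized fold
  changes; raw-count statistics are reported alongside for this reason.
* Reads overlapping two genes are counted for both; fractional assignment is
  out of scope.
* Candidate ncRNA calling includes antisense shadows of highly expressed
  genes (same-strand exclusion only) and applies no structure or coding
  potential scoring.
* The permutation test resamples gene labels, not genomic positions, so
  spatial autocorrelation of expression is not part of its null.
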