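"""Synthetic time-course generator with ground truth.

Emulates the statistical structure the downstream analyses assume for a
bacterial batch culture crossing a metabolic switch:

* a circular genome split into core / non-core macro-regions, with paralogous
  transposon clusters straddling the two region borders;
* seven sampled timepoints, with the switch at a designated index;
* heavy-tailed (log-normal) per-gene expression sampled through a
  negative-binomial count model;
* a pre-switch / post-switch pair of expression programs, a non-core
  repression after the switch, transposon and ribonuclease induction at the
  switch, and a global mRNA bottleneck at the switch;
* fragment (degradome) libraries whose per-gene representation follows the
  long libraries times a per-gene degradation rate, with targeted classes
  degraded faster or slower from the switch onward.

Randomness is two-level: structural draws (gene placement, categories,
programs, base expression, per-gene stability) and count-level sampling use
independent sub-seeds, so structure can be held fixed while counts are
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (ChromosomeModel, CountTable, CoverageTrack, GeneAnnotation,
                    LibraryInfo, RegionPartition, interval_add)

CATEGORIES = (
    "translation",
    "ribosomal structure and biogenesis",
    "transcription regulation",
    "carbohydrate synthesis",
    "cell wall biogenesis",
    "energy production",
    "lipid metabolism",
    "secretion and transport",
    "posttranslational modification",
    "signal transduction",
    "secondary metabolism",
    "RNA degradation and processing",
)

# relative category draw weights by macro-region: core is enriched for the
# growth machinery, non-core for adaptive/secondary functions
_CORE_W = np.array([2.0, 1.5, 1.0, 1.5, 1.2, 1.5, 1.0, 0.6, 0.8, 0.6, 0.3, 0.8])
_NONCORE_W = np.array([0.8, 0.5, 1.0, 0.8, 0.8, 0.8, 1.0, 1.6, 1.0, 1.5, 2.5, 0.8])

BORDER_WINDOW = 5_000  # bp; transposon clusters sit within this of a border


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults define the study conditions."""
    seed: int = 0
    genome_length: int = 2_000_000
    n_genes: int = 2000
    gene_length_mean: int = 900
    noncore_fraction: float = 0.5
    n_border_transposons: int = 20
    timepoints: tuple = (28.0, 36.0, 40.0, 51.0, 66.0, 82.0, 93.0)
    switch_index: int = 3
    expression_logmean: float = 0.0     # natural-log scale of the log-normal
    expression_logsd: float = 1.35      # gives a top-1% mRNA share of ~0.28
    nb_dispersion: float = 0.1
    long_depth: float = 1e6
    fragment_depth: float = 5e5
    bottleneck_factor: float = 0.4      # global mRNA scale at the switch
    noncore_postswitch_log2fc: float = -2.0
    transposon_switch_log2fc: float = 3.0
    rnase_switch_log2fc: float = 2.0
    class_degradation_log2: Mapping[str, float] = field(
        default_factory=lambda: {
            # log2 relative stability (expected relative DI) from the switch on;
            # degradation rate multiplier is 2**(-value)
            "ribosomal structure and biogenesis": -2.0,   # degraded faster
            "transcription regulation": 1.0,              # more stable
        })
    # --- secondary knobs -------------------------------------------------- #
    read_length: int = 50
    leading_strand_bias: float = 0.75   # P(leading strand) for high-expression genes
    antisense_leak: float = 0.03        # fraction of a gene's reads on the antisense strand
    changed_fraction_target: float = 0.6   # injected fraction of prominent genes >2-fold changed
    postswitch_ramp_log2: float = 0.5   # extra late induction of post-program genes
    degradation_logsd: float = 1.25     # per-gene stability heterogeneity, log2 units
    global_degradation_log2_at_switch: float = 1.0
    fragment_timepoint_indices: tuple = (2, 3, 6)   # 40, 51, 93 h
    n_ncrna: int = 40
    n_rrna: int = 4

    def __post_init__(self):
        if self.long_depth <= 0 or self.fragment_depth <= 0:
            raise ValueError("library depths must be positive")
        if not 0 < self.noncore_fraction < 1:
            raise ValueError("noncore_fraction must be in (0,1)")
        if not 0 < self.switch_index < len(self.timepoints) - 1:
            raise ValueError("switch_index must be strictly inside the timepoints")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def switch_timepoint(self) -> float:
        return self.timepoints[self.switch_index]

    def program_calibration(self) -> tuple:
        """Calibrate the reciprocal-program design: the fraction ``w`` of
        region genes carrying a phase program and the half-swing ``h`` (log2).

        The two genetic programs are region-locked (pre-program genes in the
        non-core region, post-program genes in the core), each swinging
        2^(+/-h) across the switch.  Because the design is mass-symmetric, the
        genome mean is invariant and the non-core region's log2 enrichment
        swing equals ``noncore_postswitch_log2fc`` exactly in expectation;
        ``w`` and ``h`` are solved so that this holds jointly with the target
        fraction of >2-fold-changed genes among the prominent (top-half) set,
        given the log-normal expression sd (prominence selection bias of
        swinging genes) and the NB dispersion (false-positive rate of
        unchanged genes at the threshold).
        """
        from scipy.optimize import brentq
        from scipy.stats import norm

        z = 2.0 ** self.noncore_postswitch_log2fc
        if z == 1.0:                      # no region swing: no program genes
            return 0.0, 1.0
        sigma = self.expression_logsd
        r = self.postswitch_ramp_log2
        ln2 = np.log(2.0)
        sd_noise = np.sqrt(2 * self.nb_dispersion) / ln2
        fpos = float(2 * norm.sf(1.0 / sd_noise)) if sd_noise > 0 else 0.0
        f_flags = (self.n_border_transposons
                   + min(self.n_genes // 80, 24)) / self.n_genes
        c_target = (self.changed_fraction_target - f_flags
                    - fpos * (1 - f_flags)) / (1 - fpos)

        def w_of_h(h):
            return (1 - z) / (1 - 2.0 ** (-h) + z * (2.0 ** h - 1))

        def changed_prominent(h):
            w = w_of_h(h)
            if not 0 < w < 1:
                return np.inf
            d1, d2 = h * ln2, (h + r) * ln2

            def excess(T):
                return (0.5 * w * (norm.sf((T - d1) / sigma)
                                   + norm.sf((T - d2) / sigma))
                        + (1 - w) * norm.sf(T / sigma) - 0.5)
            T = brentq(excess, -10 * sigma, 10 * sigma)
            return w * (norm.sf((T - d1) / sigma) + norm.sf((T - d2) / sigma))

        h = brentq(lambda h: changed_prominent(h) - c_target, 1.05, 8.0)
        return float(w_of_h(h)), float(h)

    def rngs(self):
        """(structure, counts, fragments) generators derived from the seed."""
        kids = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(k) for k in kids)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""
    config: SimConfig
    genes: pd.DataFrame            # per-gene structure: region, program, base_expr, ...
    borders: list
    ncrna: pd.DataFrame            # planted intergenic transcribed elements
    expected: pd.DataFrame | None = None   # gene x timepoint expected expression
    rates: pd.DataFrame | None = None      # gene x timepoint degradation rate
    bottleneck: pd.Series | None = None    # per-timepoint global mRNA factor


# --------------------------------------------------------------------------- #
# genome structure
# --------------------------------------------------------------------------- #

def _place_segment(rng, seg_start, seg_len, lengths):
    """Place genes with the given lengths inside [seg_start, seg_start+seg_len),
    separated by random gaps; returns list of (start, end)."""
    k = len(lengths)
    total = int(np.sum(lengths))
    free = seg_len - total
    if free < k + 1:
        raise ValueError(
            "genome too small to place genes without overlap; increase "
            "genome_length or reduce n_genes/gene_length_mean")
    w = rng.exponential(1.0, k + 1)
    gaps = np.floor(w / w.sum() * free).astype(int)
    gaps[-1] += free - gaps.sum()
    out = []
    pos = seg_start
    for i in range(k):
        pos += int(gaps[i])
        out.append((pos, pos + int(lengths[i])))
        pos += int(lengths[i])
    return out


def generate_genome(config: SimConfig):
    """Build chromosome, gene annotation, region partition and partial truth.

    Returns ``(ChromosomeModel, list[GeneAnnotation], RegionPartition,
    SyntheticTruth)``.
    """
    rng, _, _ = config.rngs()
    L, n = config.genome_length, config.n_genes
    chrom = ChromosomeModel("chr", L, circular=True, origin=0)

    core_len = int(round(L * (1 - config.noncore_fraction)))
    partition = RegionPartition([(0, core_len, "core"), (core_len, L, "noncore")], L)
    borders = partition.borders                     # [core_len, 0]

    lengths = np.maximum(
        100, np.round(rng.gamma(4.0, config.gene_length_mean / 4.0, n))).astype(int)
    n_tr = config.n_border_transposons
    if n_tr >= n:
        raise ValueError("n_border_transposons must be smaller than n_genes")

    # transposon clusters: reserved 2*BORDER_WINDOW blocks straddling each border
    k1 = n_tr - n_tr // 2
    k2 = n_tr // 2
    tr_intervals, tr_onto = [], []
    for border, k in ((borders[0], k1), (borders[1], k2)):
        if k == 0:
            continue
        block_start = (border - BORDER_WINDOW) % L
        block_len = 2 * BORDER_WINDOW
        lens = lengths[len(tr_intervals):len(tr_intervals) + k].copy()
        if lens.sum() > block_len - 20 * k:         # scale to fit the block
            lens = np.maximum(80, (lens * (block_len - 20 * k) / lens.sum())
                              .astype(int))
        placed = _place_segment(rng, 0, block_len, lens)
        for (s, e) in placed:
            tr_intervals.append(((block_start + s) % L, (block_start + e) % L))
        tr_onto.extend([border] * k)

    # the rest of the genome, outside the reserved blocks
    segs = []
    bA, bB = borders[0], borders[1]
    segs.append((bB + BORDER_WINDOW, bA - BORDER_WINDOW))          # 0-side to core border
    segs.append((bA + BORDER_WINDOW, (bB - BORDER_WINDOW) % L))    # core border to wrap
    seg_lens = [e - s for (s, e) in segs]
    n_rest = n - n_tr
    rest_lengths = lengths[n_tr:]
    alloc = [int(round(n_rest * sl / sum(seg_lens))) for sl in seg_lens]
    alloc[-1] = n_rest - sum(alloc[:-1])
    rest_intervals = []
    used = 0
    for (s, e), k in zip(segs, alloc):
        rest_intervals.extend(_place_segment(rng, s, e - s, rest_lengths[used:used + k]))
        used += k

    intervals = tr_intervals + rest_intervals
    is_transposon = np.zeros(n, dtype=bool)
    is_transposon[:n_tr] = True

    # order genes by genomic start for stable ids
    order = np.argsort([iv[0] for iv in intervals], kind="stable")
    intervals = [intervals[i] for i in order]
    is_transposon = is_transposon[order]

    starts = np.array([iv[0] for iv in intervals])
    ends = np.array([iv[1] for iv in intervals])
    glens = np.where(ends > starts, ends - starts, L - starts + ends)
    mids = (starts + glens // 2) % L
    region = np.array([partition.label_at(int(m)) for m in mids])

    # base expression (structural) and strand assignment with leading bias
    base_expr = rng.lognormal(config.expression_logmean, config.expression_logsd, n)
    high = base_expr >= np.median(base_expr)
    repl = np.array([chrom.replichore(int(m)) for m in mids])
    leading_strand = np.where(repl == 1, "+", "-")
    lagging_strand = np.where(repl == 1, "-", "+")
    p_leading = np.where(high, config.leading_strand_bias, 0.5)
    take_leading = rng.random(n) < p_leading
    strand = np.where(take_leading, leading_strand, lagging_strand)

    # categories with region-biased frequencies
    cat_idx = np.empty(n, dtype=int)
    for lab, w in (("core", _CORE_W), ("noncore", _NONCORE_W)):
        mask = region == lab
        cat_idx[mask] = rng.choice(len(CATEGORIES), size=mask.sum(), p=w / w.sum())
    category = np.array(CATEGORIES, dtype=object)[cat_idx]

    # flags
    flags = [set() for _ in range(n)]
    for i in np.flatnonzero(is_transposon):
        flags[i].add("transposon")
    n_rnase = min(n // 80, 24)
    eligible = np.flatnonzero(~is_transposon)
    rnase_idx = rng.choice(eligible, size=n_rnase, replace=False)
    for i in rnase_idx:
        flags[i].add("ribonuclease")
        category[i] = "RNA degradation and processing"
    remaining = np.setdiff1d(eligible, rnase_idx)
    rrna_idx = rng.choice(remaining, size=min(config.n_rrna, len(remaining)),
                          replace=False)
    for i in rrna_idx:
        flags[i].add("rRNA")
        base_expr[i] *= 50.0                        # residual rRNA dominates depth
    for i in np.flatnonzero(category == "transcription regulation"):
        flags[i].add("transcription_factor")

    # reciprocal region-locked expression programs: a calibrated fraction w of
    # non-core genes follows the pre-switch program, of core genes the
    # post-switch program; the rest are constitutive.  Flagged genes
    # (transposon/ribonuclease/rRNA) are kept out — their switch induction is
    # modelled separately and would otherwise be swamped by program swings.
    w_prog, _ = config.program_calibration()
    u = rng.random(n)
    unflagged = np.array([len(f) == 0 for f in flags])
    program = np.full(n, "constitutive", dtype=object)
    program[(region == "noncore") & (u < w_prog) & unflagged] = "pre"
    program[(region == "core") & (u < w_prog) & unflagged] = "post"

    # per-gene degradation-rate heterogeneity (log2 scale)
    het_log2 = rng.normal(0.0, config.degradation_logsd, n)

    width = len(str(n))
    gene_ids = [f"SE_{i + 1:0{width}d}" for i in range(n)]
    genes = [GeneAnnotation(gene_ids[i], int(starts[i]), int(ends[i]),
                            str(strand[i]), int(glens[i]), str(category[i]),
                            str(region[i]), frozenset(flags[i]))
             for i in range(n)]

    # planted intergenic transcribed elements (putative ncRNAs)
    nc_rows = []
    if config.n_ncrna > 0:
        gaps = []
        for a, b in zip(genes[:-1], genes[1:]):
            if b.start - a.end >= 90:
                gaps.append((a.end, b.start))
        take = rng.choice(len(gaps), size=min(config.n_ncrna, len(gaps)),
                          replace=False)
        for j, gi in enumerate(sorted(take)):
            gs, ge = gaps[gi]
            max_len = min(250, ge - gs - 30)
            ln = int(rng.integers(60, max(61, max_len + 1)))
            s = gs + (ge - gs - ln) // 2
            nc_rows.append({
                "ncrna_id": f"ncRNA_{j + 1:03d}", "start": s, "end": s + ln,
                "strand": "+" if rng.random() < 0.5 else "-",
                "expr": float(rng.lognormal(config.expression_logmean,
                                            config.expression_logsd) * 0.5),
                "supported": bool(j % 2 == 0),
            })
    ncrna = pd.DataFrame(nc_rows).set_index("ncrna_id") if nc_rows else \
        pd.DataFrame(columns=["start", "end", "strand", "expr", "supported"])

    gdf = pd.DataFrame({
        "start": starts, "end": ends, "strand": strand, "length": glens,
        "category": category, "region": region,
        "flags": [",".join(sorted(f)) for f in flags],
        "program": program, "base_expr": base_expr, "het_log2": het_log2,
    }, index=pd.Index(gene_ids, name="gene_id"))

    truth = SyntheticTruth(config, gdf, borders, ncrna)
    return chrom, genes, partition, truth


# --------------------------------------------------------------------------- #
# expression time course
# --------------------------------------------------------------------------- #

def expected_expression(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-gene expected expression (linear, arbitrary units) at every
    timepoint, including all modifiers and the bottleneck."""
    cfg = truth.config
    g = truth.genes
    T = len(cfg.timepoints)
    s = cfg.switch_index
    off = np.zeros((len(g), T))

    _, h = cfg.program_calibration()
    pre = (g["program"] == "pre").to_numpy()
    post = (g["program"] == "post").to_numpy()
    off[pre, :s] += h
    off[pre, s:] -= h
    off[post, :s] -= h
    off[post, s:] += h
    off[post, s + 1:] += cfg.postswitch_ramp_log2   # full induction after the switch

    fl = g["flags"].str.contains("transposon").to_numpy()
    off[fl, s] += cfg.transposon_switch_log2fc
    rn = g["flags"].str.contains("ribonuclease").to_numpy()
    off[rn, s] += cfg.rnase_switch_log2fc

    expr = g["base_expr"].to_numpy()[:, None] * np.exp2(off)
    bott = np.ones(T)
    bott[s] = cfg.bottleneck_factor
    expr = expr * bott[None, :]
    return pd.DataFrame(expr, index=g.index, columns=list(cfg.timepoints))


def degradation_rates(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-gene, per-timepoint degradation rate (linear scale, >0)."""
    cfg = truth.config
    g = truth.genes
    T = len(cfg.timepoints)
    s = cfg.switch_index
    log2r = np.tile(g["het_log2"].to_numpy()[:, None], (1, T))
    for cat, stab in cfg.class_degradation_log2.items():
        mask = (g["category"] == cat).to_numpy()
        log2r[mask, s:] += -stab      # stability -> rate
    log2r[:, s] += cfg.global_degradation_log2_at_switch
    return pd.DataFrame(np.exp2(log2r), index=g.index, columns=list(cfg.timepoints))


def expected_top_share(config: SimConfig, q: float = 0.01) -> float:
    """Analytic expected top-``q`` mRNA share at a pre-switch timepoint.

    Expression is a three-component log-normal mixture (pre-program genes at
    +h, post-program at -h, constitutive at 0, log2 offsets); the share is the
    mixture's partial expectation above its upper ``q`` quantile.  rRNA genes
    are excluded (they are masked from all expression statistics)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    w, h = config.program_calibration()
    sig = config.expression_logsd
    ln2 = np.log(2.0)
    fracs = np.array([0.5 * w, 0.5 * w, 1 - w])
    mus = np.array([h * ln2, -h * ln2, 0.0]) + config.expression_logmean

    def tail(lt):
        return float(fracs @ norm.sf((lt - mus) / sig) - q)

    lt = brentq(tail, min(mus) - 20 * sig, max(mus) + 20 * sig)
    num = fracs @ (np.exp(mus + sig ** 2 / 2) * norm.sf((lt - mus - sig ** 2) / sig))
    den = fracs @ np.exp(mus + sig ** 2 / 2)
    return float(num / den)


def _sample_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = m + d m^2); the d=0 limit is the rounded expectation."""
    if dispersion == 0:
        return np.round(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def _antisense_weights(length: int) -> np.ndarray:
    """Antisense positional weights in the gene's 5'->3' orientation: uniform
    over the first two thirds, doubling linearly over the last third.  The
    ramp is discretized to the ten relative-position deciles (piecewise
    constant), which keeps synthesized tracks compact without changing the
    decile-level profile."""
    edges = np.linspace(0, length, 11).astype(int)
    w = np.empty(length)
    for d in range(10):
        x0, x1 = d / 10.0, (d + 1) / 10.0
        extra = 3.0 * (max(0.0, x1 - 2 / 3) ** 2
                       - max(0.0, x0 - 2 / 3) ** 2) / (2 * (x1 - x0))
        w[edges[d]:edges[d + 1]] = 1.0 + extra
    return w / w.sum()


def generate_timecourse(truth: SyntheticTruth, *, with_coverage: bool = True,
                        counts_seed: int | None = None):
    """Sample the long (full-length mRNA) libraries.

    Returns ``(CountTable, {timepoint: CoverageTrack} or None, truth)`` with
    the truth's ``expected``/``rates``/``bottleneck`` fields filled in.

    Sampling mode: one global scaling constant, calibrated so the first
    timepoint's expected total equals ``long_depth``; later library totals
    scale with the true relative mRNA pool, so the bottleneck is visible in
    raw column sums (as it is when sequencing a fixed culture volume).
    """
    cfg = truth.config
    _, counts_rng, _ = cfg.rngs()
    if counts_seed is not None:     # resample counts over fixed structure
        counts_rng = np.random.default_rng(np.random.SeedSequence(counts_seed))
    expected = expected_expression(truth)
    truth.expected = expected
    truth.rates = degradation_rates(truth)
    bott = np.ones(len(cfg.timepoints))
    bott[cfg.switch_index] = cfg.bottleneck_factor
    truth.bottleneck = pd.Series(bott, index=list(cfg.timepoints))

    len_kb = truth.genes["length"].to_numpy() / 1000.0
    e0 = expected.iloc[:, 0].to_numpy()
    K = cfg.long_depth / float((e0 * len_kb).sum())

    cols, libs = {}, []
    nc_reads_by_tp = {}
    for t in cfg.timepoints:
        mean = expected[t].to_numpy() * len_kb * K
        c = _sample_counts(counts_rng, mean, cfg.nb_dispersion)
        nc_reads = np.round(truth.ncrna["expr"].to_numpy()
                            * (truth.ncrna["end"] - truth.ncrna["start"]).to_numpy()
                            / 1000.0 * K * (cfg.bottleneck_factor
                                            if t == cfg.switch_timepoint else 1.0)
                            ).astype(np.int64) if len(truth.ncrna) else \
            np.zeros(0, dtype=np.int64)
        nc_reads_by_tp[t] = nc_reads
        lib_id = f"long_t{t:g}"
        cols[lib_id] = c
        libs.append(LibraryInfo(lib_id, t, "long",
                                float(c.sum() + nc_reads.sum())))
    counts = CountTable(pd.DataFrame(cols, index=truth.genes.index), libs)

    tracks = None
    if with_coverage:
        tracks = {t: _coverage_from_counts(truth, counts, t, nc_reads_by_tp[t])
                  for t in cfg.timepoints}
    return counts, tracks, truth


def _coverage_from_counts(truth: SyntheticTruth, counts: CountTable,
                          timepoint: float, nc_reads: np.ndarray) -> CoverageTrack:
    """Spread each gene's sampled reads deterministically over its interval:
    (1 - leak) uniformly on the sense strand, leak on the antisense strand with
    a 3'-biased profile."""
    cfg = truth.config
    L = cfg.genome_length
    plus = np.zeros(L, dtype=np.float32)
    minus = np.zeros(L, dtype=np.float32)
    lib_id = counts.column_for_timepoint(timepoint, "long")
    n_reads = counts.counts[lib_id].to_numpy().astype(float)
    g = truth.genes
    starts = g["start"].to_numpy()
    ends = g["end"].to_numpy()
    lens = g["length"].to_numpy()
    strands = g["strand"].to_numpy()
    leak = cfg.antisense_leak
    rl = cfg.read_length
    for i in range(len(g)):
        n = n_reads[i]
        if n == 0:
            continue
        s, e, ln = int(starts[i]), int(ends[i]), int(lens[i])
        sense_density = np.float32(n * (1 - leak) * rl / ln)
        anti = (n * leak * rl) * _antisense_weights(ln)
        if strands[i] == "+":
            interval_add(plus, s, e, sense_density)
            interval_add(minus, s, e, anti.astype(np.float32))
        else:
            interval_add(minus, s, e, sense_density)
            interval_add(plus, s, e, anti[::-1].astype(np.float32))
    for j, (_, row) in enumerate(truth.ncrna.iterrows()):
        if len(nc_reads) == 0 or nc_reads[j] == 0:
            continue
        dens = np.float32(nc_reads[j] * rl / (row["end"] - row["start"]))
        target = plus if row["strand"] == "+" else minus
        interval_add(target, int(row["start"]), int(row["end"]), dens)
    lib = counts.library(lib_id)
    return CoverageTrack(lib_id, timepoint, True, plus, minus=minus,
                         library_size=lib.library_size)


# --------------------------------------------------------------------------- #
# fragment (degradome) libraries
# --------------------------------------------------------------------------- #

def generate_fragments(truth: SyntheticTruth, *,
                       fragment_seed: int | None = None) -> CountTable:
    """Sample fragment libraries at the configured fragment timepoints.

    Per-gene fragment expectation is proportional to the long-library
    expectation times the true degradation rate.  Each library is multinomial
    with total round(fragment_depth x relative fragment pool), where the pool
    is measured against a rate-of-one baseline; the recorded ``library_size``
    is the nominal ``fragment_depth``, so genuinely global rate shifts remain
    visible in the degradation index.
    """
    cfg = truth.config
    if truth.expected is None:
        raise ValueError("run generate_timecourse first")
    _, _, frag_rng = cfg.rngs()
    if fragment_seed is not None:   # resample fragments over fixed structure
        frag_rng = np.random.default_rng(np.random.SeedSequence(fragment_seed))
    len_kb = truth.genes["length"].to_numpy() / 1000.0
    cols, libs = {}, []
    for ti in cfg.fragment_timepoint_indices:
        t = cfg.timepoints[ti]
        e = truth.expected[t].to_numpy() * len_kb
        f = e * truth.rates[t].to_numpy()
        pool = float(f.sum() / e.sum())
        n_total = int(round(cfg.fragment_depth * pool))
        c = frag_rng.multinomial(n_total, f / f.sum())
        lib_id = f"frag_t{t:g}"
        cols[lib_id] = c
        libs.append(LibraryInfo(lib_id, t, "fragment", float(cfg.fragment_depth)))
    return CountTable(pd.DataFrame(cols, index=truth.genes.index), libs)


def generate_fragment_tracks(truth: SyntheticTruth,
                             frag_counts: CountTable) -> dict:
    """Per-timepoint stranded fragment coverage (sense-only, uniform spread),
    including reads for the 'supported' half of the planted ncRNAs."""
    cfg = truth.config
    out = {}
    g = truth.genes
    frag_len = 35                         # middle of the 20-50 nt window
    for lib in frag_counts.libraries:
        plus = np.zeros(cfg.genome_length, dtype=np.float32)
        minus = np.zeros(cfg.genome_length, dtype=np.float32)
        n_reads = frag_counts.counts[lib.library_id].to_numpy()
        for i in range(len(g)):
            if n_reads[i] == 0:
                continue
            row = g.iloc[i]
            dens = np.float32(n_reads[i] * frag_len / row["length"])
            target = plus if row["strand"] == "+" else minus
            interval_add(target, int(row["start"]), int(row["end"]), dens)
        for _, row in truth.ncrna[truth.ncrna["supported"]].iterrows():
            n = max(10.0, row["expr"] * 20.0)
            dens = np.float32(n * frag_len / (row["end"] - row["start"]))
            target = plus if row["strand"] == "+" else minus
            interval_add(target, int(row["start"]), int(row["end"]), dens)
        out[lib.timepoint] = CoverageTrack(lib.library_id, lib.timepoint, True,
                                           plus, minus=minus,
                                           library_size=lib.library_size)
    return out


def write_simulation(bundle: dict, outdir: str) -> dict:
    """Write a simulated dataset to disk in the pipeline's input formats.

    Emits annotation GFF3, regions BED, flags TSV, long/fragment count TSVs,
    per-library stranded bedGraphs, ground-truth TSVs and a ready-to-run
    pipeline YAML.  Returns the path map.
    """
    import os

    import yaml

    from . import genome_io

    os.makedirs(outdir, exist_ok=True)
    chrom, genes = bundle["chrom"], bundle["genes"]
    truth: SyntheticTruth = bundle["truth"]
    paths = {
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "regions": os.path.join(outdir, "regions.bed"),
        "flags": os.path.join(outdir, "flags.tsv"),
        "long_counts": os.path.join(outdir, "long_counts.tsv"),
        "frag_counts": os.path.join(outdir, "frag_counts.tsv"),
    }
    genome_io.write_annotation(paths["annotation"], chrom, genes)
    genome_io.write_region_bed(paths["regions"], chrom, bundle["partition"])
    genome_io.write_flags_tsv(paths["flags"], genes)
    genome_io.write_count_table(paths["long_counts"], bundle["long_counts"])
    genome_io.write_count_table(paths["frag_counts"], bundle["frag_counts"])
    for key in ("tracks", "frag_tracks"):
        for t, tr in (bundle.get(key) or {}).items():
            for strand, vec in (("plus", tr.plus), ("minus", tr.minus)):
                genome_io.write_track(
                    vec, "bedgraph",
                    os.path.join(outdir, f"{tr.library_id}_{strand}.bedgraph"),
                    chrom_name=chrom.name)
    truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
    truth.ncrna.to_csv(os.path.join(outdir, "truth_ncrna.tsv"), sep="\t")
    if truth.expected is not None:
        truth.expected.to_csv(os.path.join(outdir, "truth_expected.tsv"),
                              sep="\t", float_format="%.6g")
        truth.rates.to_csv(os.path.join(outdir, "truth_rates.tsv"),
                           sep="\t", float_format="%.6g")
    cfg = truth.config
    pipe = {
        "annotation": paths["annotation"], "regions": paths["regions"],
        "flags": paths["flags"], "long_counts": paths["long_counts"],
        "frag_counts": paths["frag_counts"], "coverage_dir": outdir,
        "outdir": os.path.join(outdir, "results"),
        "switch_timepoint": float(cfg.switch_timepoint),
        "seed": int(cfg.seed),
    }
    paths["pipeline"] = os.path.join(outdir, "pipeline.yaml")
    with open(paths["pipeline"], "w") as fh:
        yaml.safe_dump(pipe, fh, sort_keys=True)
    return paths


def simulate(config: SimConfig, *, with_coverage: bool = True):
    """Run the full generator.  Returns a dict bundle of everything."""
    chrom, genes, partition, truth = generate_genome(config)
    long_counts, tracks, truth = generate_timecourse(truth,
                                                     with_coverage=with_coverage)
    frag_counts = generate_fragments(truth)
    frag_tracks = generate_fragment_tracks(truth, frag_counts) \
        if with_coverage else None
    return {
        "chrom": chrom, "genes": genes, "partition": partition, "truth": truth,
        "long_counts": long_counts, "tracks": tracks,
        "frag_counts": frag_counts, "frag_tracks": frag_tracks,
    }
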