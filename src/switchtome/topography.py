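"""Genome-scale transcription topography.

Pervasive-transcription saturation metrics, replichore strand preference,
core/non-core macro-region enrichment with switch detection, transposon
border-cluster induction, antisense quantification, and intergenic ncRNA
candidate calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (ChromosomeModel, CoverageTrack, GeneAnnotation,
                    RegionPartition, ValidationError, interval_positions,
                    interval_slice, interval_sum)


@dataclass
class BinnedGenomeStat:
    bin_size: int
    values: np.ndarray          # one per bin, circular; NaN = missing
    timepoint: float
    statistic: str


@dataclass
class RegionEnrichmentSeries:
    table: pd.DataFrame         # columns: timepoint, region, mean_expression, log2_enrichment
    switch_detected: bool
    switch_sign: int            # -1: noncore repressed after the switch; +1: opposite; 0: none

    def enrichment(self, timepoint: float, region: str) -> float:
        t = self.table
        row = t[(t["timepoint"] == timepoint) & (t["region"] == region)]
        return float(row["log2_enrichment"].iloc[0])


# --------------------------------------------------------------------------- #
# pervasive transcription
# --------------------------------------------------------------------------- #

def pool_tracks(tracks: Iterable[CoverageTrack]) -> CoverageTrack:
    """Sum a set of stranded per-base tracks into one pooled track."""
    tracks = list(tracks)
    if not tracks:
        raise ValidationError("empty track set")
    plus = np.zeros(len(tracks[0].plus), dtype=np.float64)
    minus = np.zeros_like(plus)
    size = 0.0
    for tr in tracks:
        plus += tr.plus
        minus += tr.minus if tr.minus is not None else 0
        size += tr.library_size
    return CoverageTrack("pooled", tracks[0].timepoint, True, plus, minus=minus,
                         library_size=size)


def transcribed_fraction(tracks: Iterable[CoverageTrack], min_cov: float = 1.0) -> dict:
    """Fraction of the genome represented in the pooled libraries.

    ``either_strand``: positions with >= min_cov on plus OR minus;
    ``unstranded``: positions with plus+minus >= min_cov;
    ``singleton_fraction``: positions with total coverage exactly 1 among
    positions with total coverage >= 1 (a saturation diagnostic).
    """
    pooled = pool_tracks(tracks)
    plus, minus = pooled.plus, pooled.minus
    total = plus + minus
    n = len(total)
    either = float(((plus >= min_cov) | (minus >= min_cov)).mean())
    unstranded = float((total >= min_cov).mean())
    expressed = total >= 1
    singleton = float((total[expressed] == 1).mean()) if expressed.any() else 0.0
    return {"either_strand": either, "unstranded": unstranded,
            "singleton_fraction": singleton, "n_positions": n}


# --------------------------------------------------------------------------- #
# strand preference
# --------------------------------------------------------------------------- #

def _bin_sums(vec: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = -(-len(vec) // bin_size)
    pad = n_bins * bin_size - len(vec)
    if pad:
        vec = np.concatenate([vec, np.zeros(pad, dtype=vec.dtype)])
    return vec.reshape(n_bins, bin_size).sum(axis=1)


def strand_preference(track: CoverageTrack, chrom: ChromosomeModel,
                      bin_size: int = 10_000) -> BinnedGenomeStat:
    """Per-bin leading-strand preference P = (L - G)/(L + G).

    Leading coverage L is plus-strand coverage on replichore 1 and minus-strand
    coverage on replichore 2 (replichores split by origin/terminus); G is the
    lagging coverage.  Bins with no coverage are NaN.
    """
    if not track.stranded:
        raise ValidationError("strand preference needs a stranded track")
    plus = _bin_sums(np.asarray(track.plus, dtype=np.float64), bin_size)
    minus = _bin_sums(np.asarray(track.minus, dtype=np.float64), bin_size)
    n_bins = len(plus)
    mids = (np.arange(n_bins) * bin_size + bin_size // 2) % chrom.genome_length
    repl1 = np.array([chrom.replichore(int(m)) == 1 for m in mids])
    lead = np.where(repl1, plus, minus)
    lag = np.where(repl1, minus, plus)
    with np.errstate(invalid="ignore", divide="ignore"):
        pref = (lead - lag) / (lead + lag)
    pref[(lead + lag) == 0] = np.nan
    return BinnedGenomeStat(bin_size, pref, track.timepoint, "strand_preference")


# --------------------------------------------------------------------------- #
# macro-region enrichment
# --------------------------------------------------------------------------- #

def binned_expression(track: CoverageTrack, bin_size: int) -> np.ndarray:
    """Per-bin coverage (both strands) per million aligned reads."""
    total = _bin_sums(np.asarray(track.total, dtype=np.float64), bin_size)
    return total / (track.library_size / 1e6)


def region_enrichment(tracks: Mapping[float, CoverageTrack],
                      partition: RegionPartition, bin_size: int = 10_000,
                      *, switch_timepoint: float | None = None,
                      epsilon: float = 0.2,
                      mask_genes: Sequence[GeneAnnotation] = ()) -> RegionEnrichmentSeries:
    """Per-timepoint log2 enrichment of each macro-region vs the genome mean.

    E_{r,t} = log2(mean bin expression in r / genome-wide mean bin expression).
    A switch is detected when the sign of E_noncore is >= +epsilon at every
    timepoint before ``switch_timepoint`` and <= -epsilon from it on
    (switch_sign = -1), or the mirror-image pattern (+1).

    Bins overlapping a gene in ``mask_genes`` (typically rRNA, whose residual
    signal would otherwise dominate a region mean) are excluded throughout.
    """
    labels = partition.label_vector(bin_size)
    keep = np.ones(len(labels), dtype=bool)
    for g in mask_genes:
        for p in (g.start, (g.end - 1) % partition.genome_length):
            keep[p // bin_size] = False
        if g.start < g.end:
            keep[g.start // bin_size:(g.end - 1) // bin_size + 1] = False
    rows = []
    for t in sorted(tracks):
        vals = binned_expression(tracks[t], bin_size)
        if len(vals) != len(labels):
            raise ValidationError("bin count mismatch between track and partition")
        gmean = vals[keep].mean()
        for reg in ("core", "noncore"):
            mask = (labels == reg) & keep
            if not mask.any():
                raise ValidationError(f"region {reg!r} has zero bins at this bin size")
            m = vals[mask].mean()
            rows.append({"timepoint": t, "region": reg, "mean_expression": m,
                         "log2_enrichment": float(np.log2(m / gmean))
                         if m > 0 and gmean > 0 else np.nan})
    table = pd.DataFrame(rows)
    detected, sign = False, 0
    if switch_timepoint is not None:
        nc = table[table["region"] == "noncore"].set_index("timepoint")[
            "log2_enrichment"]
        before = nc[nc.index < switch_timepoint]
        after = nc[nc.index >= switch_timepoint]
        if len(before) and len(after):
            if (before >= epsilon).all() and (after <= -epsilon).all():
                detected, sign = True, -1
            elif (before <= -epsilon).all() and (after >= epsilon).all():
                detected, sign = True, +1
    return RegionEnrichmentSeries(table, detected, sign)


def region_enrichment_from_matrix(expr, genes: Sequence[GeneAnnotation],
                                  partition: RegionPartition,
                                  **kwargs) -> RegionEnrichmentSeries:
    """Gene-level variant: region mean of normalized gene expression.

    ``expr`` is an ExpressionMatrix (see :mod:`switchtome.programs`); genes
    play the role of bins.
    """
    by_gene = {g.gene_id: g.region for g in genes}
    rows = []
    for t in expr.timepoints():
        vals = expr.at_timepoint(t)
        lab = np.array([by_gene.get(g, "") for g in vals.index])
        gmean = vals.mean()
        for reg in ("core", "noncore"):
            m = vals[lab == reg].mean()
            rows.append({"timepoint": t, "region": reg, "mean_expression": m,
                         "log2_enrichment": float(np.log2(m / gmean))})
    table = pd.DataFrame(rows)
    series = RegionEnrichmentSeries(table, False, 0)
    st = kwargs.get("switch_timepoint")
    if st is not None:
        eps = kwargs.get("epsilon", 0.2)
        nc = table[table["region"] == "noncore"].set_index("timepoint")[
            "log2_enrichment"]
        before, after = nc[nc.index < st], nc[nc.index >= st]
        if len(before) and len(after):
            if (before >= eps).all() and (after <= -eps).all():
                series.switch_detected, series.switch_sign = True, -1
            elif (before <= -eps).all() and (after >= eps).all():
                series.switch_detected, series.switch_sign = True, +1
    return series


# --------------------------------------------------------------------------- #
# transposon border induction
# --------------------------------------------------------------------------- #

def _log2_fold_changes(expr, pre_tp: float, switch_tp: float,
                       pseudocount: float = 0.5) -> pd.Series:
    pre = expr.at_timepoint(pre_tp)
    post = expr.at_timepoint(switch_tp)
    return np.log2((post + pseudocount) / (pre + pseudocount))


def border_induction(expr, genes: Sequence[GeneAnnotation],
                     partition: RegionPartition,
                     switch_pair: tuple, *, window: int = 5_000,
                     n_perm: int = 10_000, seed: int = 0,
                     exact_limit: int = 200_000) -> dict:
    """Induction of border transposon clusters at the switch.

    Statistic: median log2 fold-change (switch vs pre) over transposon-flagged
    genes within ``window`` bp of any core/non-core border.  Two p-values are
    reported: a one-sided rank-sum against all other genes' fold-changes, and
    a label-permutation p (exhaustive when the number of distinct subsets is
    small, Monte-Carlo otherwise).
    """
    pre_tp, switch_tp = switch_pair
    fc = _log2_fold_changes(expr, pre_tp, switch_tp)
    genome_length = partition.genome_length
    borders = partition.borders

    def near_border(g: GeneAnnotation) -> bool:
        mid = (g.start + g.length // 2) % genome_length
        for b in borders:
            d = abs(mid - b)
            if min(d, genome_length - d) <= window:
                return True
        return False

    in_set = [g.gene_id for g in genes
              if g.has_flag("transposon") and near_border(g) and g.gene_id in fc.index]
    if not in_set:
        raise ValidationError(
            f"no transposon-flagged genes within {window} bp of a region border")
    others = [g for g in fc.index if g not in set(in_set)]
    set_fc = fc[in_set].to_numpy()
    other_fc = fc[others].to_numpy()
    observed = float(np.median(set_fc))
    p_mw = float(stats.mannwhitneyu(set_fc, other_fc,
                                    alternative="greater").pvalue)

    all_fc = fc.to_numpy()
    k, n = len(set_fc), len(all_fc)
    if comb(n, k) <= exact_limit:
        hits = total = 0
        for subset in combinations(range(n), k):
            total += 1
            if np.median(all_fc[list(subset)]) >= observed:
                hits += 1
        p_perm = hits / total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            m = np.median(rng.choice(all_fc, size=k, replace=False))
            if m >= observed:
                hits += 1
        p_perm = (1 + hits) / (1 + n_perm)
    return {"fold": float(2 ** observed), "median_log2fc": observed,
            "n_set": k, "p_mw": p_mw, "p_perm": float(p_perm)}


# --------------------------------------------------------------------------- #
# antisense transcription
# --------------------------------------------------------------------------- #

def antisense_fraction(tracks: Iterable[CoverageTrack],
                       genes: Sequence[GeneAnnotation]) -> dict:
    """Antisense share of transcription over annotated gene bodies.

    ``overall`` = antisense base-coverage / total base-coverage within gene
    bodies (pooled libraries); ``positional_profile`` = the same ratio per
    relative-position decile along the gene, 5'->3' in the gene's orientation.
    """
    pooled = pool_tracks(tracks)
    if not pooled.stranded:
        raise ValidationError("antisense quantification needs stranded tracks")
    anti_total = sense_total = 0.0
    anti_dec = np.zeros(10)
    tot_dec = np.zeros(10)
    for g in genes:
        sense = interval_slice(pooled.strand_vector(g.strand), g.start, g.end)
        anti = interval_slice(
            pooled.strand_vector("-" if g.strand == "+" else "+"), g.start, g.end)
        if g.strand == "-":
            sense, anti = sense[::-1], anti[::-1]
        sense_total += sense.sum()
        anti_total += anti.sum()
        edges = np.linspace(0, len(sense), 11).astype(int)
        for d in range(10):
            sl = slice(edges[d], edges[d + 1])
            anti_dec[d] += anti[sl].sum()
            tot_dec[d] += anti[sl].sum() + sense[sl].sum()
    denom = anti_total + sense_total
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(tot_dec > 0, anti_dec / tot_dec, 0.0)
    return {"overall": float(anti_total / denom) if denom else 0.0,
            "positional_profile": profile}


# --------------------------------------------------------------------------- #
# intergenic ncRNA candidates
# --------------------------------------------------------------------------- #

def _runs_from_mask(mask: np.ndarray, circular: bool = True):
    """(start, end) half-open runs of True; a run wrapping the origin is
    reported as one (start > end) interval."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == len(mask):
        s, _ = runs[-1]
        _, e = runs[0]
        runs = runs[1:-1] + [(s, e)]
    return runs


def intergenic_candidates(long_tracks: Iterable[CoverageTrack],
                          genes: Sequence[GeneAnnotation],
                          chrom: ChromosomeModel, *,
                          fragment_tracks: Iterable[CoverageTrack] | None = None,
                          min_len: int = 50, max_len: int = 1000,
                          min_expr: float = 1.0, merge_gap: int = 20,
                          support_fraction: float = 0.5) -> pd.DataFrame:
    """Call putative ncRNA loci from intergenic transcribed runs.

    Per strand, maximal runs of positions with no same-strand gene overlap and
    normalized coverage (per million aligned reads) >= ``min_expr`` in at least
    one long library; runs separated by gaps < ``merge_gap`` are merged, then
    filtered to lengths in [min_len, max_len].  A candidate is 'supported' when
    pooled fragment libraries cover >= ``support_fraction`` of the run.
    """
    if min_len > max_len:
        raise ValidationError("min_len > max_len")
    long_tracks = list(long_tracks)
    L = chrom.genome_length
    frag = pool_tracks(list(fragment_tracks)) if fragment_tracks else None
    rows = []
    for strand in ("+", "-"):
        genic = np.zeros(L, dtype=bool)
        for g in genes:
            if g.strand == strand:
                genic[interval_positions(g.start, g.end, L)] = True
        exprmask = np.zeros(L, dtype=bool)
        best = np.zeros(L)
        for tr in long_tracks:
            norm = np.asarray(tr.strand_vector(strand), dtype=np.float64) \
                / (tr.library_size / 1e6)
            exprmask |= norm >= min_expr
            best = np.maximum(best, norm)
        mask = exprmask & ~genic
        runs = _runs_from_mask(mask, circular=chrom.circular)
        runs.sort(key=lambda r: r[0])
        merged = []
        for (s, e) in runs:
            if merged:
                ps, pe = merged[-1]
                gap = s - pe if pe <= s else -1
                if 0 <= gap < merge_gap and not genic[pe:s].any():
                    merged[-1] = (ps, e)
                    continue
            merged.append((s, e))
        for (s, e) in merged:
            ln = e - s if e > s else L - s + e
            if not (min_len <= ln <= max_len):
                continue
            mean_expr = float(interval_sum(best, s, e) / ln)
            supported = False
            if frag is not None:
                fv = interval_slice(frag.strand_vector(strand), s, e)
                supported = bool((fv > 0).mean() >= support_fraction)
            rows.append({"start": s, "end": e, "strand": strand, "length": ln,
                         "mean_expression": mean_expr, "supported": supported})
    df = pd.DataFrame(rows, columns=["start", "end", "strand", "length",
                                     "mean_expression", "supported"])
    return df.sort_values(["start", "strand"]).reset_index(drop=True)


# --------------------------------------------------------------------------- #
# inspection plot
# --------------------------------------------------------------------------- #

def plot_genome_polar(stat: BinnedGenomeStat, path: str) -> None:
    """Quick polar rendering of a binned genome statistic (inspection only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.linspace(0, 2 * np.pi, len(stat.values), endpoint=False)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="polar")
    vals = np.nan_to_num(stat.values, nan=0.0)
    ax.bar(theta, vals, width=2 * np.pi / len(vals), bottom=1.0)
    ax.set_title(f"{stat.statistic} (t={stat.timepoint:g} h)")
    ax.set_xticks([])
    fig.savefig(path, dpi=100)
    plt.close(fig)
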