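"""Targeted mRNA degradation from paired full-length and fragment libraries.

Fragment-read filtering, the per-gene degradation index (DI), relative-rate
classification, class-level stability enrichment, and browser tracks.

DI_{g,t} = log2((F_{g,t}+c)/N^F_t) - log2((S_{g,t}+c)/N^S_t) where F are
full-length counts, S fragment counts, N the respective library totals and c
a pseudocount.  Lower DI = faster degradation.  relative_DI is DI centered to
the per-timepoint median over unmasked genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (CountTable, CoverageTrack, GeneAnnotation, ValidationError,
                    interval_positions)
from . import genome_io


@dataclass
class FragmentReadSet:
    """Small-RNA (degradome) reads: one row per read with position (0-based
    start), strand and length in nt."""
    reads: pd.DataFrame            # columns: position, strand, length
    timepoint: float
    depth: float = 0.0

    def __post_init__(self):
        need = {"position", "strand", "length"}
        if not need <= set(self.reads.columns):
            raise ValidationError(f"read table needs columns {sorted(need)}")
        if (self.reads["length"] <= 0).any():
            raise ValidationError("non-positive read length")


@dataclass
class DegradationTable:
    table: pd.DataFrame            # per gene/timepoint: full_count, fragment_count,
                                   # DI, relative_DI, class, masked
    pseudocount: float
    min_full: int
    delta: float                   # class threshold, log2 units

    def at_timepoint(self, t: float) -> pd.DataFrame:
        return self.table[self.table["timepoint"] == t].set_index("gene_id")

    def timepoints(self) -> list:
        return sorted(self.table["timepoint"].unique())


@dataclass
class StabilityEnrichment:
    label: str
    n: int
    fold: float                    # linear-scale stability vs all other genes
    p: float
    q: float = float("nan")


# --------------------------------------------------------------------------- #
# fragment filtering
# --------------------------------------------------------------------------- #

def transcribed_regions(track: CoverageTrack, min_norm_cov: float = 1.0) -> dict:
    """Per-strand boolean masks of transcribed positions (normalized coverage,
    per million aligned reads, >= threshold) from a matched long library."""
    if not track.stranded:
        raise ValidationError("transcribed regions need a stranded track")
    scale = 1e6 / track.library_size
    return {"+": np.asarray(track.plus) * scale >= min_norm_cov,
            "-": np.asarray(track.minus) * scale >= min_norm_cov}


def filter_fragments(reads: FragmentReadSet, regions: Mapping[str, np.ndarray],
                     min_len: int = 20, max_len: int = 50) -> tuple:
    """Keep fragments of length in [min_len, max_len] lying fully within a
    transcribed region on the SAME strand; everything else is discarded.

    Returns ``(FragmentReadSet, report_dict)`` with per-rule discard counts.
    Idempotent: filtering a filtered set changes nothing.
    """
    if not any(np.asarray(m).any() for m in regions.values()):
        raise ValidationError("no transcribed regions supplied")
    L = len(next(iter(regions.values())))
    df = reads.reads
    lengths = df["length"].to_numpy()
    len_ok = (lengths >= min_len) & (lengths <= max_len)
    sense_ok = np.zeros(len(df), dtype=bool)
    pos = df["position"].to_numpy()
    strands = df["strand"].to_numpy()
    for i in range(len(df)):
        if not len_ok[i]:
            continue
        mask = regions[strands[i]]
        idx = interval_positions(int(pos[i]) % L,
                                 (int(pos[i]) + int(lengths[i])) % L, L)
        sense_ok[i] = bool(mask[idx].all())
    keep = len_ok & sense_ok
    report = {
        "n_input": int(len(df)),
        "discarded_length": int((~len_ok).sum()),
        "discarded_sense": int((len_ok & ~sense_ok).sum()),
        "n_kept": int(keep.sum()),
    }
    out = FragmentReadSet(df[keep].reset_index(drop=True), reads.timepoint,
                          reads.depth)
    return out, report


# --------------------------------------------------------------------------- #
# degradation index
# --------------------------------------------------------------------------- #

def degradation_index(full: CountTable, frag: CountTable, *,
                      pseudocount: float = 0.5, min_full: int = 10,
                      delta: float = 1.0) -> DegradationTable:
    """Per-gene degradation index at every timepoint shared by the two tables.

    Genes with full-length count < ``min_full`` are masked (DI undefined for
    classification; the value is still reported).  relative_DI is median-
    centered over unmasked genes per timepoint; class thresholds are
    +/- ``delta`` log2 units (<= -delta: faster; >= +delta: slower).
    """
    if set(full.genes) != set(frag.genes):
        missing = set(full.genes) ^ set(frag.genes)
        raise ValidationError(
            f"gene sets differ between full and fragment tables: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")
    frag_tps = {lib.timepoint for lib in frag.libraries}
    full_tps = {lib.timepoint for lib in full.libraries}
    tps = sorted(frag_tps & full_tps)
    if not tps:
        raise ValidationError("no shared timepoints between full and fragment tables")
    rows = []
    genes = full.genes
    for t in tps:
        fcol = full.column_for_timepoint(t, "long")
        scol = frag.column_for_timepoint(t, "fragment")
        NF = full.library(fcol).library_size or full.counts[fcol].sum()
        NS = frag.library(scol).library_size or frag.counts[scol].sum()
        F = full.counts.loc[genes, fcol].to_numpy(dtype=float)
        S = frag.counts.loc[genes, scol].to_numpy(dtype=float)
        di = np.log2((F + pseudocount) / NF) - np.log2((S + pseudocount) / NS)
        masked = F < min_full
        med = float(np.median(di[~masked])) if (~masked).any() else 0.0
        rel = di - med
        cls = np.where(masked, "masked",
                       np.where(rel <= -delta, "faster",
                                np.where(rel >= delta, "slower", "neutral")))
        for i, gid in enumerate(genes):
            rows.append({"gene_id": gid, "timepoint": t,
                         "full_count": int(F[i]), "fragment_count": int(S[i]),
                         "DI": float(di[i]), "relative_DI": float(rel[i]),
                         "class": cls[i], "masked": bool(masked[i])})
    return DegradationTable(pd.DataFrame(rows), pseudocount, min_full, delta)


def global_degradation_shift(table: DegradationTable, tp_a: float,
                             tp_b: float) -> dict:
    """Difference of unmasked-gene median DI between two timepoints (b - a);
    negative values mean accelerated degradation at b."""
    def med(t):
        sub = table.at_timepoint(t)
        return float(sub.loc[~sub["masked"], "DI"].median())
    return {"delta_median_DI": med(tp_b) - med(tp_a)}


def stability_class_enrichment(table: DegradationTable,
                               class_map: Mapping[str, Sequence[str]],
                               timepoint: float, *,
                               min_genes: int = 3) -> list:
    """Relative stability of gene classes at one timepoint.

    fold = 2^(mean relative_DI of class - mean relative_DI of complement);
    fold > 1 = more stable than the rest, < 1 = degraded faster.  p from a
    two-sided rank-sum of relative_DI (class vs complement), BH-adjusted
    across classes.  Classes with < ``min_genes`` unmasked genes are skipped.
    """
    sub = table.at_timepoint(timepoint)
    sub = sub[~sub["masked"]]
    out, skipped = [], []
    for label, members in class_map.items():
        in_class = sub.index.isin(set(members))
        n = int(in_class.sum())
        if n < min_genes:
            skipped.append(label)
            continue
        x = sub.loc[in_class, "relative_DI"].to_numpy()
        y = sub.loc[~in_class, "relative_DI"].to_numpy()
        fold = float(2 ** (x.mean() - y.mean()))
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        out.append(StabilityEnrichment(label, n, fold, p))
    if out:
        qs = multipletests([r.p for r in out], method="fdr_bh")[1]
        for r, q in zip(out, qs):
            r.q = float(q)
    if skipped:
        import warnings
        warnings.warn(f"classes skipped (fewer than {min_genes} unmasked genes): "
                      f"{skipped}")
    return out


def degradation_track(table: DegradationTable, genes: Sequence[GeneAnnotation],
                      timepoint: float, path: str, *,
                      chrom_name: str = "chr") -> None:
    """bedGraph of relative_DI painted over gene bodies (masked genes omitted);
    records sorted and non-overlapping for disjoint genes."""
    sub = table.at_timepoint(timepoint)
    vals = {gid: (row["relative_DI"] if not row["masked"] else float("nan"))
            for gid, row in sub.iterrows()}
    genome_io.write_track(pd.Series(vals), "bedgraph", path,
                          chrom_name=chrom_name, genes=genes)
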