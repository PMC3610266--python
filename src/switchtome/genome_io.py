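"""Readers and writers for the on-disk formats shared by every pipeline stage.

Formats: GFF3 (gene annotation, 1-based inclusive), BED (core/non-core region
partition, 0-based half-open), bedGraph (per-base coverage and score tracks),
TSV (counts, per-gene flags/categories, results).  Internally everything is
0-based half-open; the conversion happens here and nowhere else.
"""

from __future__ import annotations

from typing import Sequence

import gffutils
import numpy as np
import pandas as pd

from .model import (ChromosomeModel, CountTable, CoverageTrack, GeneAnnotation,
                    LibraryInfo, RegionPartition, ValidationError,
                    interval_length, interval_sum, midpoint)

FLOAT_FMT = "%.6g"


# --------------------------------------------------------------------------- #
# annotation
# --------------------------------------------------------------------------- #

def read_region_bed(path: str, genome_length: int) -> RegionPartition:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValidationError(f"region BED line lacks a label: {line!r}")
            intervals.append((int(fields[1]), int(fields[2]) % genome_length,
                              fields[3]))
    return RegionPartition(intervals, genome_length)


def read_flags_tsv(path: str) -> pd.DataFrame:
    """TSV with columns gene_id, category, flags (comma-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene_id", "category"):
        if col not in df.columns:
            raise ValidationError(f"flags TSV missing column {col!r}")
    if "flags" not in df.columns:
        df["flags"] = ""
    return df.set_index("gene_id")


def read_annotation(gff_path: str, region_bed: str, flags_tsv: str,
                    *, circular: bool = True, origin: int = 0,
                    terminus: int | None = None):
    """Load the full genomic model.

    Returns ``(ChromosomeModel, list[GeneAnnotation], RegionPartition)``.
    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Genes without a region label in the flags table get one by midpoint lookup.
    """
    genome_length = None
    chrom_name = None
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                chrom_name = parts[1]
                genome_length = int(parts[3])
                break
    if genome_length is None:
        raise ValidationError(f"{gff_path}: no ##sequence-region directive")

    chrom = ChromosomeModel(chrom_name, genome_length, circular=circular,
                            origin=origin, terminus=terminus)
    partition = read_region_bed(region_bed, genome_length)
    flags = read_flags_tsv(flags_tsv)

    db = gffutils.create_db(gff_path, ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneAnnotation] = []
    seen = set()
    for feat in db.features_of_type("gene", order_by="start"):
        gid = feat.id
        if gid in seen:
            raise ValidationError(f"duplicate gene_id {gid}")
        seen.add(gid)
        start, end = feat.start - 1, feat.end          # GFF3 -> half-open
        if feat.strand not in ("+", "-"):
            raise ValidationError(f"gene {gid}: unknown strand {feat.strand!r}")
        if end > genome_length:                        # origin-wrapping convention
            if not circular:
                raise ValidationError(f"gene {gid} beyond end of linear chromosome")
            end -= genome_length                       # stored with start > end
        if not (0 <= start < genome_length) or start == end:
            raise ValidationError(f"gene {gid} outside chromosome bounds")
        length = interval_length(start, end, genome_length)
        category, region, flagset = "unknown", "", frozenset()
        if gid in flags.index:
            row = flags.loc[gid]
            category = row["category"] or "unknown"
            region = row["region"] if "region" in row.index else ""
            flagset = frozenset(f for f in row["flags"].split(",") if f)
        if not region:
            region = partition.label_at(midpoint(start, end, genome_length))
        genes.append(GeneAnnotation(gid, start, end, feat.strand, length,
                                    category, region, flagset))
    return chrom, genes, partition


def write_annotation(path_gff: str, chrom: ChromosomeModel,
                     genes: Sequence[GeneAnnotation]) -> None:
    with open(path_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom.name} 1 {chrom.genome_length}\n")
        for g in genes:
            start1 = g.start + 1
            end1 = g.end if g.end > g.start else chrom.genome_length + g.end
            fh.write(f"{chrom.name}\tswitchtome\tgene\t{start1}\t{end1}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def write_region_bed(path: str, chrom: ChromosomeModel,
                     partition: RegionPartition) -> None:
    with open(path, "w") as fh:
        for (s, e, lab) in partition.intervals:
            if s < e:
                fh.write(f"{chrom.name}\t{s}\t{e}\t{lab}\n")
            elif e == 0:
                fh.write(f"{chrom.name}\t{s}\t{chrom.genome_length}\t{lab}\n")
            else:  # wrapping interval written as two records
                fh.write(f"{chrom.name}\t{s}\t{chrom.genome_length}\t{lab}\n")
                fh.write(f"{chrom.name}\t0\t{e}\t{lab}\n")


def write_flags_tsv(path: str, genes: Sequence[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\tregion\tflags\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.category}\t{g.region}\t"
                     f"{','.join(sorted(g.flags))}\n")


# --------------------------------------------------------------------------- #
# coverage
# --------------------------------------------------------------------------- #

def read_bedgraph(path: str, chrom: ChromosomeModel) -> np.ndarray:
    """Dense per-base vector from a bedGraph; untouched positions are 0.

    Overlapping records are an error (the format forbids them); records past
    the chromosome end are an error on a linear model and wrap on a circular one.
    """
    vec = np.zeros(chrom.genome_length, dtype=np.float64)
    filled = np.zeros(chrom.genome_length, dtype=bool)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            name, s, e, v = line.split("\t")[:4]
            s, e, v = int(s), int(e), float(v)
            if v < 0:
                raise ValidationError(f"negative bedGraph value at {s}-{e}")
            if e > chrom.genome_length:
                if not chrom.circular:
                    raise ValidationError(
                        f"bedGraph interval {s}-{e} beyond linear chromosome end")
                e = e % chrom.genome_length
            idx = (np.arange(s, e) if s < e
                   else np.concatenate([np.arange(s, chrom.genome_length),
                                        np.arange(0, e)]))
            if filled[idx].any():
                raise ValidationError(f"overlapping bedGraph records at {s}-{e}")
            filled[idx] = True
            vec[idx] = v
    return vec


def read_coverage(bedgraph_path: str, chrom: ChromosomeModel,
                  strand: str = "unstranded", *, minus_path: str | None = None,
                  library_id: str = "lib", timepoint: float = 0.0,
                  library_size: float = 0.0) -> CoverageTrack:
    """Load one library's coverage.

    ``strand='unstranded'`` gives a single-vector track; ``strand='+'`` with
    ``minus_path`` gives a stranded track.
    """
    plus = read_bedgraph(bedgraph_path, chrom)
    if strand == "unstranded":
        return CoverageTrack(library_id, timepoint, False, plus,
                             library_size=library_size)
    if strand == "-" and minus_path is None:
        return CoverageTrack(library_id, timepoint, True,
                             np.zeros_like(plus), minus=plus,
                             library_size=library_size)
    if minus_path is None:
        raise ValidationError("stranded track requires minus_path")
    minus = read_bedgraph(minus_path, chrom)
    return CoverageTrack(library_id, timepoint, True, plus, minus=minus,
                         library_size=library_size)


def write_track(values, mode: str, path: str, *, chrom_name: str = "chr",
                bin_size: int = 1, genes: Sequence[GeneAnnotation] | None = None,
                header: str = "gene_id\tvalue") -> None:
    """Emit a browser-loadable bedGraph or a plain TSV.

    ``values`` is a per-bin numpy vector (bedGraph/TSV) or a gene-keyed
    mapping/Series (TSV, or bedGraph when ``genes`` supplies the intervals).
    Adjacent equal-valued bedGraph bins are merged; NaN/missing values are
    omitted from bedGraph and written as NA in TSV.
    """
    if mode == "bedgraph":
        with open(path, "w") as fh:
            if isinstance(values, (dict, pd.Series)):
                if genes is None:
                    raise ValidationError("gene-keyed bedGraph needs gene intervals")
                vals = pd.Series(values)
                recs = []
                for g in sorted(genes, key=lambda g: g.start):
                    if g.gene_id not in vals.index or not np.isfinite(vals[g.gene_id]):
                        continue
                    recs.append((g.start, g.end, float(vals[g.gene_id])))
                for s, e, v in recs:
                    fh.write(f"{chrom_name}\t{s}\t{e}\t{FLOAT_FMT % v}\n")
            else:
                arr = np.asarray(values, dtype=float)
                i = 0
                while i < len(arr):
                    v = arr[i]
                    j = i + 1
                    while j < len(arr) and (arr[j] == v or
                                            (np.isnan(arr[j]) and np.isnan(v))):
                        j += 1
                    if np.isfinite(v):
                        fh.write(f"{chrom_name}\t{i * bin_size}\t{j * bin_size}\t"
                                 f"{FLOAT_FMT % v}\n")
                    i = j
    elif mode == "tsv":
        with open(path, "w") as fh:
            fh.write(header + "\n")
            items = (values.items() if isinstance(values, (dict, pd.Series))
                     else enumerate(np.asarray(values, dtype=float)))
            for k, v in items:
                out = "NA" if (v is None or not np.isfinite(v)) else FLOAT_FMT % v
                fh.write(f"{k}\t{out}\n")
    else:
        raise ValidationError(f"unknown track mode {mode!r}")


# --------------------------------------------------------------------------- #
# counting
# --------------------------------------------------------------------------- #

def count_reads_in_genes(track: CoverageTrack, genes: Sequence[GeneAnnotation],
                         sense_only: bool = True, read_length: int = 50) -> pd.Series:
    """Per-gene read counts from a per-base coverage track.

    Count = (summed per-base coverage over the gene interval) / read_length,
    rounded to the nearest integer.  With ``sense_only`` the gene's own strand
    is used (stranded input required); otherwise both strands are pooled.
    Bases inside overlapping genes count for every overlapping gene.
    """
    if sense_only and not track.stranded:
        raise ValidationError("sense_only counting needs a stranded track")
    if track.bin_size != 1:
        raise ValidationError("counting requires per-base coverage")
    out = {}
    for g in genes:
        if sense_only:
            vec = track.strand_vector(g.strand)
            total = interval_sum(vec, g.start, g.end)
        else:
            total = interval_sum(track.total, g.start, g.end)
        out[g.gene_id] = int(round(total / read_length))
    return pd.Series(out, name=track.library_id)


# --------------------------------------------------------------------------- #
# count tables
# --------------------------------------------------------------------------- #

def write_count_table(path: str, table: CountTable) -> None:
    """TSV with three metadata header rows (timepoint, kind, library_size)."""
    with open(path, "w") as fh:
        ids = [lib.library_id for lib in table.libraries]
        fh.write("gene_id\t" + "\t".join(ids) + "\n")
        fh.write("#timepoint\t" + "\t".join(FLOAT_FMT % lib.timepoint
                                            for lib in table.libraries) + "\n")
        fh.write("#kind\t" + "\t".join(lib.kind for lib in table.libraries) + "\n")
        fh.write("#library_size\t" + "\t".join(FLOAT_FMT % lib.library_size
                                               for lib in table.libraries) + "\n")
        for gid, row in table.counts.iterrows():
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_count_table(path: str) -> CountTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = header[1:]
        meta = {}
        pos = fh.tell()
        for _ in range(3):
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, *vals = line.rstrip("\n").split("\t")
            meta[key.lstrip("#")] = vals
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    df.columns = ids
    df.index.name = "gene_id"
    tps = [float(x) for x in meta.get("timepoint", [0.0] * len(ids))]
    kinds = meta.get("kind", ["long"] * len(ids))
    sizes = [float(x) for x in meta.get("library_size", [0.0] * len(ids))]
    libs = [LibraryInfo(i, t, k, s) for i, t, k, s in zip(ids, tps, kinds, sizes)]
    return CountTable(df.astype(int), libs)
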