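"""End-to-end orchestration: load inputs once, run the four analysis stages,
write a manifest and a summary of headline statistics.

Outputs are deterministic for a fixed config + inputs (no timestamps in any
file); every emitted file is listed in the manifest with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from . import (bottleneck, degradome, genome_io, programs, topography)
from .genome_io import FLOAT_FMT
from .model import ValidationError

log = logging.getLogger("switchtome")


@dataclass
class PipelineConfig:
    annotation: str
    regions: str
    flags: str
    long_counts: str
    outdir: str
    frag_counts: str | None = None
    coverage_dir: str | None = None
    switch_timepoint: float = 51.0
    pre_timepoint: float | None = None     # default: last pre-switch timepoint
    bin_size: int = 10_000
    border_window: int = 5_000
    n_perm: int = 10_000
    seed: int = 0
    fc_threshold: float = 2.0
    min_cov: float = 1.0
    epsilon: float = 0.2
    top_fraction: float = 0.01
    suppression_category: str = "translation"
    stability_classes: tuple = ("ribosomal structure and biogenesis",
                                "transcription regulation")
    ncrna_min_len: int = 50
    ncrna_max_len: int = 1000
    ncrna_min_expr: float = 1.0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "stability_classes" in raw:
            raw["stability_classes"] = tuple(raw["stability_classes"])
        cfg = cls(**raw)
        for p in (cfg.annotation, cfg.regions, cfg.flags, cfg.long_counts):
            if not os.path.exists(p):
                raise ValidationError(f"input path does not exist: {p}")
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(cfg: PipelineConfig) -> dict:
    chrom, genes, partition = genome_io.read_annotation(
        cfg.annotation, cfg.regions, cfg.flags)
    long_counts = genome_io.read_count_table(cfg.long_counts)
    frag_counts = genome_io.read_count_table(cfg.frag_counts) \
        if cfg.frag_counts and os.path.exists(cfg.frag_counts) else None
    tracks = frag_tracks = None
    if cfg.coverage_dir:
        tracks, frag_tracks = {}, {}
        for lib in long_counts.libraries:
            base = os.path.join(cfg.coverage_dir, f"{lib.library_id}")
            if os.path.exists(base + "_plus.bedgraph"):
                tracks[lib.timepoint] = genome_io.read_coverage(
                    base + "_plus.bedgraph", chrom, "+",
                    minus_path=base + "_minus.bedgraph",
                    library_id=lib.library_id, timepoint=lib.timepoint,
                    library_size=lib.library_size)
        if frag_counts is not None:
            for lib in frag_counts.libraries:
                base = os.path.join(cfg.coverage_dir, f"{lib.library_id}")
                if os.path.exists(base + "_plus.bedgraph"):
                    frag_tracks[lib.timepoint] = genome_io.read_coverage(
                        base + "_plus.bedgraph", chrom, "+",
                        minus_path=base + "_minus.bedgraph",
                        library_id=lib.library_id, timepoint=lib.timepoint,
                        library_size=lib.library_size)
        if not tracks:
            tracks = None
    timepoints = sorted({lib.timepoint for lib in long_counts.libraries})
    pre_tp = cfg.pre_timepoint
    if pre_tp is None:
        before = [t for t in timepoints if t < cfg.switch_timepoint]
        if not before:
            raise ValidationError("no timepoint precedes the switch")
        pre_tp = before[-1]
    return {"chrom": chrom, "genes": genes, "partition": partition,
            "long_counts": long_counts, "frag_counts": frag_counts,
            "tracks": tracks, "frag_tracks": frag_tracks,
            "timepoints": timepoints, "pre_tp": pre_tp}


# --------------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------------- #

def stage_topography(data: dict, cfg: PipelineConfig, outdir: str) -> dict:
    if data["tracks"] is None:
        log.warning("topography: no coverage tracks; stage skipped")
        return {}
    tracks = data["tracks"]
    chrom, partition, genes = data["chrom"], data["partition"], data["genes"]
    tf = topography.transcribed_fraction(tracks.values(), cfg.min_cov)
    for t, tr in sorted(tracks.items()):
        sp = topography.strand_preference(tr, chrom, cfg.bin_size)
        genome_io.write_track(sp.values, "bedgraph",
                              os.path.join(outdir, f"strand_pref_t{t:g}.bedgraph"),
                              chrom_name=chrom.name, bin_size=cfg.bin_size)
    rrna = [g for g in genes if g.has_flag("rRNA")]
    enr = topography.region_enrichment(tracks, partition, cfg.bin_size,
                                       switch_timepoint=cfg.switch_timepoint,
                                       epsilon=cfg.epsilon, mask_genes=rrna)
    enr.table.to_csv(os.path.join(outdir, "region_enrichment.tsv"), sep="\t",
                     index=False, float_format=FLOAT_FMT)
    anti = topography.antisense_fraction(tracks.values(), genes)
    cands = topography.intergenic_candidates(
        tracks.values(), genes, chrom,
        fragment_tracks=(data["frag_tracks"] or {}).values() or None,
        min_len=cfg.ncrna_min_len, max_len=cfg.ncrna_max_len,
        min_expr=cfg.ncrna_min_expr)
    with open(os.path.join(outdir, "ncrna_candidates.bed"), "w") as fh:
        for i, row in cands.iterrows():
            fh.write(f"{chrom.name}\t{row['start']}\t{row['end']}\t"
                     f"cand_{i + 1:04d}\t{FLOAT_FMT % row['mean_expression']}\t"
                     f"{row['strand']}\n")
    return {"transcribed": tf, "enrichment": enr, "antisense": anti,
            "candidates": cands}


def stage_programs(data: dict, cfg: PipelineConfig, outdir: str) -> dict:
    expr = programs.normalize_expression(data["long_counts"], data["genes"])
    expr.values.to_csv(os.path.join(outdir, "expression_normalized.tsv"),
                       sep="\t", float_format=FLOAT_FMT)
    fc = programs.switch_fold_changes(expr, data["pre_tp"],
                                      cfg.switch_timepoint, cfg.fc_threshold)
    genome_io.write_track(fc["log2fc"], "tsv",
                          os.path.join(outdir, "switch_log2fc.tsv"),
                          header="gene_id\tlog2fc")
    pmap = programs.default_phase_map(data["timepoints"], cfg.switch_timepoint)
    phases = programs.cluster_phases(expr, pmap, gene_ids=fc["prominent"])
    phases.assignments.to_csv(os.path.join(outdir, "phases.tsv"), sep="\t")
    cat_map = {g.gene_id: g.category for g in data["genes"]}
    universe = list(phases.assignments.index)
    enrich_rows = []
    for phase in ("exponential", "transitional", "stationary"):
        in_phase = [g for g in universe
                    if phases.assignments.loc[g, "phase"] == phase]
        if not in_phase:
            continue
        res = programs.category_enrichment(in_phase, universe, cat_map)
        df = programs.enrichment_frame(res)
        df.insert(0, "phase", phase)
        enrich_rows.append(df)
    if enrich_rows:
        pd.concat(enrich_rows).to_csv(
            os.path.join(outdir, "category_enrichment.tsv"), sep="\t",
            index=False, float_format=FLOAT_FMT)

    # border induction needs the normalized matrix, so it lives here
    border = None
    try:
        border = topography.border_induction(
            expr, data["genes"], data["partition"],
            (data["pre_tp"], cfg.switch_timepoint), window=cfg.border_window,
            n_perm=cfg.n_perm, seed=cfg.seed)
    except ValidationError as err:
        log.warning("border induction skipped: %s", err)
    return {"expr": expr, "fold_changes": fc, "phases": phases, "border": border}


def stage_bottleneck(data: dict, cfg: PipelineConfig, outdir: str,
                     expr) -> dict:
    conc = {t: bottleneck.expression_concentration(expr, t, cfg.top_fraction)
            for t in data["timepoints"]}
    with open(os.path.join(outdir, "concentration.tsv"), "w") as fh:
        fh.write("timepoint\ttop_fraction\tshare\tgini\n")
        for t, c in sorted(conc.items()):
            fh.write(f"{t:g}\t{c.q:g}\t{FLOAT_FMT % c.share}\t"
                     f"{FLOAT_FMT % c.gini}\n")
    cat_genes = [g.gene_id for g in data["genes"]
                 if g.category == cfg.suppression_category
                 and not g.has_flag("rRNA")]
    pres = [t for t in data["timepoints"] if t < cfg.switch_timepoint]
    supp = bottleneck.category_suppression(expr, data["long_counts"],
                                           cat_genes, pres,
                                           cfg.switch_timepoint)
    rnases = [g.gene_id for g in data["genes"] if g.has_flag("ribonuclease")]
    induction = None
    if len(rnases) >= 2:
        induction = bottleneck.induction_test(expr, rnases, data["pre_tp"],
                                              cfg.switch_timepoint,
                                              label="ribonuclease")
    return {"concentration": conc, "suppression": supp, "induction": induction}


def stage_degradome(data: dict, cfg: PipelineConfig, outdir: str) -> dict:
    if data["frag_counts"] is None:
        log.warning("degradome: no fragment counts; stage skipped")
        return {}
    table = degradome.degradation_index(data["long_counts"], data["frag_counts"])
    table.table.to_csv(os.path.join(outdir, "degradation_index.tsv"), sep="\t",
                       index=False, float_format=FLOAT_FMT)
    tps = table.timepoints()
    class_map = {}
    for cls in cfg.stability_classes:
        class_map[cls] = [g.gene_id for g in data["genes"] if g.category == cls]
    switch_like = [t for t in tps if t >= cfg.switch_timepoint]
    stab = []
    if switch_like:
        stab = degradome.stability_class_enrichment(table, class_map,
                                                    switch_like[0])
        pd.DataFrame([{"class": r.label, "n": r.n, "fold": r.fold,
                       "p": r.p, "q": r.q} for r in stab]).to_csv(
            os.path.join(outdir, "stability_enrichment.tsv"), sep="\t",
            index=False, float_format=FLOAT_FMT)
    for t in tps:
        degradome.degradation_track(
            table, data["genes"], t,
            os.path.join(outdir, f"relative_DI_t{t:g}.bedgraph"),
            chrom_name=data["chrom"].name)
    shift = None
    pre_like = [t for t in tps if t < cfg.switch_timepoint]
    if pre_like and switch_like:
        shift = degradome.global_degradation_shift(table, pre_like[-1],
                                                   switch_like[0])
    return {"table": table, "stability": stab, "shift": shift}


# --------------------------------------------------------------------------- #
# run-all
# --------------------------------------------------------------------------- #

def run_all(cfg: PipelineConfig) -> dict:
    os.makedirs(cfg.outdir, exist_ok=True)
    data = load_inputs(cfg)
    topo = stage_topography(data, cfg, cfg.outdir)
    prog = stage_programs(data, cfg, cfg.outdir)
    bott = stage_bottleneck(data, cfg, cfg.outdir, prog["expr"])
    degr = stage_degradome(data, cfg, cfg.outdir)

    summary = {}
    if topo:
        summary["transcribed_either_strand"] = topo["transcribed"]["either_strand"]
        summary["transcribed_unstranded"] = topo["transcribed"]["unstranded"]
        summary["singleton_fraction"] = topo["transcribed"]["singleton_fraction"]
        summary["antisense_fraction"] = topo["antisense"]["overall"]
        summary["n_ncrna_candidates"] = len(topo["candidates"])
        summary["switch_detected"] = int(topo["enrichment"].switch_detected)
        summary["switch_sign"] = topo["enrichment"].switch_sign
    summary["changed_fraction"] = prog["fold_changes"]["changed_fraction"]
    if prog["border"]:
        summary["border_induction_fold"] = prog["border"]["fold"]
        summary["border_induction_p_perm"] = prog["border"]["p_perm"]
    c0 = bott["concentration"][data["pre_tp"]]
    summary["top1pct_share"] = c0.share
    summary["gini"] = c0.gini
    summary["suppression_fold_raw"] = bott["suppression"]["max_fold_raw"]
    summary["suppression_fold_norm"] = bott["suppression"]["max_fold_norm"]
    if bott["induction"]:
        summary["rnase_n_induced"] = bott["induction"].n_induced
        summary["rnase_n"] = bott["induction"].n
        summary["rnase_p"] = bott["induction"].p
    if degr and degr.get("shift"):
        summary["delta_median_DI"] = degr["shift"]["delta_median_DI"]
    for r in (degr.get("stability") or []):
        key = "stability_fold_" + r.label.replace(" ", "_")
        summary[key] = r.fold

    with open(os.path.join(cfg.outdir, "summary.tsv"), "w") as fh:
        fh.write("statistic\tvalue\n")
        for k in sorted(summary):
            v = summary[k]
            fh.write(f"{k}\t{v if isinstance(v, int) else FLOAT_FMT % v}\n")

    manifest = {
        "inputs": {name: _sha256(path) for name, path in
                   (("annotation", cfg.annotation), ("regions", cfg.regions),
                    ("flags", cfg.flags), ("long_counts", cfg.long_counts))
                   if path and os.path.exists(path)},
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "outputs": {},
    }
    for name in sorted(os.listdir(cfg.outdir)):
        if name == "manifest.json":
            continue
        manifest["outputs"][name] = _sha256(os.path.join(cfg.outdir, name))
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return {"summary": summary, "topography": topo, "programs": prog,
            "bottleneck": bott, "degradome": degr}
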