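"""Expression normalization and the phase-program analysis.

RPKM with between-library upper-quartile scaling, prominence filtering
(top half by maximal expression), switch fold-changes, Pearson
complete-linkage phase clustering, and Fisher-exact functional-category
enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .model import CountTable, GeneAnnotation, ValidationError

PSEUDOCOUNT_RPKM = 0.5


@dataclass
class ExpressionMatrix:
    """Genes x libraries normalized expression (upper-quartile scaled RPKM).

    rRNA-flagged genes are excluded; raw counts and per-library size factors
    are retained.
    """
    values: pd.DataFrame           # normalized expression
    raw: pd.DataFrame              # raw counts (same shape)
    libraries: list                # LibraryInfo per column
    size_factors: pd.Series        # per-library upper-quartile factor
    gene_lengths: pd.Series        # bp

    def timepoints(self) -> list:
        return sorted({lib.timepoint for lib in self.libraries})

    def at_timepoint(self, timepoint: float, kind: str = "long") -> pd.Series:
        cols = [lib.library_id for lib in self.libraries
                if lib.timepoint == timepoint and lib.kind == kind]
        if not cols:
            raise KeyError(f"no {kind} library at timepoint {timepoint}")
        return self.values[cols].mean(axis=1)

    def matrix_by_timepoint(self, kind: str = "long") -> pd.DataFrame:
        return pd.DataFrame({t: self.at_timepoint(t, kind)
                             for t in self.timepoints()})


@dataclass
class PhaseAssignment:
    assignments: pd.DataFrame      # index gene_id: cluster, phase, peak_timepoint
    centroids: pd.DataFrame        # cluster x timepoint (standardized units)
    excluded: list                 # zero-variance genes left out

    def phase_of(self, gene_id: str) -> str:
        return str(self.assignments.loc[gene_id, "phase"])


@dataclass
class EnrichmentResult:
    category: str
    a: int; b: int; c: int; d: int      # in-set&in-cat, in-set&out, out&in-cat, out&out
    odds_ratio: float
    fold_enrichment: float
    p: float
    q: float = float("nan")


# --------------------------------------------------------------------------- #
# normalization
# --------------------------------------------------------------------------- #

def normalize_expression(counts: CountTable,
                         genes: Sequence[GeneAnnotation]) -> ExpressionMatrix:
    """RPKM + between-library upper-quartile scaling.

    value = count / (gene_length_kb * library_size_millions), then each
    library is divided by (its upper quartile of nonzero values / the
    geometric mean of those quartiles across libraries).  rRNA-flagged genes
    are dropped before the quartiles are computed.
    """
    by_id = {g.gene_id: g for g in genes}
    keep = [gid for gid in counts.genes
            if gid in by_id and not by_id[gid].has_flag("rRNA")]
    if not keep:
        raise ValidationError("no genes left after rRNA masking")
    raw = counts.counts.loc[keep].astype(float)
    lengths = pd.Series({gid: by_id[gid].length for gid in keep}, name="length")

    rpkm = pd.DataFrame(index=raw.index)
    for lib in counts.libraries:
        col = raw[lib.library_id]
        if col.sum() == 0:
            raise ValidationError(f"library {lib.library_id} has all-zero counts")
        size = lib.library_size if lib.library_size > 0 else col.sum()
        rpkm[lib.library_id] = col / (lengths / 1000.0) / (size / 1e6)

    uq = {}
    for lib in counts.libraries:
        nz = rpkm[lib.library_id][rpkm[lib.library_id] > 0]
        if nz.empty:
            raise ValidationError(f"library {lib.library_id} has no nonzero values")
        uq[lib.library_id] = float(np.percentile(nz, 75))
    uq = pd.Series(uq)
    geo = float(np.exp(np.log(uq).mean()))
    factors = uq / geo
    values = rpkm / factors

    return ExpressionMatrix(values, raw, list(counts.libraries), factors, lengths)


# --------------------------------------------------------------------------- #
# prominence and fold changes
# --------------------------------------------------------------------------- #

def prominent_genes(expr: ExpressionMatrix) -> list:
    """Top half of genes (ceil at odd counts) ranked by maximal normalized
    expression across timepoints; boundary ties broken by gene_id order."""
    if expr.values.empty:
        raise ValidationError("empty expression matrix")
    long_cols = [lib.library_id for lib in expr.libraries if lib.kind == "long"]
    maxima = expr.values[long_cols].max(axis=1)
    order = sorted(maxima.index, key=lambda g: (-maxima[g], g))
    return order[:ceil(len(order) / 2)]


def switch_fold_changes(expr: ExpressionMatrix, pre_tp: float, post_tp: float,
                        fc_threshold: float = 2.0,
                        pseudocount: float = PSEUDOCOUNT_RPKM) -> dict:
    """Per-gene log2 fold-change across the switch and the fraction of
    prominent genes changing more than ``fc_threshold``-fold."""
    if pre_tp == post_tp:
        raise ValidationError("pre and post timepoints coincide")
    pre = expr.at_timepoint(pre_tp)
    post = expr.at_timepoint(post_tp)
    log2fc = np.log2((post + pseudocount) / (pre + pseudocount))
    prominent = prominent_genes(expr)
    changed = (log2fc[prominent].abs() > np.log2(fc_threshold)).mean()
    return {"log2fc": log2fc, "changed_fraction": float(changed),
            "prominent": prominent}


# --------------------------------------------------------------------------- #
# phase clustering
# --------------------------------------------------------------------------- #

def default_phase_map(timepoints: Sequence[float], switch_timepoint: float) -> dict:
    """Pre-switch -> exponential, switch -> transitional, post -> stationary."""
    out = {}
    for t in timepoints:
        if t < switch_timepoint:
            out[t] = "exponential"
        elif t == switch_timepoint:
            out[t] = "transitional"
        else:
            out[t] = "stationary"
    return out


def cluster_phases(expr: ExpressionMatrix, phase_map: Mapping[float, str],
                   *, gene_ids: Sequence[str] | None = None,
                   n_clusters: int = 3) -> PhaseAssignment:
    """Agglomerative complete-linkage clustering under Pearson distance.

    Profiles (one value per timepoint) are mean-centered; distance is
    1 - Pearson correlation.  The tree is cut into ``n_clusters`` groups and
    each cluster's phase is the phase of its centroid's argmax timepoint under
    ``phase_map``.  The centroid is the per-timepoint MEDIAN of the members'
    standardized profiles: a cluster built around a coherent program always
    recruits some noise profiles that happen to correlate with it, and those
    share a spurious peak at the step timepoint which would bias a mean
    centroid.  Zero-variance profiles are excluded with a warning list.
    """
    mat = expr.matrix_by_timepoint()
    if gene_ids is not None:
        mat = mat.loc[list(gene_ids)]
    if len(mat) < 2:
        raise ValidationError("need at least two genes to cluster")
    tps = list(mat.columns)
    X = mat.to_numpy(dtype=float)
    sd = X.std(axis=1)
    excluded = list(mat.index[sd == 0])
    keep = sd > 0
    X = X[keep]
    idx = mat.index[keep]
    Xc = X - X.mean(axis=1, keepdims=True)
    Z = linkage(Xc, method="complete", metric="correlation")
    k = min(n_clusters, len(idx))
    labels = fcluster(Z, t=k, criterion="maxclust")

    Xs = Xc / Xc.std(axis=1, keepdims=True)
    rows, cents = [], {}
    for cl in np.unique(labels):
        member = labels == cl
        centroid = np.median(Xs[member], axis=0)
        cents[cl] = centroid
        peak = tps[int(np.argmax(centroid))]
        phase = phase_map[peak]
        for gid in idx[member]:
            rows.append({"gene_id": gid, "cluster": int(cl), "phase": phase,
                         "peak_timepoint": peak})
    assignments = pd.DataFrame(rows).set_index("gene_id").loc[idx]
    centroids = pd.DataFrame(cents, index=tps).T
    return PhaseAssignment(assignments, centroids, excluded)


# --------------------------------------------------------------------------- #
# category enrichment
# --------------------------------------------------------------------------- #

def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table
    [[a, b], [c, d]]: upper hypergeometric tail P(X >= a)."""
    M, n, N = a + b + c + d, a + c, a + b
    return float(stats.hypergeom.sf(a - 1, M, n, N))


def category_enrichment(gene_set: Sequence[str], universe: Sequence[str],
                        category_map: Mapping[str, str],
                        alternative: str = "greater") -> list:
    """Fisher-exact enrichment of each functional category in ``gene_set``
    against ``universe``, BH-adjusted across the tested categories."""
    if alternative != "greater":
        raise ValidationError("only the enrichment ('greater') alternative is supported")
    uni = list(dict.fromkeys(universe))
    sset = set(gene_set)
    if not sset <= set(uni):
        raise ValidationError("gene_set must be a subset of the universe")
    cats = sorted({category_map[g] for g in uni if g in category_map})
    results = []
    for cat in cats:
        in_cat = {g for g in uni if category_map.get(g) == cat}
        if not in_cat:
            continue
        a = len(sset & in_cat)
        b = len(sset - in_cat)
        c = len(in_cat - sset)
        d = len(uni) - a - b - c
        p = fisher_one_sided(a, b, c, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        set_rate = a / (a + b) if (a + b) else 0.0
        uni_rate = (a + c) / len(uni)
        fold = set_rate / uni_rate if uni_rate else float("nan")
        results.append(EnrichmentResult(cat, a, b, c, d, float(odds), float(fold), p))
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "category": r.category, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "fold_enrichment": r.fold_enrichment,
        "p": r.p, "q": r.q} for r in results])
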