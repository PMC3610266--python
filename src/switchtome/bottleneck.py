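"""The transcriptional bottleneck: mRNA concentration, category suppression
across the switch, and ribonuclease/protease induction at the switch."""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CountTable, ValidationError
from .programs import ExpressionMatrix


@dataclass
class ConcentrationStat:
    timepoint: float
    q: float                    # top fraction of genes
    share: float                # their fraction of total normalized mRNA
    gini: float


@dataclass
class InductionTestResult:
    label: str
    n: int
    log2_folds: pd.Series       # per-gene log2 fold (switch vs pre)
    median_fold: float
    t: float
    p: float                    # two-sided by default
    n_induced: int              # genes with fold > 1
    degenerate: bool = False    # zero-variance paired differences


def gini_coefficient(values: np.ndarray) -> float:
    """Gini of a non-negative expression vector, from the Lorenz curve."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    total = v.sum()
    if total == 0 or n == 0:
        return 0.0
    cum = np.cumsum(v)
    # mean absolute difference formulation
    return float((2 * np.sum((np.arange(1, n + 1)) * v) / (n * total)) - (n + 1) / n)


def expression_concentration(expr: ExpressionMatrix, timepoint: float,
                             q: float = 0.01) -> ConcentrationStat:
    """Share of total normalized mRNA contributed by the top ``q`` fraction of
    genes, plus the Gini concentration coefficient."""
    if not 0 < q <= 1:
        raise ValidationError("q must be in (0, 1]")
    vals = expr.at_timepoint(timepoint).to_numpy()
    if vals.sum() == 0:
        raise ValidationError(f"all-zero expression at timepoint {timepoint}")
    srt = np.sort(vals)[::-1]
    k = ceil(q * len(srt))
    share = float(srt[:k].sum() / srt.sum())
    return ConcentrationStat(timepoint, q, share, gini_coefficient(vals))


def category_suppression(expr: ExpressionMatrix, counts: CountTable,
                         category_genes: Sequence[str], tp_pre,
                         tp_at: float) -> dict:
    """Fold suppression of a gene category's summed signal at ``tp_at``.

    fold = (summed signal at the pre timepoint) / (same at tp_at); values > 1
    mean suppression at tp_at.  ``tp_pre`` may be a single timepoint or a list,
    in which case the per-pre-timepoint maximum is also reported ("up to").
    Both raw-count and normalized-expression folds are emitted: raw counts
    carry absolute pool changes when library depths track the mRNA pool,
    normalized expression is relative composition only.
    """
    cat = [g for g in category_genes if g in expr.values.index]
    if not cat:
        raise ValidationError("category has no genes in the matrix")
    pres = tp_pre if isinstance(tp_pre, (list, tuple)) else [tp_pre]

    def fold_pair(get):
        at = get(tp_at)
        out = {}
        for tp in pres:
            pre = get(tp)
            out[tp] = float("inf") if at == 0 else pre / at
        return out

    def raw_sum(t):
        col = counts.column_for_timepoint(t, "long")
        return float(counts.counts.loc[cat, col].sum())

    def norm_sum(t):
        return float(expr.at_timepoint(t)[cat].sum())

    raw_folds = fold_pair(raw_sum)
    norm_folds = fold_pair(norm_sum)
    first = pres[0]
    return {
        "fold_raw": raw_folds[first], "fold_norm": norm_folds[first],
        "max_fold_raw": max(raw_folds.values()),
        "max_fold_norm": max(norm_folds.values()),
        "per_pre_raw": raw_folds, "per_pre_norm": norm_folds,
        "zero_denominator": any(np.isinf(v) for v in raw_folds.values()),
    }


def induction_test(expr: ExpressionMatrix, flagged: Sequence[str],
                   tp_pre: float, tp_switch: float, *, label: str = "flagged",
                   one_sided: bool = False, center: bool = True,
                   pseudocount: float = 0.5) -> InductionTestResult:
    """Paired t-test on log2(normalized expression + pseudocount) between two
    timepoints over a flagged gene set (e.g. ribonucleases).

    With ``center`` (default) the paired differences are measured relative to
    the genome-wide median log2 shift between the two timepoints, so the test
    asks whether the flagged set moves relative to the rest of the
    transcriptome; this removes shared between-library normalization noise
    and keeps the statistic calibrated.  Two-sided by default; ``one_sided``
    tests for induction at ``tp_switch``.  Zero-variance paired differences
    are reported as degenerate rather than p = 0.
    """
    present = [g for g in flagged if g in expr.values.index]
    if len(present) < 2:
        raise ValidationError("need at least two flagged genes with expression")
    pre_all = np.log2(expr.at_timepoint(tp_pre) + pseudocount)
    post_all = np.log2(expr.at_timepoint(tp_switch) + pseudocount)
    pre, post = pre_all[present], post_all[present]
    raw = post - pre
    n_induced = int((raw > 0).sum())
    median_fold = float(2 ** raw.median())
    diffs = raw
    if center:
        shift = float((post_all - pre_all).median())
        diffs = raw - shift
        pre = pre + shift / 2
        post = post - shift / 2
    if np.allclose(diffs.std(ddof=1), 0.0):
        return InductionTestResult(label, len(present), diffs, median_fold,
                                   float("inf") if diffs.mean() > 0 else
                                   (-float("inf") if diffs.mean() < 0 else 0.0),
                                   0.0 if diffs.mean() != 0 else 1.0,
                                   n_induced, degenerate=True)
    res = stats.ttest_rel(post, pre)
    p = float(res.pvalue)
    if one_sided:
        p = p / 2 if res.statistic > 0 else 1 - p / 2
    return InductionTestResult(label, len(present), diffs, median_fold,
                               float(res.statistic), p, n_induced)
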