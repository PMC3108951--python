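"""Site-level and gene-level evaluation machinery.

Site level: ROC/AUC over energy cutoffs separating true from control
sites, Wilcoxon rank-sum significance, and paired empirical CDFs.
Gene level: enrichment of bona fide targets (observed log2FC at or below
a cutoff) within top-scoring gene sets of increasing size, against the
constant baseline of a canonical 6-mer seed-match search.  These
operations consume any labelled score tables, so they are agnostic to
where the labels came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class EnrichmentCurve:
    set_sizes: np.ndarray  # gene counts, strictly increasing
    enrichment: np.ndarray
    baseline: float | None
    bona_fide_cutoff: float


def roc_auc(
    values_pos: Sequence[float],
    values_neg: Sequence[float],
    lower_is_positive: bool = True,
) -> RocResult:
    """ROC over all distinct value cutoffs.

    AUC equals the Mann-Whitney U statistic normalized by n_pos * n_neg,
    ties counted one half.  ``lower_is_positive`` matches energy-style
    scores where more negative = more target-like.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both value lists must be non-empty")
    y = np.concatenate([np.ones_like(pos), np.zeros_like(neg)])
    scores = np.concatenate([pos, neg])
    if lower_is_positive:
        scores = -scores
    fpr, tpr, thr = _roc_curve(y, scores, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U), two-sided, normal approx with
    tie correction.  All-tied input degenerates to p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def _ranked_genes(scores: Mapping[str, float]) -> list[str]:
    # ascending score (most negative = strongest prediction); ties by gene id
    return sorted(scores, key=lambda g: (scores[g], g))


def enrichment_curve(
    scores: Mapping[str, float],
    observed: Mapping[str, float],
    cutoff: float,
    increment: int = 50,
) -> EnrichmentCurve:
    """Bona fide enrichment within top-N predicted sets, N in 50-gene steps.

    enrichment(N) = (bona fide in top N / N) / (bona fide overall /
    total).  The final point is the full gene set (enrichment exactly 1);
    a last partial bin is truncated to the gene count, never extrapolated.
    """
    if set(scores) != set(observed):
        raise ValueError("scores and observations must be keyed identically")
    ranked = _ranked_genes(scores)
    total = len(ranked)
    bona = {g for g, v in observed.items() if v <= cutoff}
    if not bona:
        raise ValueError("no bona fide genes at this cutoff")
    prevalence = len(bona) / total
    sizes = list(range(increment, total + 1, increment))
    if not sizes or sizes[-1] != total:
        sizes.append(total)
    is_bona = np.array([g in bona for g in ranked])
    cum = np.cumsum(is_bona)
    enr = np.array([cum[n - 1] / n / prevalence for n in sizes])
    return EnrichmentCurve(
        set_sizes=np.array(sizes),
        enrichment=enr,
        baseline=None,
        bona_fide_cutoff=cutoff,
    )


def seed_baseline_enrichment(
    has_6mer: Mapping[str, bool],
    observed: Mapping[str, float],
    cutoff: float,
) -> float:
    """Enrichment of bona fide genes among those with a canonical 6-mer
    (or better) site, vs the full set.

    On a gene set restricted to 6-mer carriers this is exactly 1 — the
    baseline a relaxed-seed model has to beat.
    """
    if set(has_6mer) != set(observed):
        raise ValueError("flags and observations must be keyed identically")
    flagged = {g for g, f in has_6mer.items() if f}
    if not flagged:
        raise ValueError("no genes carry a canonical 6-mer site")
    bona = {g for g, v in observed.items() if v <= cutoff}
    if not bona:
        raise ValueError("no bona fide genes at this cutoff")
    prevalence = len(bona) / len(observed)
    return (len(bona & flagged) / len(flagged)) / prevalence


def cdf_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> pd.DataFrame:
    """Empirical CDFs of both samples on the merged value grid.

    Returns a DataFrame with columns ``value``, ``cdf_a``, ``cdf_b``
    (step functions evaluated at every distinct value), exportable as TSV.
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return pd.DataFrame({"value": grid, "cdf_a": cdf_a, "cdf_b": cdf_b})
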