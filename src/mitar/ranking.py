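"""Decision-score ranking and rank-distribution / resampling analyses.

Interactions are ranked by descending SVM decision value (rank 1 is the
highest score, ties share the mean rank).  The analyses quantify whether
true positives concentrate near the top of a ranked list and whether one
scorer's resampled classification metrics beat another's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import metrics

#: per-group size above which the rank-sum test switches from exact
#: enumeration to the tie-corrected normal approximation
EXACT_LIMIT = 20


@dataclass(frozen=True)
class RankedItem:
    id: str
    score: float
    rank: float
    true_positive: Optional[bool] = None


def rank_interactions(
    scored: Sequence[tuple[str, float]],
    truth: Optional[Sequence[bool]] = None,
) -> list[RankedItem]:
    """Rank (id, decision value) items descending; ties get the mean rank.

    Input order never affects the assigned ranks.
    """
    if not scored:
        return []
    scores = np.array([s for _, s in scored], dtype=float)
    ranks = stats.rankdata(-scores)  # average method: tied items share mean rank
    out = []
    for i, (id_, score) in enumerate(scored):
        tp = None if truth is None else bool(truth[i])
        out.append(RankedItem(id_, float(score), float(ranks[i]), tp))
    return out


def top_percentile_fraction(ranked: Sequence[RankedItem], pct: float = 20) -> float:
    """Fraction of true positives ranked within the top ``pct`` percent.

    The boundary rank is ceil(pct/100 * list length), inclusive.
    """
    tps = [r for r in ranked if r.true_positive]
    if not tps:
        raise ValueError("no true positives in the ranked list")
    cutoff = math.ceil(pct / 100.0 * len(ranked))
    return sum(1 for r in tps if r.rank <= cutoff) / len(tps)


def within_half_ratio(ranked: Sequence[RankedItem]) -> float:
    """Fraction of true positives within the 50th percentile of the list."""
    return top_percentile_fraction(ranked, 50)


def _ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= EXACT_LIMIT and len(b) <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_rank_lists(
    ranks_a: Sequence[float],
    ranks_b: Sequence[float],
) -> float:
    """Rank-sum p-value comparing two sets of normalized TP rank positions."""
    if len(ranks_a) == 0 or len(ranks_b) == 0:
        raise ValueError("both rank lists must be non-empty")
    return _ranksum_pvalue(np.asarray(ranks_a), np.asarray(ranks_b))


def normalized_tp_ranks(ranked: Sequence[RankedItem]) -> np.ndarray:
    """Rank positions of true positives scaled to (0, 1] by list length."""
    n = len(ranked)
    return np.array([r.rank / n for r in ranked if r.true_positive])


def _metric_row(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    pred = np.where(scores > 0, 1, -1)
    c = metrics.confusion(labels, pred)
    sn, sp, m, _ = metrics.sn_sp_mcc_aca(c)
    prec = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else float("nan")
    return {"Sn": sn, "Sp": sp, "MCC": m, "Precision": prec}


def resampled_metric_comparison(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    sample_size: int = 100,
    repeats: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Per-metric rank-sum p-values between two scorers over resamples.

    Each repeat draws ``sample_size`` pairs without replacement (redrawn
    until both classes are present), computes Sn/Sp/MCC/Precision for each
    scorer's sign predictions, and the metrics are compared across repeats
    with the two-sided rank-sum test.  Repeats where a scorer makes no
    positive prediction contribute no Precision value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n < sample_size:
        raise ValueError(f"dataset of {n} smaller than sample_size={sample_size}")
    rng = np.random.default_rng(seed)
    rows_a: list[dict[str, float]] = []
    rows_b: list[dict[str, float]] = []
    for _ in range(repeats):
        while True:
            idx = rng.choice(n, size=sample_size, replace=False)
            if len(np.unique(labels[idx])) == 2:
                break
        rows_a.append(_metric_row(scores_a[idx], labels[idx]))
        rows_b.append(_metric_row(scores_b[idx], labels[idx]))
    pvals: dict[str, float] = {}
    for key in ("Sn", "Sp", "MCC", "Precision"):
        va = np.array([r[key] for r in rows_a])
        vb = np.array([r[key] for r in rows_b])
        va = va[~np.isnan(va)]
        vb = vb[~np.isnan(vb)]
        if len(va) == 0 or len(vb) == 0:
            pvals[key] = float("nan")
        elif np.array_equal(np.sort(va), np.sort(vb)) and np.all(va == va[0]):
            pvals[key] = 1.0  # both scorers constant and identical
        else:
            pvals[key] = _ranksum_pvalue(va, vb)
    return pvals
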