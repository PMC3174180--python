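"""Wrapper feature selection: AMOSA driven by SVM cross-validation objectives.

A solution is a 90-bit mask over the feature catalog; its objectives are
the pooled 5-fold-CV sensitivity, specificity and MCC of an RBF-SVM
trained on the masked columns.  The final mask is the archived solution
with the highest pooled-CV accuracy on the (balanced) training data.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional, Sequence

import numpy as np

from . import amosa, metrics
from .amosa import Archive, Schedule, Solution
from .classifier import SVMParams
from .featurize import FeatureCatalog, build_catalog

log = logging.getLogger(__name__)


def bits_to_mask(bits: Sequence[int]) -> tuple[int, ...]:
    """1-based catalog indices of the set bits."""
    return tuple(i + 1 for i, b in enumerate(bits) if b)


def mask_to_bits(mask: Iterable[int], length: int) -> tuple[int, ...]:
    mask = set(mask)
    return tuple(1 if (i + 1) in mask else 0 for i in range(length))


def evaluate_mask(
    bits: Sequence[int],
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams | None = None,
    seed: int = 0,
    k: int = 5,
) -> tuple[float, float, float]:
    """(Sn, Sp, MCC) of the masked feature set under pooled k-fold CV."""
    mask = bits_to_mask(bits)
    if not mask:
        raise ValueError("bitstring has no set bits")
    return metrics.cv_objectives(X, y, mask, params, k=k, seed=seed)


def make_evaluator(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams | None = None,
    seed: int = 0,
    k: int = 5,
):
    """Caching evaluator for AMOSA (bitstrings recur during annealing)."""
    cache: dict[tuple[int, ...], tuple[float, float, float]] = {}

    def evaluator(bits: tuple[int, ...]) -> tuple[float, float, float]:
        key = tuple(bits)
        if key not in cache:
            cache[key] = evaluate_mask(key, X, y, params, seed=seed, k=k)
        return cache[key]

    evaluator.cache = cache
    return evaluator


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    schedule: Schedule | None = None,
    params: SVMParams | None = None,
    cv_seed: int = 0,
    k: int = 5,
) -> tuple[tuple[int, ...], Archive]:
    """Run AMOSA-SVM feature selection; return (final mask, archive).

    The final mask maximizes pooled-CV accuracy over archive members; ties
    break to larger MCC, then fewer selected features, then the
    lexicographically smallest bitstring.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if int(np.sum(y == 1)) != int(np.sum(y == -1)):
        log.warning(
            "training data is not balanced (%d positive vs %d negative)",
            int(np.sum(y == 1)),
            int(np.sum(y == -1)),
        )
    schedule = schedule or Schedule()
    evaluator = make_evaluator(X, y, params, seed=cv_seed, k=k)
    archive = amosa.run(evaluator, X.shape[1], schedule)

    def pick_key(sol: Solution):
        c = metrics.cv_confusion(X, y, bits_to_mask(sol.bits), params, k=k, seed=cv_seed)
        return (-c.accuracy, -metrics.mcc(c), sol.n_set, sol.bits)

    best = min(archive.members, key=pick_key)
    return bits_to_mask(best.bits), archive


def common_features(archive: Archive, threshold: float = 0.90) -> frozenset[int]:
    """Catalog indices set in at least ceil(threshold * |archive|) members."""
    if len(archive) == 0:
        raise ValueError("empty archive")
    need = math.ceil(threshold * len(archive))
    counts = np.sum([m.bits for m in archive.members], axis=0)
    return frozenset(int(i) + 1 for i in np.flatnonzero(counts >= need))


def feature_selection_ratio(
    mask: Iterable[int],
    catalog: Optional[FeatureCatalog] = None,
) -> dict[int, float]:
    """Per-category FSR: 100 * |selected in category| / |category|, 2 dp."""
    catalog = catalog or build_catalog()
    mask = set(mask)
    if mask and (min(mask) < 1 or max(mask) > len(catalog)):
        raise ValueError("mask indices outside the catalog")
    fsr: dict[int, float] = {}
    for cat, size in sorted(catalog.category_sizes().items()):
        selected = len(mask & set(catalog.category_indices(cat)))
        fsr[cat] = round(100.0 * selected / size, 2)
    return fsr
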