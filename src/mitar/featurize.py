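"""The 90-feature targeting-site context catalog and feature extraction.

The catalog is a fixed, deterministic indexing (1..90) of seven feature
categories computed on a miRNA-UTR pair's *effective* seed site (the
strongest site on the UTR) and its 30-nt flanks:

1.  (12) site-category counts over the whole UTR, plus the supplementary-
    pairing and AU-rich-flank flags of each category's effective site;
2.  (4)  single-nucleotide counts in the site (A, U, G, C);
3.  (4)  single-nucleotide counts in the pooled flanks;
4.  (16) dinucleotide counts in the site (first letter A,U,G,C x second);
5.  (16) dinucleotide counts in the flanks (each flank scanned separately);
6.  (6)  seed base-pair counts over the required seed-match positions,
    pair order A:U, U:A, U:G, G:C, G:U, C:G (miRNA:target);
7.  (32) consecutive base-pair bigrams read 5'->3' along the miRNA seed,
    first/second pair each in order A:U, U:A, G:C, C:G, G:U, U:G with the
    four double-wobble combinations excluded (a site carries at most one
    wobble, so they cannot occur).

"Frequency" means a raw count within the region; the classifier's scaler
absorbs the (near-constant) region lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import LabeledPair, MiRNASeq, UTRSeq, resolve_pairs
from .seedscan import (
    PairType,
    SeedRegister,
    SeedSite,
    SiteCategory,
    effective_site,
    find_sites,
    flanks,
    pairs,
    site_context,
)

log = logging.getLogger(__name__)

CATALOG_VERSION = "1"

N_FEATURES = 90

NUC_ORDER = ("A", "U", "G", "C")
DINUC_ORDER = tuple(a + b for a in NUC_ORDER for b in NUC_ORDER)
#: category-6 base-pair order (miRNA:target)
PAIR_ORDER = ("AU", "UA", "UG", "GC", "GU", "CG")
#: category-7 block order for the first pair of a bigram
BIGRAM_PAIR_ORDER = ("AU", "UA", "GC", "CG", "GU", "UG")
_WOBBLE = {"GU", "UG"}
#: bigrams in catalog order; double-wobble combinations cannot occur
BIGRAM_ORDER = tuple(
    f"{p}-{q}"
    for p in BIGRAM_PAIR_ORDER
    for q in BIGRAM_PAIR_ORDER
    if not (p in _WOBBLE and q in _WOBBLE)
)

#: category order used by the category-1 block
CAT1_SITE_ORDER = (
    SiteCategory.SIX_MER,
    SiteCategory.SEVEN_MER_M8,
    SiteCategory.SEVEN_MER_A1,
    SiteCategory.EIGHT_MER,
)

#: the published 39-feature selection (catalog indices)
SELECTED_39 = frozenset(
    {6, 19, 22, 24, 25, 26, 28, 30, 32, 35, 36}
    | {38, 39, 40, 42, 44, 45, 47, 48}
    | {53, 54, 56, 57, 58}
    | {59, 62, 64, 65, 67, 68, 69, 70, 73, 74, 78, 79, 83, 84, 86}
)

#: the subset of SELECTED_39 shared by >=90% of archived solutions
COMMON_22 = frozenset(
    {6, 26, 28, 30, 35, 36}
    | {39, 40, 42, 44}
    | {53, 56, 57, 58}
    | {59, 62, 64, 68, 70, 78, 79, 84}
)


@dataclass(frozen=True)
class FeatureEntry:
    index: int  # 1-based catalog index
    name: str
    category: int  # 1..7


@dataclass(frozen=True)
class FeatureCatalog:
    entries: tuple[FeatureEntry, ...]
    selected_39: frozenset[int] = SELECTED_39
    common_22: frozenset[int] = COMMON_22

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, index: int) -> FeatureEntry:
        """Entry at 1-based catalog index."""
        return self.entries[index - 1]

    def category_indices(self, category: int) -> tuple[int, ...]:
        return tuple(e.index for e in self.entries if e.category == category)

    def category_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for e in self.entries:
            sizes[e.category] = sizes.get(e.category, 0) + 1
        return sizes


def build_catalog() -> FeatureCatalog:
    """The immutable 90-feature catalog (bit-identical across runs)."""
    entries: list[FeatureEntry] = []

    def add(name: str, category: int) -> None:
        entries.append(FeatureEntry(len(entries) + 1, name, category))

    # category 1: per-category site counts, then supplementary / AU flags
    # of the effective site of each category (order 6mer, 7mer-m8, 7mer-A1,
    # 8mer in every block)
    cat_names = ("six mer", "seven mer m8", "seven mer A1", "eight mer")
    for nm in cat_names:
        add(f"Number of {nm} sites in UTR", 1)
    for nm in cat_names:
        add(f"Number of additional Watson-Crick pairing associated with effective {nm}", 1)
    for nm in cat_names:
        add(f"AU rich flanking region associated with effective {nm}", 1)
    # category 2/3: single-nucleotide counts, site then pooled flanks
    for b in NUC_ORDER:
        add(f"{b}'s frequency in effective seed matching site", 2)
    for b in NUC_ORDER:
        add(f"{b}'s frequency in effective seed matching out site", 3)
    # category 4/5: dinucleotide counts, site then flanks
    for d in DINUC_ORDER:
        add(f"{d}'s frequency in effective seed matching site", 4)
    for d in DINUC_ORDER:
        add(f"{d}'s frequency in effective seed matching out site", 5)
    # category 6: seed base-pair counts
    for p in PAIR_ORDER:
        add(f"Frequency of {p} base pair", 6)
    # category 7: consecutive base-pair bigrams
    for bg in BIGRAM_ORDER:
        add(f"Frequency of {bg}", 7)

    assert len(entries) == N_FEATURES
    return FeatureCatalog(entries=tuple(entries))


@dataclass(frozen=True)
class FeatureVector:
    """One pair's 90 feature values (index i at ``values[i-1]``)."""

    values: np.ndarray
    effective: Optional[SeedSite]
    mirna_id: str = ""
    utr_id: str = ""

    def __getitem__(self, index: int) -> float:
        """Value at 1-based catalog index."""
        return float(self.values[index - 1])


def _required_positions(site: SeedSite) -> range:
    """miRNA seed positions whose pairing defines the site.

    2-7 for 6mer/7mer-A1, 2-8 for 7mer-m8/8mer; 3-8 for a 3-8-register
    core.  The A1 anchor (position 1) is an identity test, not a pair, and
    is excluded.
    """
    if site.seed_register is SeedRegister.POS_3_8:
        return range(3, 9)
    if site.category in (SiteCategory.SEVEN_MER_M8, SiteCategory.EIGHT_MER):
        return range(2, 9)
    return range(2, 8)


def _seed_pair_labels(mirna: MiRNASeq, utr: UTRSeq, site: SeedSite) -> list[str]:
    labels = []
    for k in _required_positions(site):
        u = utr.base(site.utr_pos_of_mirna(k))
        m = mirna.base(k)
        if pairs(m, u) is PairType.NONE:  # cannot happen for a valid site
            raise AssertionError(f"unpaired required position {k}")
        labels.append(m + u)
    return labels


def _count_into(values: np.ndarray, start_index: int, order: Sequence[str], items: Iterable[str]) -> None:
    pos = {key: start_index - 1 + i for i, key in enumerate(order)}
    for it in items:
        values[pos[it]] += 1


def _dinucs(s: str) -> list[str]:
    return [s[i : i + 2] for i in range(len(s) - 1)]


def extract(mirna: MiRNASeq, utr: UTRSeq) -> FeatureVector:
    """Compute the 90-feature vector for one miRNA-UTR pair.

    A pair without any seed site gets the all-zero vector.
    """
    values = np.zeros(N_FEATURES)
    sites = find_sites(mirna, utr)
    if not sites:
        return FeatureVector(values, None, mirna.id, utr.id)

    # category 1
    for i, cat in enumerate(CAT1_SITE_ORDER):
        cat_sites = [s for s in sites if s.category is cat]
        values[i] = len(cat_sites)
        if cat_sites:
            eff_c = effective_site(cat_sites)
            ctx = site_context(mirna, utr, eff_c)
            values[4 + i] = ctx.supplementary_pairing
            values[8 + i] = ctx.au_rich_flank

    eff = effective_site(sites)
    site_str = utr.subseq(eff.utr_start, eff.utr_end)
    up, down = flanks(utr, eff)

    _count_into(values, 13, NUC_ORDER, site_str)  # category 2
    _count_into(values, 17, NUC_ORDER, up + down)  # category 3
    _count_into(values, 21, DINUC_ORDER, _dinucs(site_str))  # category 4
    _count_into(values, 37, DINUC_ORDER, _dinucs(up) + _dinucs(down))  # category 5

    labels = _seed_pair_labels(mirna, utr, eff)
    _count_into(values, 53, PAIR_ORDER, labels)  # category 6
    bigrams = [f"{a}-{b}" for a, b in zip(labels, labels[1:])]
    _count_into(values, 59, BIGRAM_ORDER, bigrams)  # category 7

    return FeatureVector(values, eff, mirna.id, utr.id)


def subset(vec: FeatureVector | np.ndarray, mask: Iterable[int]) -> np.ndarray:
    """Values at the (1-based) mask indices, ascending."""
    idx = sorted(set(int(i) for i in mask))
    if not idx:
        raise ValueError("empty feature mask")
    if idx[0] < 1 or idx[-1] > N_FEATURES:
        raise ValueError(f"mask indices must be within 1..{N_FEATURES}")
    values = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec)
    return values[np.array(idx) - 1]


def featurize_dataset(
    pairs_list: Sequence[LabeledPair],
    mirnas: Sequence[MiRNASeq],
    utrs: Sequence[UTRSeq],
) -> tuple[np.ndarray, np.ndarray, list[LabeledPair]]:
    """Feature matrix (one row per resolvable pair, catalog column order),
    aligned label vector, and the pairs actually kept."""
    resolved = resolve_pairs(pairs_list, mirnas, utrs)
    X = np.zeros((len(resolved), N_FEATURES))
    y = np.zeros(len(resolved), dtype=int)
    kept = []
    for i, (p, m, u) in enumerate(resolved):
        X[i] = extract(m, u).values
        y[i] = p.label
        kept.append(p)
    return X, y, kept
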