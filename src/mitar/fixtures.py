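"""Synthetic miRNA/UTR data with planted seed sites and class signal.

The generator emulates the structure of a curated training set: a balanced
collection of positive pairs (UTRs carrying a strong planted seed site,
optionally with AU-rich flanks and 3'-supplementary pairing) and negative
pairs (mostly site-free, with a configurable fraction of weak 6mer sites
to mimic hard negatives).  Everything is deterministic under the config
seed, and written files parse back losslessly through :mod:`mitar.seqio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import (
    LabeledPair,
    MiRNASeq,
    UTRSeq,
    write_fasta,
    write_pairs,
)
from .seedscan import WC, SeedRegister, SiteCategory

NUCS = ("A", "U", "G", "C")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror a balanced 289+289 training collection: every positive
    carries a planted strong site (90% with AU-rich flanks, 70% with
    supplementary pairing) while 20% of negatives carry only a weak 6mer.
    """

    n_pos: int = 289
    n_neg: int = 289
    utr_len: int = 200
    mirna_len: int = 22
    n_mirnas: int = 50
    gc_content: float = 0.5
    p_site_pos: float = 1.0
    p_site_neg: float = 0.2
    p_au_flank_pos: float = 0.9
    p_supp_pos: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "p_site_pos", "p_site_neg", "p_au_flank_pos", "p_supp_pos"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be >= 0")


def _random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random RNA with the given GC content (A=U and G=C split equally)."""
    p = ((1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2)
    return "".join(rng.choice(NUCS, size=length, p=p))


def gen_mirna(seed: int | np.random.Generator, length: int = 22, name: str = "mir-syn") -> MiRNASeq:
    """A uniform-random mature miRNA; deterministic under the seed."""
    if length < 16:
        raise ValueError(f"miRNA length must be >= 16, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MiRNASeq(id=name, seq="".join(rng.choice(NUCS, size=length)))


def gen_utr(seed: int | np.random.Generator, length: int, gc: float = 0.5, name: str = "utr-syn") -> UTRSeq:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return UTRSeq(id=name, seq=_random_rna(rng, length, gc))


def _target_base(mirna: MiRNASeq, k: int) -> str:
    """WC complement of miRNA position k (the target base that pairs it)."""
    return WC[mirna.base(k)]


def _m8_guard(mirna: MiRNASeq) -> str:
    """A base that does not WC-pair miRNA position 8 (blocks m8 upgrade)."""
    t8 = _target_base(mirna, 8)
    return "C" if t8 != "C" else "A"


def implant_site(
    utr: UTRSeq,
    mirna: MiRNASeq,
    category: SiteCategory,
    position: int,
    with_au_flanks: bool = False,
    with_supplementary: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> UTRSeq:
    """Write an exact seed site of ``category`` starting at UTR ``position``.

    The motif is the WC complement of the relevant miRNA seed positions
    read 3'->5' onto the UTR; guard bases prevent accidental upgrade of
    the planted category.  Optional edits rewrite the 30-nt flanks to A/U
    and plant the complement of miRNA positions 13-16 at the registered
    offset.  The edited UTR, scanned by seedscan, is guaranteed to yield a
    site of the requested category at the requested position.
    """
    rng = rng or np.random.default_rng(0)
    seq = list(utr.seq)
    n = len(seq)

    # motif 5'->3' on the UTR covers miRNA positions high -> low
    if category is SiteCategory.SIX_MER:
        motif = [_target_base(mirna, k) for k in range(7, 1, -1)]
        core_offset = 0
    elif category is SiteCategory.SEVEN_MER_M8:
        motif = [_target_base(mirna, k) for k in range(8, 1, -1)]
        core_offset = 1
    elif category is SiteCategory.SEVEN_MER_A1:
        motif = [_target_base(mirna, k) for k in range(7, 1, -1)] + ["A"]
        core_offset = 0
    elif category is SiteCategory.EIGHT_MER:
        motif = [_target_base(mirna, k) for k in range(8, 1, -1)] + ["A"]
        core_offset = 1
    else:
        raise ValueError(f"unknown category {category}")

    start0 = position - 1  # 0-based
    end0 = start0 + len(motif) - 1
    if start0 < 0 or end0 >= n:
        raise ValueError(
            f"insufficient room: site [{position}, {position + len(motif) - 1}] "
            f"outside UTR of length {n}"
        )

    core_start = position + core_offset  # 1-based UTR start of the 6mer core
    p1 = core_start + 6  # UTR position aligned with miRNA position 1

    # guard positions that would otherwise upgrade the category
    guards: dict[int, str] = {}
    if category in (SiteCategory.SIX_MER, SiteCategory.SEVEN_MER_A1):
        g = core_start - 1  # opposite miRNA position 8
        if g >= 1:
            guards[g] = _m8_guard(mirna)
    if category in (SiteCategory.SIX_MER, SiteCategory.SEVEN_MER_M8):
        if p1 <= n:
            guards[p1] = "C"  # anything but 'A'

    if with_supplementary and p1 - 15 < 1:
        raise ValueError("insufficient room for supplementary pairing block")

    if with_au_flanks:
        # A/U-only flanks keep pooled AU content >= 60% even with guards
        for pos in range(max(1, position - 30), position):
            seq[pos - 1] = str(rng.choice(("A", "U")))
        for pos in range(position + len(motif), min(n, position + len(motif) + 29) + 1):
            seq[pos - 1] = str(rng.choice(("A", "U")))

    for i, b in enumerate(motif):
        seq[start0 + i] = b
    for pos, b in guards.items():
        seq[pos - 1] = b

    if with_supplementary:
        # UTR positions p1-15..p1-12 pair miRNA 16..13 (ascending UTR order)
        for i, k in enumerate((16, 15, 14, 13)):
            seq[p1 - 15 + i - 1] = _target_base(mirna, k)

    return UTRSeq(id=utr.id, seq="".join(seq))


@dataclass
class SynthDataset:
    mirnas: list[MiRNASeq]
    utrs: list[UTRSeq]
    pairs: list[LabeledPair]
    config: SynthConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write mirnas.fa, utrs.fa and pairs.tsv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirnas": outdir / "mirnas.fa",
            "utrs": outdir / "utrs.fa",
            "pairs": outdir / "pairs.tsv",
        }
        write_fasta(self.mirnas, paths["mirnas"])
        write_fasta(self.utrs, paths["utrs"])
        write_pairs(self.pairs, paths["pairs"])
        return paths


_POSITIVE_CATEGORIES = (
    SiteCategory.SEVEN_MER_M8,
    SiteCategory.SEVEN_MER_A1,
    SiteCategory.EIGHT_MER,
)


def gen_dataset(cfg: SynthConfig) -> SynthDataset:
    """Balanced labeled pairs with class-dependent planted site signal.

    Positives receive a strong site (7mer-m8 / 7mer-A1 / 8mer, uniformly)
    with probability ``p_site_pos``, AU-rich flanks with
    ``p_au_flank_pos`` and supplementary pairing with ``p_supp_pos``;
    negatives receive only an unenriched weak 6mer with ``p_site_neg``.
    """
    rng = np.random.default_rng(cfg.seed)
    mirnas = [
        gen_mirna(rng, cfg.mirna_len, name=f"mir-{i + 1:03d}")
        for i in range(cfg.n_mirnas)
    ]
    utrs: list[UTRSeq] = []
    pairs: list[LabeledPair] = []
    # planted sites stay clear of the UTR ends so flanks and the
    # supplementary block always fit
    lo, hi = 40, cfg.utr_len - 40
    if hi < lo:
        raise ValueError("utr_len too short for planted sites (need >= 80 nt)")

    def one(i: int, label: int) -> None:
        mirna = mirnas[int(rng.integers(0, len(mirnas)))]
        utr = gen_utr(rng, cfg.utr_len, cfg.gc_content, name=f"utr-{i + 1:04d}")
        if label == +1:
            if rng.random() < cfg.p_site_pos:
                category = _POSITIVE_CATEGORIES[int(rng.integers(0, 3))]
                utr = implant_site(
                    utr,
                    mirna,
                    category,
                    int(rng.integers(lo, hi + 1)),
                    with_au_flanks=rng.random() < cfg.p_au_flank_pos,
                    with_supplementary=rng.random() < cfg.p_supp_pos,
                    rng=rng,
                )
        else:
            if rng.random() < cfg.p_site_neg:
                utr = implant_site(
                    utr,
                    mirna,
                    SiteCategory.SIX_MER,
                    int(rng.integers(lo, hi + 1)),
                    rng=rng,
                )
        utrs.append(utr)
        pairs.append(LabeledPair(mirna.id, utr.id, label))

    for i in range(cfg.n_pos):
        one(i, +1)
    for j in range(cfg.n_neg):
        one(cfg.n_pos + j, -1)
    return SynthDataset(mirnas, utrs, pairs, cfg)


#: catalog indices of the default planted informative features (category 4)
DEFAULT_INFORMATIVE = (22, 25, 28, 31, 34)


def gen_feature_matrix(
    n_pos: int = 289,
    n_neg: int = 289,
    informative: Sequence[int] = DEFAULT_INFORMATIVE,
    effect: float = 1.0,
    n_features: int = 90,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix with class signal planted in known catalog columns.

    Noise columns are standard normal in both classes; each informative
    column's positive-class mean is shifted by ``effect`` standard
    deviations.  Used to test whether wrapper selection recovers planted
    features.
    """
    informative = sorted(set(int(i) for i in informative))
    if not informative or informative[0] < 1 or informative[-1] > n_features:
        raise ValueError("informative indices must be within the catalog")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.standard_normal((n, n_features))
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    for idx in informative:
        X[:n_pos, idx - 1] += effect
    return X, y
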