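"""Seed-site detection and classification on 3'UTRs.

A seed-matching site is a UTR window that pairs, in the antiparallel
duplex register, with the miRNA seed (positions 2-7 or 3-8) with
Watson-Crick pairs throughout and at most one G:U wobble.  Sites on the
2-7 register are upgraded to 7mer-m8 (extra WC pair opposite miRNA
position 8), 7mer-A1 (an 'A' on the target aligned with miRNA position 1),
or 8mer (both).

Register arithmetic: if miRNA position 1 aligns with UTR position ``p1``,
miRNA position ``k`` aligns with UTR position ``p1 - (k - 1)``.  For a
6mer core on the 2-7 register starting at UTR position ``s``,
``p1 = s + 6``; on the 3-8 register, ``p1 = s + 7``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .seqio import MiRNASeq, UTRSeq

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


class PairType(Enum):
    WC = "WC"
    GU = "GU"
    NONE = "NONE"


class SiteCategory(Enum):
    SIX_MER = "6mer"
    SEVEN_MER_A1 = "7mer-A1"
    SEVEN_MER_M8 = "7mer-m8"
    EIGHT_MER = "8mer"

    @property
    def priority(self) -> int:
        return _PRIORITY[self]


_PRIORITY = {
    SiteCategory.EIGHT_MER: 3,
    SiteCategory.SEVEN_MER_M8: 2,
    SiteCategory.SEVEN_MER_A1: 1,
    SiteCategory.SIX_MER: 0,
}


class SeedRegister(Enum):
    POS_2_7 = "2-7"
    POS_3_8 = "3-8"


def pairs(mirna_base: str, utr_base: str) -> PairType:
    """Pairing type of a miRNA:target base pair."""
    if WC[mirna_base] == utr_base:
        return PairType.WC
    if (mirna_base, utr_base) in (("G", "U"), ("U", "G")):
        return PairType.GU
    return PairType.NONE


@dataclass(frozen=True)
class SeedSite:
    """One classified seed-match occurrence on a UTR (1-based, closed)."""

    utr_start: int
    utr_end: int
    category: SiteCategory
    seed_register: SeedRegister
    gu_count: int
    gu_mirna_pos: Optional[int]
    core_start: int  # UTR start of the 6mer core window

    @property
    def p1(self) -> int:
        """UTR position aligned with miRNA position 1."""
        if self.seed_register is SeedRegister.POS_2_7:
            return self.core_start + 6
        return self.core_start + 7

    def utr_pos_of_mirna(self, k: int) -> int:
        """UTR position opposite miRNA position ``k`` in this register."""
        return self.p1 - (k - 1)

    @property
    def length(self) -> int:
        return self.utr_end - self.utr_start + 1


@dataclass(frozen=True)
class SiteContext:
    """Context annotation of a site: 3'-supplementary pairing and flanks."""

    supplementary_pairing: int
    supp_extension_count: int  # additional WC pairs at miRNA positions 12/17
    au_rich_flank: int
    flank_up: str
    flank_down: str


def _match_core(mirna: MiRNASeq, utr: UTRSeq, s: int, register: SeedRegister):
    """Try to match the 6mer core window [s, s+5] in the given register.

    Returns (ok, gu_count, gu_mirna_pos): WC at every position with at most
    one G:U wobble.
    """
    lo = 2 if register is SeedRegister.POS_2_7 else 3
    gu_count = 0
    gu_pos = None
    # miRNA position lo pairs the 3'-most window base (s+5), lo+5 pairs s
    for off in range(6):
        k = lo + off
        u = utr.base(s + 5 - off)
        pt = pairs(mirna.base(k), u)
        if pt is PairType.NONE:
            return False, 0, None
        if pt is PairType.GU:
            gu_count += 1
            if gu_count > 1:
                return False, 0, None
            gu_pos = k
    return True, gu_count, gu_pos


def classify(site: SeedSite, mirna: MiRNASeq, utr: UTRSeq) -> SeedSite:
    """Upgrade a 2-7-register 6mer core to 7mer-m8 / 7mer-A1 / 8mer.

    The position-8 upgrade demands a Watson-Crick pair (wobble does not
    qualify); the A1 anchor is an identity test for 'A' on the target.
    3-8-register cores are returned unchanged.
    """
    if site.seed_register is not SeedRegister.POS_2_7:
        return site
    n = len(utr)
    start, end = site.utr_start, site.utr_end
    pos8_utr = site.utr_pos_of_mirna(8)  # = core_start - 1
    pos1_utr = site.p1
    m8 = (
        1 <= pos8_utr <= n
        and pairs(mirna.base(8), utr.base(pos8_utr)) is PairType.WC
    )
    a1 = 1 <= pos1_utr <= n and utr.base(pos1_utr) == "A"
    if m8 and a1:
        cat = SiteCategory.EIGHT_MER
        start, end = pos8_utr, pos1_utr
    elif m8:
        cat = SiteCategory.SEVEN_MER_M8
        start = pos8_utr
    elif a1:
        cat = SiteCategory.SEVEN_MER_A1
        end = pos1_utr
    else:
        cat = SiteCategory.SIX_MER
    return replace(site, category=cat, utr_start=start, utr_end=end)


def find_sites(mirna: MiRNASeq, utr: UTRSeq) -> list[SeedSite]:
    """All classified seed sites of ``mirna`` on ``utr``, sorted by start.

    Every 6-nt window matching either seed register yields its own site;
    overlapping occurrences are not merged (see :func:`effective_site`).
    """
    sites: list[SeedSite] = []
    for s in range(1, len(utr) - 4):
        for register in (SeedRegister.POS_2_7, SeedRegister.POS_3_8):
            ok, gu, gu_pos = _match_core(mirna, utr, s, register)
            if not ok:
                continue
            site = SeedSite(
                utr_start=s,
                utr_end=s + 5,
                category=SiteCategory.SIX_MER,
                seed_register=register,
                gu_count=gu,
                gu_mirna_pos=gu_pos,
                core_start=s,
            )
            sites.append(classify(site, mirna, utr))
    sites.sort(key=lambda x: (x.utr_start, x.utr_end, x.seed_register.value))
    return sites


def effective_site(sites: list[SeedSite]) -> Optional[SeedSite]:
    """Pick the strongest site: 8mer > 7mer-m8 > 7mer-A1 > 6mer.

    Ties break to fewer GU wobbles, then the smallest UTR start.
    """
    if not sites:
        return None
    return min(sites, key=lambda x: (-x.category.priority, x.gu_count, x.utr_start))


def supplementary_pairing(mirna: MiRNASeq, utr: UTRSeq, site: SeedSite) -> int:
    """1 iff miRNA positions 13-16 are all WC-paired in the site's register.

    Positions falling outside the UTR yield 0.  Extra pairing at 12/17 does
    not change the flag (it is reported separately by :func:`site_context`).
    """
    if len(mirna) < 16:
        raise ValueError(f"miRNA {mirna.id!r} shorter than 16 nt")
    n = len(utr)
    for k in range(13, 17):
        u = site.utr_pos_of_mirna(k)
        if not (1 <= u <= n):
            return 0
        if pairs(mirna.base(k), utr.base(u)) is not PairType.WC:
            return 0
    return 1


def _supp_extension_count(mirna: MiRNASeq, utr: UTRSeq, site: SeedSite) -> int:
    count = 0
    n = len(utr)
    for k in (12, 17):
        if k > len(mirna):
            continue
        u = site.utr_pos_of_mirna(k)
        if 1 <= u <= n and pairs(mirna.base(k), utr.base(u)) is PairType.WC:
            count += 1
    return count


def flanks(utr: UTRSeq, site: SeedSite, window: int = 30) -> tuple[str, str]:
    """Up/downstream flanks of the site, truncated at the UTR boundaries."""
    up = utr.subseq(site.utr_start - window, site.utr_start - 1)
    down = utr.subseq(site.utr_end + 1, site.utr_end + window)
    return up, down


def au_flank_flag(
    utr: UTRSeq,
    site: SeedSite,
    window: int = 30,
    threshold: float = 0.60,
) -> tuple[int, SiteContext]:
    """AU-richness of the pooled site flanks (>= 60% A+U -> 1).

    Pools up to ``window`` nt on each side of the site (site excluded,
    truncated at the UTR ends); an empty pool yields 0.  Returns the flag
    plus a partial :class:`SiteContext` (supplementary fields unset = 0).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    up, down = flanks(utr, site, window)
    pooled = up + down
    if pooled:
        au = sum(1 for b in pooled if b in "AU") / len(pooled)
        flag = int(au >= threshold)
    else:
        flag = 0
    return flag, SiteContext(0, 0, flag, up, down)


def site_context(
    mirna: MiRNASeq,
    utr: UTRSeq,
    site: SeedSite,
    window: int = 30,
    threshold: float = 0.60,
) -> SiteContext:
    """Full context annotation: supplementary pairing, extension, AU flanks."""
    supp = supplementary_pairing(mirna, utr, site) if len(mirna) >= 16 else 0
    ext = _supp_extension_count(mirna, utr, site) if supp else 0
    au, ctx = au_flank_flag(utr, site, window, threshold)
    return SiteContext(supp, ext, au, ctx.flank_up, ctx.flank_down)
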