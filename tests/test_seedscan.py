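import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitar.seqio import MiRNASeq, UTRSeq
from mitar.seedscan import (
    PairType,
    SeedRegister,
    SeedSite,
    SiteCategory,
    au_flank_flag,
    effective_site,
    find_sites,
    flanks,
    pairs,
    supplementary_pairing,
)

from .conftest import utr_with
from .oracles import brute_force_sites


@pytest.mark.parametrize(
    "m,u,expected",
    [
        ("A", "U", PairType.WC),
        ("U", "A", PairType.WC),
        ("G", "C", PairType.WC),
        ("C", "G", PairType.WC),
        ("G", "U", PairType.GU),
        ("U", "G", PairType.GU),
        ("A", "G", PairType.NONE),
        ("A", "C", PairType.NONE),
        ("C", "U", PairType.NONE),
        ("A", "A", PairType.NONE),
    ],
)
def test_base_pairing_table(m, u, expected):
    assert pairs(m, u) is expected


@pytest.mark.parametrize(
    "motif,category,length,gu",
    [
        ("UACCUC", SiteCategory.SIX_MER, 6, 0),
        ("UACCUU", SiteCategory.SIX_MER, 6, 1),  # G2:U wobble
        ("CUACCUC", SiteCategory.SEVEN_MER_M8, 7, 0),
        ("UACCUCA", SiteCategory.SEVEN_MER_A1, 7, 0),
        ("CUACCUCA", SiteCategory.EIGHT_MER, 8, 0),
    ],
)
def test_let7a_site_classification(let7a, motif, category, length, gu):
    """The canonical let-7a seed motifs classify to their site categories."""
    sites = find_sites(let7a, utr_with(motif))
    hits = [s for s in sites if s.category is category]
    assert len(hits) == 1
    site = hits[0]
    assert site.length == length
    assert site.gu_count == gu
    if gu:
        assert site.gu_mirna_pos == 2


def test_no_complementarity_yields_empty(let7a):
    assert find_sites(let7a, UTRSeq("u", "G" * 40)) == []


def test_two_wobbles_never_a_site(let7a):
    # UACCUC with both U1->G-pairing changes: G2:U and G5:U need 2 wobbles
    assert all(
        s.gu_count <= 1 for s in find_sites(let7a, utr_with("UAUCUU"))
    )
    assert not [s for s in find_sites(let7a, utr_with("UAUCUU")) if s.seed_register is SeedRegister.POS_2_7]


def _mk_site(start, end, category, gu=0, register=SeedRegister.POS_2_7, core=None):
    return SeedSite(start, end, category, register, gu, None, core if core is not None else start)


def test_effective_site_priority_and_ties():
    six = _mk_site(10, 15, SiteCategory.SIX_MER)
    eight = _mk_site(50, 57, SiteCategory.EIGHT_MER, core=51)
    assert effective_site([six, eight]) is eight
    a = _mk_site(10, 16, SiteCategory.SEVEN_MER_M8, core=11)
    b = _mk_site(40, 46, SiteCategory.SEVEN_MER_M8, core=41)
    assert effective_site([b, a]) is a  # smallest start wins
    wob = _mk_site(5, 10, SiteCategory.SIX_MER, gu=1)
    clean = _mk_site(30, 35, SiteCategory.SIX_MER, gu=0)
    assert effective_site([wob, clean]) is clean  # fewer wobbles beat position
    assert effective_site([]) is None


def _wc(b):
    return {"A": "U", "U": "A", "G": "C", "C": "G"}[b]


def test_supplementary_pairing_constructed(let7a):
    """UTR built from the register arithmetic triggers the 13-16 flag."""
    # plant an 8mer: core starts at s, p1 = s + 6; miRNA k pairs UTR p1-(k-1)
    s = 30
    seq = list("G" * 60)
    for i, k in enumerate(range(8, 1, -1)):  # positions s-1 .. s+5
        seq[s - 2 + i] = _wc(let7a.base(k))
    seq[s + 5] = "A"  # p1
    p1 = s + 6
    for k in range(13, 17):
        seq[p1 - (k - 1) - 1] = _wc(let7a.base(k))
    utr = UTRSeq("u", "".join(seq))
    site = [x for x in find_sites(let7a, utr) if x.category is SiteCategory.EIGHT_MER][0]
    assert supplementary_pairing(let7a, utr, site) == 1

    # breaking any one of the four opposite bases kills the flag
    broken = list(seq)
    broken[p1 - 13 - 1] = "G"  # opposite miRNA position 14 (let-7a U14 pairs A)
    site2 = [
        x
        for x in find_sites(let7a, UTRSeq("u", "".join(broken)))
        if x.category is SiteCategory.EIGHT_MER
    ][0]
    assert supplementary_pairing(let7a, UTRSeq("u", "".join(broken)), site2) == 0


def test_supplementary_out_of_range_is_zero(let7a):
    """A site at the UTR 5' end has no room opposite positions 13-16."""
    utr = utr_with("UACCUC", pad=0)  # site at start 1
    site = find_sites(let7a, utr)[0]
    assert site.utr_start == 1
    assert supplementary_pairing(let7a, utr, site) == 0


def test_au_flank_flag_extremes_and_boundary(let7a):
    core = "UACCUC"
    for fill, want in (("A", 1), ("G", 0)):
        utr = UTRSeq("u", fill * 30 + core + fill * 30)
        site = [s for s in find_sites(let7a, utr) if s.utr_start == 31][0]
        assert au_flank_flag(utr, site)[0] == want
    # exactly 36 A/U of pooled 60 -> >= 60% boundary holds
    up = "A" * 18 + "G" * 12
    down = "G" * 12 + "A" * 18
    utr = UTRSeq("u", up + core + down)
    site = [s for s in find_sites(let7a, utr) if s.utr_start == 31][0]
    assert au_flank_flag(utr, site)[0] == 1
    # one fewer A/U falls below
    utr35 = UTRSeq("u", ("A" * 17 + "G" * 13) + core + down)
    site = [s for s in find_sites(let7a, utr35) if s.utr_start == 31][0]
    assert au_flank_flag(utr35, site)[0] == 0


def test_flank_truncation_at_utr_ends(let7a):
    utr = UTRSeq("u", "GG" + "UACCUC" + "G" * 50)
    site = [s for s in find_sites(let7a, utr) if s.utr_start == 3][0]
    up, down = flanks(utr, site)
    assert len(up) == 2 and len(down) == 30


_rna = st.text(alphabet="ACGU", min_size=16, max_size=24)
_utr = st.text(alphabet="ACGU", min_size=6, max_size=120)


@given(_rna, _utr)
def test_scanner_matches_brute_force(mirna_seq, utr_seq):
    """find_sites agrees exactly with a naive window-by-window scanner."""
    got = [
        (s.utr_start, s.utr_end, s.category.value, s.seed_register.value, s.gu_count)
        for s in find_sites(MiRNASeq("m", mirna_seq), UTRSeq("u", utr_seq))
    ]
    assert sorted(got) == brute_force_sites(mirna_seq, utr_seq)


def test_scanner_matches_brute_force_seeded_random():
    rng = np.random.default_rng(7)
    nucs = np.array(list("ACGU"))
    for _ in range(150):
        m = "".join(rng.choice(nucs, size=22))
        u = "".join(rng.choice(nucs, size=int(rng.integers(6, 200))))
        got = [
            (s.utr_start, s.utr_end, s.category.value, s.seed_register.value, s.gu_count)
            for s in find_sites(MiRNASeq("m", m), UTRSeq("u", u))
        ]
        assert sorted(got) == brute_force_sites(m, u)
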