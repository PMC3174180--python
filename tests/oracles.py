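"""Independent brute-force oracles used by the test suite.

Deliberately naive re-derivations of the scanning and metric rules,
written directly from their definitions and kept independent of the
package implementation they check.
"""

import math

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_sites(mirna_seq: str, utr_seq: str):
    """Every seed site as (start, end, category, register, gu_count).

    Tests each 6-nt UTR window against miRNA positions 2-7 and 3-8 in the
    antiparallel register: all positions WC with at most one G:U/U:G
    wobble.  2-7 cores are upgraded by re-checking the rules: 7mer-m8 if
    the base opposite miRNA position 8 is the WC partner, 7mer-A1 if the
    base aligned with miRNA position 1 is 'A', 8mer if both.
    """
    n = len(utr_seq)
    out = []
    for s in range(1, n - 4):  # 1-based window start, window = [s, s+5]
        for register, lo in (("2-7", 2), ("3-8", 3)):
            gu = 0
            ok = True
            for off in range(6):
                m = mirna_seq[lo + off - 1]
                u = utr_seq[s + 5 - off - 1]
                if _WC[m] == u:
                    continue
                if (m, u) in (("G", "U"), ("U", "G")):
                    gu += 1
                    if gu > 1:
                        ok = False
                        break
                else:
                    ok = False
                    break
            if not ok:
                continue
            start, end, category = s, s + 5, "6mer"
            if register == "2-7":
                p1 = s + 6
                pos8 = s - 1
                m8 = 1 <= pos8 <= n and utr_seq[pos8 - 1] == _WC[mirna_seq[7]]
                a1 = p1 <= n and utr_seq[p1 - 1] == "A"
                if m8 and a1:
                    category, start, end = "8mer", pos8, p1
                elif m8:
                    category, start = "7mer-m8", pos8
                elif a1:
                    category, end = "7mer-A1", p1
            out.append((start, end, category, register, gu))
    out.sort()
    return out


def mcc_formula(tp, tn, fp, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auc_pairwise(scores, labels):
    """Fraction of correctly ordered (positive, negative) pairs, ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def pearson_formula(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
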