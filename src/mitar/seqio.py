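"""Sequence and pair-table I/O.

All coordinate conventions used by the rest of the package live here:
positions are 1-based, intervals are closed ``[start, end]``, sequences are
written 5'->3' and carried in the RNA alphabet ``{A, C, G, U}``.  DNA input
(``T``) and lowercase are normalized on load, so downstream modules only
ever see uppercase RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: minimum plausible mature miRNA length
MIN_MIRNA_LEN = 15

#: default textual aliases for pair labels
LABEL_ALIASES = {"1": 1, "+1": 1, "-1": -1}


class DataError(ValueError):
    """Malformed input data (bad FASTA record, bad pair table, ...)."""


def normalize_seq(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, map T->U and validate against the RNA alphabet.

    Raises :class:`DataError` naming the 1-based position of the first
    offending character.
    """
    seq = raw.upper().replace("T", "U")
    for pos, base in enumerate(seq, start=1):
        if base not in RNA_ALPHABET:
            raise DataError(
                f"record {record_id!r}: invalid base {base!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class MiRNASeq:
    """A mature miRNA, 5'->3'.

    Position 1 is the 5' base; the seed region is positions 1-8 and the
    out-seed region is 9..length.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < MIN_MIRNA_LEN:
            raise DataError(
                f"miRNA {self.id!r}: length {len(self.seq)} < {MIN_MIRNA_LEN}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.seq[pos - 1]

    @property
    def seed(self) -> str:
        return self.seq[:8]


@dataclass(frozen=True)
class UTRSeq:
    """A 3'UTR, 5'->3', 1-based closed coordinates."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise DataError(f"UTR {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        return self.seq[pos - 1]

    def subseq(self, start: int, end: int) -> str:
        """Substring for the closed interval [start, end], clipped to bounds."""
        start = max(start, 1)
        end = min(end, len(self.seq))
        if start > end:
            return ""
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class LabeledPair:
    """A miRNA-transcript pair with class label (+1 target, -1 non-target)."""

    mirna_id: str
    utr_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise DataError(f"label must be +1 or -1, got {self.label}")


def read_fasta(path: str | Path, kind: str) -> list[MiRNASeq] | list[UTRSeq]:
    """Read a multi-record FASTA as miRNAs or UTRs.

    Record ids must be unique; sequences are normalized to uppercase RNA.
    """
    if kind not in ("mirna", "utr"):
        raise ValueError(f"kind must be 'mirna' or 'utr', got {kind!r}")
    cls = MiRNASeq if kind == "mirna" else UTRSeq
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(cls(id=rec.id, seq=normalize_seq(str(rec.seq), record_id=rec.id)))
    return records


def write_fasta(records: Iterable[MiRNASeq | UTRSeq], path: str | Path) -> None:
    """Write records as plain FASTA (id + one sequence line)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_pairs(
    path: str | Path,
    *,
    aliases: dict[str, int] | None = None,
    header: bool = False,
) -> list[LabeledPair]:
    """Read a TSV of (mirna_id, utr_id, label) rows.

    ``aliases`` maps label spellings to {+1, -1}; anything else is an error
    citing the 1-based data row number.
    """
    aliases = dict(LABEL_ALIASES if aliases is None else aliases)
    pairs: list[LabeledPair] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if header and lines:
        lines = lines[1:]
    for row_no, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}: row {row_no}: expected >=3 columns, got {len(fields)}")
        mirna_id, utr_id, label_str = fields[0], fields[1], fields[2].strip()
        if label_str not in aliases:
            raise DataError(f"{path}: row {row_no}: invalid label {label_str!r}")
        pairs.append(LabeledPair(mirna_id, utr_id, aliases[label_str]))
    return pairs


def write_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.mirna_id}\t{p.utr_id}\t{p.label:+d}\n")


def index_by_id(records: Sequence) -> dict[str, object]:
    return {rec.id: rec for rec in records}


def resolve_pairs(
    pairs: Sequence[LabeledPair],
    mirnas: Sequence[MiRNASeq],
    utrs: Sequence[UTRSeq],
) -> list[tuple[LabeledPair, MiRNASeq, UTRSeq]]:
    """Join pairs to their sequences; unresolvable pairs are logged and skipped."""
    mi = index_by_id(mirnas)
    ut = index_by_id(utrs)
    out = []
    for p in pairs:
        if p.mirna_id not in mi or p.utr_id not in ut:
            log.warning("skipping pair (%s, %s): unknown id", p.mirna_id, p.utr_id)
            continue
        out.append((p, mi[p.mirna_id], ut[p.utr_id]))
    return out
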