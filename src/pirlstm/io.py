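"""Reading, validating and writing RNA sequences in FASTA.

Sequences are held as :class:`RnaSequence` records over the alphabet
``{A, U, C, G, N}`` (``N`` marks an uncertain base).  Incoming DNA-alphabet
files are normalized transparently: case is folded and ``T`` is mapped to
``U``.  Any other character is rejected rather than silently coerced, so a
malformed record can never contaminate a benchmark.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("AUCGN")

__all__ = [
    "RnaSequence",
    "SequenceValidationError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
]


class SequenceValidationError(ValueError):
    """Raised when a sequence record violates the RNA alphabet contract."""


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over ``{A, U, C, G, N}``.

    Attributes
    ----------
    id : str
        First whitespace-delimited token of the FASTA header.
    bases : str
        Upper-case RNA bases, length >= 1.
    description : str
        Free-text remainder of the header (may be empty).
    """

    id: str
    bases: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = next((i for i, b in enumerate(self.bases) if b not in RNA_ALPHABET), None)
        if bad is not None:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal character {self.bases[bad]!r} "
                f"at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.bases)


def normalize_sequence(raw: str, *, record_id: str = "<anonymous>",
                       map_ambiguous_to_n: bool = False) -> str:
    """Upper-case ``raw`` and map DNA ``T`` to RNA ``U``.

    Characters outside ``{A, C, G, U, T, N}`` (case-insensitive) raise
    :class:`SequenceValidationError` naming the character and its 1-based
    position.  With ``map_ambiguous_to_n`` the IUPAC ambiguity codes
    (R, Y, S, W, K, M, B, D, H, V) are mapped to ``N`` instead of rejected.
    """
    if not raw:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    out = raw.upper().replace("T", "U")
    if map_ambiguous_to_n:
        out = "".join("N" if c in "RYSWKMBDHV" else c for c in out)
    for i, c in enumerate(out):
        if c not in RNA_ALPHABET:
            raise SequenceValidationError(
                f"record {record_id!r}: illegal character {raw[i]!r} at position {i + 1}"
            )
    return out


def read_fasta(path: str | os.PathLike, *, map_ambiguous_to_n: bool = False) -> list[RnaSequence]:
    """Read a FASTA file into a list of normalized :class:`RnaSequence`.

    Multi-line record bodies are concatenated; records appear in file order.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[RnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.id if rec.id else "<missing header>"
        bases = normalize_sequence(str(rec.seq), record_id=rec_id,
                                   map_ambiguous_to_n=map_ambiguous_to_n)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(RnaSequence(id=rec_id, bases=bases, description=desc))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | os.PathLike) -> None:
    """Write sequences as FASTA (60-column bodies). Ids must be unique.

    Round trip: ``read_fasta(write_fasta(x))`` reproduces ids and bases.
    """
    seqs = list(seqs)
    seen: set[str] = set()
    for s in seqs:
        if s.id in seen:
            raise SequenceValidationError(f"duplicate sequence id {s.id!r}")
        seen.add(s.id)
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
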