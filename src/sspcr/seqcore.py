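"""Sequence types, coordinate conventions and file I/O shared by all modules.

Conventions used throughout the package:

* Coordinates are 0-based, half-open (`[start, end)`), matching BED. Any
  1-based presentation happens only at a formatting boundary.
* Primers are always written 5'->3'.  A site on strand ``+`` means the primer
  sequence itself appears on the plus strand over the footprint (the primer
  anneals to the minus strand and extension proceeds toward increasing
  coordinates); a site on strand ``-`` means the footprint's plus-strand slice
  is the primer's reverse complement (extension proceeds toward decreasing
  coordinates).
* Only strict ``ACGT`` is accepted.  IUPAC ambiguity codes are rejected rather
  than silently matched, because every downstream rule counts base matches.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "InvalidBaseError",
    "NucleotideSequence",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "revcomp",
    "write_bed",
    "read_bed",
    "CLASS_CODES",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class InvalidBaseError(ValueError):
    """Raised when a sequence contains a symbol outside {A, C, G, T}."""


def _normalise(bases: str, name: str) -> str:
    up = bases.upper()
    for off, ch in enumerate(up):
        if ch not in _VALID:
            raise InvalidBaseError(
                f"record {name!r}: non-ACGT symbol {ch!r} at offset {off}"
            )
    return up


@dataclass(frozen=True)
class NucleotideSequence:
    """An immutable DNA sequence over the strict {A,C,G,T} alphabet.

    Lowercase input is normalised to uppercase; empty sequences and ambiguity
    codes are rejected with :class:`InvalidBaseError`.
    """

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise InvalidBaseError(f"record {self.name!r}: empty sequence")
        object.__setattr__(self, "bases", _normalise(self.bases, self.name))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def slice(self, start: int, end: int, name: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(self.bases[start:end], name or self.name)

    def reverse_complement(self, name: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(revcomp(self.bases), name or self.name)


def revcomp(bases: str) -> str:
    """Reverse complement of a raw ACGT string (fast path for internals)."""
    return bases.translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement; an involution."""
    return seq.reverse_complement()


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | os.PathLike) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into :class:`NucleotideSequence` records.

    Order is preserved.  Raises ``FileNotFoundError`` for a missing file,
    ``ValueError`` for an empty file and :class:`InvalidBaseError` (naming the
    record and offset) for non-ACGT residues.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such FASTA file: {path}")
    records = [
        NucleotideSequence(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(s.bases), id=s.name or "seq", description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


#: BED score codes for amplifiability classes.
CLASS_CODES = {
    "target": 2,
    "suppressed-short": 1,
    "nontarget-unamplifiable": 0,
}
_CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}


def write_bed(predictions: Sequence, path: str | os.PathLike) -> None:
    """Write amplicon predictions (or any objects exposing ``interval``,
    ``amplicon_class`` and optionally ``name``) as BED6.

    The score column carries the amplifiability class code
    (2 target, 1 suppressed-short, 0 nontarget-unamplifiable).
    """
    with open(path, "w") as fh:
        for pred in predictions:
            iv = pred.interval
            name = getattr(pred, "name", None) or getattr(pred, "amplicon_class", ".")
            code = CLASS_CODES.get(getattr(pred, "amplicon_class", ""), 0)
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{code}\t{iv.strand}\n"
            )


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str
    score: int

    @property
    def amplicon_class(self) -> str:
        return _CODE_CLASSES.get(self.score, "nontarget-unamplifiable")


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    out: list[BedRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = int(parts[4]) if len(parts) > 4 else 0
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(BedRecord(GenomicInterval(contig, start, end, strand), name, score))
    return out
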