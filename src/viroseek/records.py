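"""Sequence records and plain-text sequence I/O.

The in-memory unit is :class:`SequenceRecord`: one nucleotide or protein
sequence with a topology flag (linear or circular) and an explicit alphabet.
Ground-truth provenance for simulated sequences travels in the description
line as ``key=value;`` pairs so that FASTA/FASTQ files stay standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import AlphabetError, ParameterError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

# '-' permitted so aligned rows (gapped) can travel as records
_NT_LETTERS = frozenset("ACGTN-")
_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """One sequence with identity, topology and alphabet.

    Residues are stored upper-case. ``topology`` is ``linear`` or
    ``circular``; ``alphabet`` is ``nucleotide`` or ``protein``.
    """

    id: str
    residues: str
    description: str = ""
    topology: str = "linear"
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParameterError(f"record {self.id!r}: residues must be non-empty")
        self.residues = self.residues.upper()
        if self.topology not in ("linear", "circular"):
            raise ParameterError(f"record {self.id!r}: bad topology {self.topology!r}")
        letters = set(self.residues)
        if self.alphabet == NUCLEOTIDE:
            if not letters <= _NT_LETTERS:
                raise AlphabetError(
                    f"record {self.id!r}: non-nucleotide letters {sorted(letters - _NT_LETTERS)}"
                )
        elif self.alphabet == PROTEIN:
            if not letters <= _AA_LETTERS:
                raise AlphabetError(
                    f"record {self.id!r}: non-protein letters {sorted(letters - _AA_LETTERS)}"
                )
        else:
            raise ParameterError(f"record {self.id!r}: bad alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != NUCLEOTIDE:
            raise AlphabetError(f"record {self.id!r}: cannot reverse-complement protein")
        return replace(self, residues=self.residues.translate(_COMPLEMENT)[::-1])

    # -- provenance ---------------------------------------------------------

    def provenance(self) -> dict[str, str]:
        """Parse ``key=value;`` pairs out of the description line."""
        out: dict[str, str] = {}
        for part in self.description.split(";"):
            part = part.strip()
            if "=" in part:
                key, _, value = part.partition("=")
                out[key.strip()] = value.strip()
        return out


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def format_provenance(**fields) -> str:
    return ";".join(f"{k}={v}" for k, v in fields.items()) + ";"


# -- file I/O ---------------------------------------------------------------


def _to_bio(rec: SequenceRecord) -> _BioRecord:
    desc = rec.description
    if rec.topology == "circular" and "topology=" not in desc:
        desc = (desc + " " if desc else "") + "topology=circular;"
    return _BioRecord(Seq(rec.residues), id=rec.id, description=desc)


def _from_bio(bio: _BioRecord, alphabet: str) -> SequenceRecord:
    desc = bio.description
    if desc.startswith(bio.id):
        desc = desc[len(bio.id) :].strip()
    topology = "circular" if "topology=circular" in desc else "linear"
    return SequenceRecord(
        id=bio.id, residues=str(bio.seq), description=desc, topology=topology, alphabet=alphabet
    )


def read_fasta(path: str | Path, alphabet: str = NUCLEOTIDE) -> list[SequenceRecord]:
    return [_from_bio(r, alphabet) for r in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    return [_from_bio(r, NUCLEOTIDE) for r in SeqIO.parse(str(path), "fastq")]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write((_to_bio(r) for r in records), str(path), "fasta")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, quality: int = 40) -> None:
    """Write reads as FASTQ with a flat quality string (quality 40 = 'I')."""

    def _iter() -> Iterator[_BioRecord]:
        for rec in records:
            bio = _to_bio(rec)
            bio.letter_annotations["phred_quality"] = [quality] * len(rec)
            yield bio

    SeqIO.write(_iter(), str(path), "fastq")


def write_ground_truth(reads: Iterable[SequenceRecord], path: str | Path) -> None:
    """Sidecar TSV of read provenance (0-based half-open, forward-strand coords)."""
    with open(path, "w") as fh:
        fh.write("read_id\tsource_id\tstart\tend\tstrand\tis_background\n")
        for rec in reads:
            p = rec.provenance()
            fh.write(
                "\t".join(
                    [
                        rec.id,
                        p.get("source", "."),
                        p.get("start", "."),
                        p.get("end", "."),
                        p.get("strand", "."),
                        p.get("background", "0"),
                    ]
                )
                + "\n"
            )
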