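"""Conserved-block marker extraction from a protein multiple alignment.

Virophage surveys here use a single-copy core gene — the major capsid
protein — as the marker. From an alignment of reference MCPs this module
scores per-column conservation (mean pairwise identity among non-gap
residues), finds the best strictly contiguous, gap-free window of a fixed
length (60 columns by default), and maps it onto the ungapped coordinates
of a chosen reference row, reported 1-based inclusive in the style
"positions 345-404".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import FormatError, MappingError, NoBlockError, ParameterError
from .records import PROTEIN, SequenceRecord


@dataclass
class MultipleAlignment:
    """An aligned set of protein sequences with a common column count."""

    records: list[SequenceRecord]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            bad = [r.id for r in self.records if len(r) != len(self.records[0])]
            raise FormatError(f"ragged alignment; offending records: {bad}")
        self.n_columns = len(self.records[0])

    def row(self, rec_id: str) -> str:
        for r in self.records:
            if r.id == rec_id:
                return r.residues
        raise ParameterError(f"record {rec_id!r} not in alignment")

    def matrix(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records], dtype="U1")


@dataclass
class ConservedBlock:
    """A contiguous window of alignment columns chosen as the survey marker."""

    start_col: int  # 0-based half-open column interval
    end_col: int
    window_length: int
    per_column_score: list[float]
    mean_score: float
    gap_fraction: float  # mean over block columns
    block_sequences: dict[str, str]  # record id -> ungapped block subsequence
    ref_id: str | None = None
    ref_start: int | None = None  # 1-based inclusive on the ungapped reference
    ref_end: int | None = None


def read_alignment(path: str | Path, format: str = "fasta") -> MultipleAlignment:
    """Load an aligned-FASTA or Clustal alignment; '.' is treated as a gap."""
    path = str(path)
    if format not in ("fasta", "clustal"):
        raise ParameterError(f"unsupported alignment format {format!r}")
    try:
        if format == "clustal":
            rows = list(AlignIO.read(path, "clustal"))
        else:
            rows = list(SeqIO.parse(path, "fasta"))
    except ValueError as exc:
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc
    records = [
        SequenceRecord(
            id=r.id,
            residues=str(r.seq).upper().replace(".", "-"),
            description="",
            alphabet=PROTEIN,
        )
        for r in rows
    ]
    return MultipleAlignment(records)


class ColumnStats(NamedTuple):
    scores: np.ndarray  # mean pairwise identity per column, in [0, 1]
    gap_fractions: np.ndarray


def column_conservation(msa: MultipleAlignment) -> ColumnStats:
    """Per-column conservation = mean pairwise identity among non-gap residues.

    A column with fewer than two non-gap residues scores 0.
    """
    mat = msa.matrix()
    n_rows, n_cols = mat.shape
    scores = np.zeros(n_cols)
    gaps = np.zeros(n_cols)
    for c in range(n_cols):
        col = mat[:, c]
        residues = col[col != "-"]
        gaps[c] = (n_rows - len(residues)) / n_rows
        n = len(residues)
        if n < 2:
            continue
        _, counts = np.unique(residues, return_counts=True)
        same = (counts * (counts - 1) // 2).sum()
        scores[c] = same / (n * (n - 1) // 2)
    return ColumnStats(scores, gaps)


def extract_conserved_block(
    msa: MultipleAlignment,
    window_length: int = 60,
    max_gap_fraction: float = 0.0,
    ref_id: str | None = None,
) -> ConservedBlock:
    """Best window of exactly ``window_length`` contiguous columns.

    Only windows whose every column has gap fraction <= ``max_gap_fraction``
    are eligible; among those the window maximizing mean conservation wins,
    ties going to the smallest start column. With ``ref_id`` the block is
    also mapped onto that reference row's ungapped coordinates.
    """
    if msa.n_columns < window_length:
        raise ParameterError(
            f"alignment has {msa.n_columns} columns < window_length {window_length}"
        )
    scores, gaps = column_conservation(msa)
    eligible = gaps <= max_gap_fraction
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    ok = np.concatenate([[0], np.cumsum(eligible.astype(int))])
    best_start, best_mean = None, -1.0
    for s in range(msa.n_columns - window_length + 1):
        e = s + window_length
        if ok[e] - ok[s] != window_length:
            continue
        mean = (csum[e] - csum[s]) / window_length
        if mean > best_mean + 1e-12:
            best_start, best_mean = s, mean
    if best_start is None:
        raise NoBlockError(
            f"no gap-compatible window of {window_length} columns at "
            f"max_gap_fraction={max_gap_fraction}; consider relaxing max_gap_fraction"
        )
    s, e = best_start, best_start + window_length
    block = ConservedBlock(
        start_col=s,
        end_col=e,
        window_length=window_length,
        per_column_score=[float(x) for x in scores[s:e]],
        mean_score=float(np.mean(scores[s:e])),
        gap_fraction=float(np.mean(gaps[s:e])),
        block_sequences={r.id: r.residues[s:e].replace("-", "") for r in msa.records},
    )
    if ref_id is not None:
        block.ref_id = ref_id
        block.ref_start, block.ref_end = map_block_to_reference(msa, block, ref_id)
    return block


def map_block_to_reference(
    msa: MultipleAlignment, block: ConservedBlock, ref_id: str
) -> tuple[int, int]:
    """1-based inclusive ungapped positions of the block on ``ref_id``.

    The interval spans the first to the last reference residue inside the
    block columns, so its length is at most the window length, with
    equality exactly when the reference row is gap-free in the block.
    """
    row = msa.row(ref_id)
    sub = row[block.start_col : block.end_col]
    non_gap_cols = [i for i, aa in enumerate(sub) if aa != "-"]
    if not non_gap_cols:
        raise MappingError(f"reference {ref_id!r} is all-gap within the block")
    before = row[: block.start_col].replace("-", "")
    first, last = non_gap_cols[0], non_gap_cols[-1]
    offset_first = len(sub[:first].replace("-", ""))
    offset_last = len(sub[: last + 1].replace("-", ""))
    ref_start = len(before) + offset_first + 1
    ref_end = len(before) + offset_last
    return ref_start, ref_end


def block_consensus(block: ConservedBlock) -> str:
    """Majority residue per position across the (gap-free) block rows.

    Ties resolve to the alphabetically smallest residue. Requires all block
    rows to have equal ungapped length (true for a gap-free block).
    """
    seqs = list(block.block_sequences.values())
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ParameterError("block rows have unequal ungapped lengths; consensus undefined")
    out = []
    for i in range(lengths.pop()):
        col = sorted(s[i] for s in seqs)
        best = max(set(col), key=lambda aa: (col.count(aa), -ord(aa)))
        out.append(best)
    return "".join(out)
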