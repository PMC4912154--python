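"""Local-alignment homology searches with survey filter semantics.

Three search families drive the pipeline:

* translated screening — every read is six-frame translated and aligned
  against the conserved marker block in protein space (identity and
  match-length cut-offs, e.g. >30% identity and >55 aligned columns);
* read recruitment — nucleotide alignment of reads against contigs at
  stringent identity with a query-coverage cut-off (>95% / >50%), keeping
  multi-contig hits because contig linking depends on reads that map to
  two distinct contigs;
* marker surveys — nucleotide (SSU V9) and translated (phycodnavirus MCP
  block) searches with a target-coverage cut-off.

All cut-offs are strict inequalities. Percent identity is computed over
all alignment columns including gap columns (the common tabular-output
convention). Small instances run full optimal local alignment
(Smith-Waterman via Biopython's pairwise aligner, BLOSUM62 11/1 for
protein, +2/-3 with gap open 5 extend 2 for nucleotide); read recruitment
against long contigs uses an exact-k-mer seeded, gapless diagonal
extension with a windowed dynamic-programming fallback, which is
score-identical for the substitution-only divergence model the synthetic
communities implement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import ParameterError
from .marker_block import ConservedBlock
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord, revcomp

# -- scoring ----------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring; gap of length k costs open + extend * k."""

    kind: str  # "protein" | "nucleotide"
    match: float | None = None
    mismatch: float | None = None
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        if self.kind == "protein":
            a.substitution_matrix = _BLOSUM62
        else:
            a.match_score = self.match
            a.mismatch_score = self.mismatch
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


PROTEIN_SCORING = Scoring(kind="protein", gap_open=11, gap_extend=1)
NUCLEOTIDE_SCORING = Scoring(kind="nucleotide", match=2, mismatch=-3, gap_open=5, gap_extend=2)

FRAME_ORDER = {f: i for i, f in enumerate((1, 2, 3, -1, -2, -3))}


# -- hits and filters --------------------------------------------------------


@dataclass
class AlignmentHit:
    """One local alignment between a query (read/ORF/frame) and a target.

    Coordinates are 0-based half-open on the *forward* coordinate system of
    each sequence, regardless of strand or frame.
    """

    query_id: str
    target_id: str
    score: float
    identities: int
    mismatches: int
    gap_opens: int
    aligned_length: int  # columns, including gap columns
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    query_length: int
    target_length: int
    strand: str = "+"
    frame: int | None = None  # +-1..3 for translated hits

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_length

    @property
    def query_cov_pct(self) -> float:
        return 100.0 * (self.query_end - self.query_start) / self.query_length

    @property
    def target_cov_pct(self) -> float:
        return 100.0 * (self.target_end - self.target_start) / self.target_length


@dataclass(frozen=True)
class FilterSpec:
    """Strict-inequality cut-offs; criteria left as None are not applied."""

    min_identity_pct: float | None = None
    min_match_length: int | None = None
    min_query_cov_pct: float | None = None
    min_target_cov_pct: float | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (
                self.min_identity_pct,
                self.min_match_length,
                self.min_query_cov_pct,
                self.min_target_cov_pct,
            )
        ):
            raise ParameterError("FilterSpec: at least one criterion must be set")

    def passes(self, hit: AlignmentHit) -> bool:
        if self.min_identity_pct is not None and not hit.identity_pct > self.min_identity_pct:
            return False
        if self.min_match_length is not None and not hit.aligned_length > self.min_match_length:
            return False
        if self.min_query_cov_pct is not None and not hit.query_cov_pct > self.min_query_cov_pct:
            return False
        if self.min_target_cov_pct is not None and not hit.target_cov_pct > self.min_target_cov_pct:
            return False
        return True

    def fails_only_query_cov(self, hit: AlignmentHit) -> bool:
        """True when the hit would pass every criterion except query coverage."""
        if self.min_query_cov_pct is None:
            return False
        relaxed = FilterSpec(
            self.min_identity_pct, self.min_match_length, None, self.min_target_cov_pct
        )
        return relaxed.passes(hit) and not hit.query_cov_pct > self.min_query_cov_pct


# paper-style default cut-offs per survey stage
TRANSLATED_SURVEY_FILTER = FilterSpec(min_identity_pct=30, min_match_length=55)
RECRUITMENT_FILTER = FilterSpec(min_identity_pct=95, min_query_cov_pct=50)
SSU_SURVEY_FILTER = FilterSpec(min_identity_pct=70, min_target_cov_pct=90)
PHYCODNA_SURVEY_FILTER = FilterSpec(min_identity_pct=30, min_target_cov_pct=90)
GENE_CONTENT_FILTER = FilterSpec(min_identity_pct=30, min_query_cov_pct=50)


# -- translation -------------------------------------------------------------


def six_frame_translate(read: SequenceRecord) -> list[tuple[int, SequenceRecord]]:
    """All six reading frames of a nucleotide read; stops rendered '*'.

    Frames +1..+3 start at offsets 0..2 of the forward strand, -1..-3 at
    offsets 0..2 of the reverse complement. Reads shorter than one codon
    yield the empty list.
    """
    if read.alphabet != NUCLEOTIDE:
        raise ParameterError(f"six_frame_translate: {read.id!r} is not nucleotide")
    if len(read) < 3:
        return []
    out = []
    for strand_sign, seq in ((1, read.residues), (-1, revcomp(read.residues))):
        for off in range(3):
            n = (len(seq) - off) // 3
            if n == 0:
                continue
            pep = str(Seq(seq[off : off + 3 * n]).translate())
            frame = strand_sign * (off + 1)
            out.append(
                (
                    frame,
                    SequenceRecord(
                        id=f"{read.id}|frame{frame:+d}",
                        residues=pep,
                        description=f"frame={frame:+d};",
                        alphabet=PROTEIN,
                    ),
                )
            )
    return out


# -- core pairwise alignment -------------------------------------------------


def align_local(
    query: SequenceRecord | str,
    target: SequenceRecord | str,
    scoring: Scoring,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment of two same-alphabet sequences.

    Returns None when no alignment scores above zero. Identity is counted
    over all alignment columns including gaps.
    """
    q = query.residues if isinstance(query, SequenceRecord) else query
    t = target.residues if isinstance(target, SequenceRecord) else target
    if isinstance(query, SequenceRecord):
        query_id = query.id
    if isinstance(target, SequenceRecord):
        target_id = target.id
    if not q or not t:
        raise ParameterError("align_local: empty sequence")
    aligner = scoring.aligner()
    alignments = aligner.align(q, t)
    # score, not len(): enumerating co-optimal paths can be combinatorial
    if alignments.score <= 0:
        return None
    return _hit_from_alignment(alignments[0], q, t, query_id, target_id)


def _hit_from_alignment(aln, q: str, t: str, query_id: str, target_id: str) -> AlignmentHit:
    blocks_q, blocks_t = aln.aligned
    qs, qe = int(blocks_q[0][0]), int(blocks_q[-1][1])
    ts, te = int(blocks_t[0][0]), int(blocks_t[-1][1])
    identities = 0
    pairs = 0
    for (q0, q1), (t0, t1) in zip(blocks_q, blocks_t):
        pairs += q1 - q0
        identities += sum(a == b for a, b in zip(q[q0:q1], t[t0:t1]))
    gap_cols = (qe - qs - pairs) + (te - ts - pairs)
    gap_opens = 0
    for i in range(1, len(blocks_q)):
        if blocks_q[i][0] > blocks_q[i - 1][1]:
            gap_opens += 1
        if blocks_t[i][0] > blocks_t[i - 1][1]:
            gap_opens += 1
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        score=float(aln.score),
        identities=identities,
        mismatches=pairs - identities,
        gap_opens=gap_opens,
        aligned_length=pairs + gap_cols,
        query_start=qs,
        query_end=qe,
        target_start=ts,
        target_end=te,
        query_length=len(q),
        target_length=len(t),
    )


def _align_both_strands(
    read: SequenceRecord, target: SequenceRecord, scoring: Scoring
) -> AlignmentHit | None:
    """Best nucleotide local alignment over both read strands.

    Query coordinates are reported on the forward read; ties prefer '+'.
    """
    fwd = align_local(read, target, scoring)
    rc_seq = revcomp(read.residues)
    rc = align_local(rc_seq, target.residues, scoring, read.id, target.id)
    if rc is not None:
        L = len(read)
        rc.query_start, rc.query_end = L - rc.query_end, L - rc.query_start
        rc.strand = "-"
    if fwd is None:
        return rc
    if rc is None or fwd.score >= rc.score:
        return fwd
    return rc


# -- seeded recruitment engine ----------------------------------------------


class _SeedIndex:
    """Exact k-mer index over contigs for recruitment candidate finding."""

    def __init__(self, contigs: Sequence[SequenceRecord], k: int = 15):
        self.k = k
        self.contigs = list(contigs)
        self.arrays = [np.frombuffer(c.residues.encode(), dtype=np.uint8) for c in contigs]
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ci, contig in enumerate(contigs):
            s = contig.residues
            for pos in range(len(s) - k + 1):
                self.index[s[pos : pos + k]].append((ci, pos))

    def candidate_diagonals(self, seq: str, stride: int = 3) -> dict[int, dict[int, int]]:
        """contig index -> {diagonal: seed count}; diagonal = target_pos - query_pos."""
        k = self.k
        cands: dict[int, dict[int, int]] = defaultdict(lambda: defaultdict(int))
        for qpos in range(0, len(seq) - k + 1, stride):
            for ci, tpos in self.index.get(seq[qpos : qpos + k], ()):
                cands[ci][tpos - qpos] += 1
        return cands


def _gapless_extend(
    read_arr: np.ndarray, target_arr: np.ndarray, diag: int, match: float, mismatch: float
) -> tuple[float, int, int] | None:
    """Optimal ungapped local alignment on one diagonal (max-sum subarray).

    Returns (score, query_start, query_end) or None if nothing positive.
    """
    q0 = max(0, -diag)
    q1 = min(len(read_arr), len(target_arr) - diag)
    if q1 <= q0:
        return None
    eq = read_arr[q0:q1] == target_arr[q0 + diag : q1 + diag]
    col = np.where(eq, match, mismatch)
    best = 0.0
    best_span = None
    run = 0.0
    run_start = 0
    for i, v in enumerate(col):
        run += v
        if run <= 0:
            run = 0.0
            run_start = i + 1
        elif run > best:
            best = run
            best_span = (run_start, i + 1)
    if best_span is None:
        return None
    return best, q0 + best_span[0], q0 + best_span[1]


def _seeded_read_hits(
    read: SequenceRecord,
    index: _SeedIndex,
    scoring: Scoring,
    filter: FilterSpec,
    window_pad: int = 60,
) -> list[AlignmentHit]:
    """Per-contig best hit for one read via seeded gapless extension.

    When the gapless hit misses the identity cut-off by less than 5 points
    the read is realigned with full windowed dynamic programming, so indel
    divergence degrades gracefully rather than silently.
    """
    L = len(read)
    hits: dict[int, AlignmentHit] = {}
    for strand, seq in (("+", read.residues), ("-", revcomp(read.residues))):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for ci, diags in index.candidate_diagonals(seq).items():
            diag = max(diags, key=lambda d: (diags[d], -d))
            res = _gapless_extend(arr, index.arrays[ci], diag, scoring.match, scoring.mismatch)
            if res is None:
                continue
            score, q0, q1 = res
            tgt = index.contigs[ci]
            eq = arr[q0:q1] == index.arrays[ci][q0 + diag : q1 + diag]
            identities = int(eq.sum())
            hit = AlignmentHit(
                query_id=read.id,
                target_id=tgt.id,
                score=float(score),
                identities=identities,
                mismatches=(q1 - q0) - identities,
                gap_opens=0,
                aligned_length=q1 - q0,
                query_start=q0 if strand == "+" else L - q1,
                query_end=q1 if strand == "+" else L - q0,
                target_start=q0 + diag,
                target_end=q1 + diag,
                query_length=L,
                target_length=len(tgt),
                strand=strand,
            )
            near_miss = (
                filter.min_identity_pct is not None
                and not hit.identity_pct > filter.min_identity_pct
                and hit.identity_pct > filter.min_identity_pct - 5
            )
            if near_miss or len(diags) > 1 and max(diags.values()) < 3:
                refined = _windowed_realign(read, seq, strand, tgt, diag, scoring, window_pad)
                if refined is not None and refined.score > hit.score:
                    hit = refined
            prev = hits.get(ci)
            if prev is None or (hit.score, hit.identity_pct, hit.strand == "+") > (
                prev.score,
                prev.identity_pct,
                prev.strand == "+",
            ):
                hits[ci] = hit
    return [hits[ci] for ci in sorted(hits, key=lambda ci: index.contigs[ci].id)]


def _windowed_realign(
    read: SequenceRecord,
    oriented_seq: str,
    strand: str,
    target: SequenceRecord,
    diag: int,
    scoring: Scoring,
    pad: int,
) -> AlignmentHit | None:
    lo = max(0, diag - pad)
    hi = min(len(target), diag + len(read) + pad)
    window = target.residues[lo:hi]
    hit = align_local(oriented_seq, window, scoring, read.id, target.id)
    if hit is None:
        return None
    hit.target_start += lo
    hit.target_end += lo
    hit.target_length = len(target)
    if strand == "-":
        L = len(read)
        hit.query_start, hit.query_end = L - hit.query_end, L - hit.query_start
        hit.strand = "-"
    return hit


@dataclass
class RecruitmentResult:
    """Recruited hits plus sub-threshold secondary alignments kept as
    contig-link evidence (hits failing only the query-coverage criterion)."""

    hits: list[AlignmentHit]
    link_evidence: list[AlignmentHit]

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def all_alignments(self) -> list[AlignmentHit]:
        return self.hits + self.link_evidence


def recruit_reads(
    reads: Iterable[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    filter: FilterSpec = RECRUITMENT_FILTER,
    method: str = "seeded",
    k: int = 15,
) -> RecruitmentResult:
    """Recruit reads to contigs at stringent nucleotide identity.

    Per (read, contig) only the top-scoring alignment is kept, but a read
    may retain hits to several distinct contigs — contig linking depends on
    reads that map to two contigs at once. Alignments that pass every
    criterion except query coverage are returned separately as link
    evidence rather than discarded.
    """
    contigs = list(contigs)
    scoring = NUCLEOTIDE_SCORING
    raw: list[AlignmentHit] = []
    if method == "seeded":
        index = _SeedIndex(contigs, k=k)
        for read in reads:
            raw.extend(_seeded_read_hits(read, index, scoring, filter))
    elif method == "exact":
        for read in reads:
            for contig in contigs:
                hit = _align_both_strands(read, contig, scoring)
                if hit is not None:
                    raw.append(hit)
    else:
        raise ParameterError(f"unknown recruitment method {method!r}")
    hits = [h for h in raw if filter.passes(h)]
    evidence = [h for h in raw if filter.fails_only_query_cov(h)]
    key = lambda h: (h.query_id, h.target_id)
    return RecruitmentResult(sorted(hits, key=key), sorted(evidence, key=key))


# -- survey searches ---------------------------------------------------------


def _block_targets(block: ConservedBlock | Sequence[SequenceRecord]) -> list[SequenceRecord]:
    if isinstance(block, ConservedBlock):
        return [
            SequenceRecord(id=rid, residues=seq, alphabet=PROTEIN)
            for rid, seq in block.block_sequences.items()
            if seq
        ]
    return list(block)


def search_reads_translated(
    reads: Iterable[SequenceRecord],
    block: ConservedBlock | Sequence[SequenceRecord],
    filter: FilterSpec = TRANSLATED_SURVEY_FILTER,
) -> list[AlignmentHit]:
    """Six-frame translated screening of reads against the marker block.

    Every read-frame x block-row alignment is computed; hits must clear the
    identity and match-length cut-offs (strict >), then one best hit per
    read is kept. Ordering is deterministic (query id, then target id).
    """
    targets = _block_targets(block)
    if not targets:
        raise ParameterError("search_reads_translated: block has no sequences")
    kept: list[AlignmentHit] = []
    for read in reads:
        for frame, pep in six_frame_translate(read):
            for tgt in targets:
                hit = align_local(pep.residues, tgt.residues, PROTEIN_SCORING, read.id, tgt.id)
                if hit is None:
                    continue
                hit.frame = frame
                hit.strand = "+" if frame > 0 else "-"
                if filter.passes(hit):
                    kept.append(hit)
    return best_hit_per_read(kept)


def survey_translated_block(
    reads: Iterable[SequenceRecord],
    block: ConservedBlock | Sequence[SequenceRecord],
    filter: FilterSpec = PHYCODNA_SURVEY_FILTER,
) -> list[AlignmentHit]:
    """Translated survey with a target-coverage criterion (block mostly aligned)."""
    return search_reads_translated(reads, block, filter)


def survey_nucleotide(
    reads: Iterable[SequenceRecord],
    targets: Sequence[SequenceRecord],
    filter: FilterSpec = SSU_SURVEY_FILTER,
) -> list[AlignmentHit]:
    """Nucleotide survey of reads against short marker targets (V9 scale).

    Both strands are aligned; hits clear identity and target-coverage
    cut-offs; one best hit per read.
    """
    kept = []
    for read in reads:
        for tgt in targets:
            hit = _align_both_strands(read, tgt, NUCLEOTIDE_SCORING)
            if hit is not None and filter.passes(hit):
                kept.append(hit)
    return best_hit_per_read(kept)


def best_hit_per_read(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the single best hit per query.

    Ties break by higher identity, then lexicographically smaller target id,
    then lowest frame index (+1,+2,+3,-1,-2,-3). Deterministic.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return [best[q] for q in sorted(best)]


def _hit_rank(h: AlignmentHit):
    frame_idx = FRAME_ORDER.get(h.frame, 0 if h.strand == "+" else 1)
    return (-h.score, -h.identity_pct, h.target_id, frame_idx)


# -- tabular output ----------------------------------------------------------

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "score", "qcov",
]


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """12-column tabular hits; coordinates converted to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TABULAR_COLUMNS) + "\n")
        for h in hits:
            if h.strand == "-" and h.frame is None:
                sstart, send = h.target_end, h.target_start + 1
            else:
                sstart, send = h.target_start + 1, h.target_end
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.target_id, f"{h.identity_pct:.2f}", h.aligned_length,
                        h.mismatches, h.gap_opens, h.query_start + 1, h.query_end,
                        sstart, send, f"{h.score:g}", f"{h.query_cov_pct:.1f}",
                    )
                )
                + "\n"
            )
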