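"""Genome annotation and gene-content comparison.

A deterministic longest-ORF caller (start-to-stop on both strands, with
wrap-around on circular replicons) stands in for heuristic-model gene
predictors; gene content against reference virophage proteomes is counted
by reciprocal best hit under identity/coverage cut-offs, and genomes are
summarized against the virophage envelope (17-28 kbp, 26-38% G+C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .errors import ParameterError
from .homology_search import (
    GENE_CONTENT_FILTER,
    AlignmentHit,
    FilterSpec,
    PROTEIN_SCORING,
    align_local,
)
from .records import PROTEIN, SequenceRecord, revcomp

VIROPHAGE_SIZE_RANGE = (17_000, 28_000)  # bp
VIROPHAGE_GC_RANGE = (26.0, 38.0)  # percent


@dataclass
class OrfRecord:
    """One predicted ORF; 0-based half-open forward coordinates.

    ``end > genome length`` marks an ORF wrapping the origin of a circular
    genome. The peptide excludes the stop codon; the interval includes it
    when present.
    """

    id: str
    start: int
    end: int
    strand: str
    peptide: str
    has_stop: bool = True

    @property
    def length_aa(self) -> int:
        return len(self.peptide)


def find_orfs(
    genome: SequenceRecord,
    min_length_aa: int = 60,
    circular: bool | None = None,
    strict_start: bool = True,
) -> list[OrfRecord]:
    """All maximal ORFs on both strands, sorted by start position.

    Stop-to-stop frames are scanned; under ``strict_start`` an ORF runs from
    the first ATG of a frame segment to its stop, otherwise the whole
    stop-bounded segment counts. Circular genomes are scanned on their
    doubled sequence so origin-spanning ORFs are recovered exactly once.
    """
    if circular is None:
        circular = genome.topology == "circular"
    seq = genome.residues
    L = len(seq)
    found: dict[tuple[str, int, int], OrfRecord] = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        work = s + s if circular else s
        for off in range(3):
            n_codons = (len(work) - off) // 3
            if n_codons == 0:
                continue
            pep = str(Seq(work[off : off + 3 * n_codons]).translate())
            for a0, a1, terminated in _segments(pep):
                if circular and not terminated:
                    continue  # doubled-sequence tail; the wrapped copy was seen already
                if strict_start:
                    m = pep.find("M", a0, a1)
                    if m == -1:
                        continue
                    a0 = m
                peptide = pep[a0:a1]
                if len(peptide) < min_length_aa:
                    continue
                nt_start = off + 3 * a0
                nt_end = off + 3 * a1 + (3 if terminated else 0)
                span = nt_end - nt_start
                if circular and (nt_start >= L or span > L):
                    continue
                if strand == "+":
                    f_start = nt_start
                else:
                    f_start = (L - (nt_end % L)) % L
                key = (strand, f_start % L, span)
                if key not in found:
                    found[key] = OrfRecord(
                        id="",
                        start=f_start,
                        end=f_start + span,
                        strand=strand,
                        peptide=peptide,
                        has_stop=terminated,
                    )
    orfs = sorted(found.values(), key=lambda o: (o.start, o.strand, o.end))
    for i, orf in enumerate(orfs):
        orf.id = f"orf_{i + 1:04d}"
    return orfs


def _segments(pep: str) -> list[tuple[int, int, bool]]:
    """Maximal stop-free runs as (start, end, ends_with_stop)."""
    out = []
    start = 0
    for i, aa in enumerate(pep):
        if aa == "*":
            if i > start:
                out.append((start, i, True))
            start = i + 1
    if start < len(pep):
        out.append((start, len(pep), False))
    return out


def gc_content(seq: str | SequenceRecord) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both terms."""
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ParameterError("sequence has no unambiguous bases")
    return (s.count("G") + s.count("C")) / acgt


# -- gene content ------------------------------------------------------------


@dataclass
class GeneContentReport:
    """Reciprocal-best-hit homologue pairing against one reference proteome."""

    reference_name: str
    pairs: list[tuple[str, str, float]]  # (orf id, reference id, identity pct)
    specific_orfs: list[str]  # ORFs with no hit passing the filter
    per_orf_best: dict[str, AlignmentHit]

    @property
    def shared_homologue_count(self) -> int:
        return len(self.pairs)

    @property
    def mean_identity_pct(self) -> float:
        if not self.pairs:
            return 0.0
        return sum(p[2] for p in self.pairs) / len(self.pairs)


def compare_gene_content(
    orf_peptides: Sequence[SequenceRecord],
    reference_proteome: Sequence[SequenceRecord],
    filter: FilterSpec = GENE_CONTENT_FILTER,
    reference_name: str = "reference",
) -> GeneContentReport:
    """Shared gene homologues by reciprocal best hit under the filter.

    Each ORF is aligned to every reference protein (ORF as query, so the
    query-coverage cut-off measures how much of the ORF aligns); a pair
    counts when each member is the other's top-scoring passing hit. ORFs
    with no passing hit at all are reported as specific. Mean identity is
    the unweighted mean over homologue pairs.
    """
    if not orf_peptides or not reference_proteome:
        raise ParameterError("compare_gene_content: both protein sets must be non-empty")
    passing: dict[tuple[str, str], AlignmentHit] = {}
    for orf in orf_peptides:
        for ref in reference_proteome:
            hit = align_local(orf, ref, PROTEIN_SCORING)
            if hit is not None and filter.passes(hit):
                passing[(orf.id, ref.id)] = hit
    rank = lambda h: (-h.score, -h.identity_pct)
    best_for_orf: dict[str, AlignmentHit] = {}
    best_for_ref: dict[str, AlignmentHit] = {}
    for (oid, rid), hit in sorted(passing.items()):
        if oid not in best_for_orf or rank(hit) < rank(best_for_orf[oid]):
            best_for_orf[oid] = hit
        if rid not in best_for_ref or rank(hit) < rank(best_for_ref[rid]):
            best_for_ref[rid] = hit
    pairs = []
    for oid, hit in sorted(best_for_orf.items()):
        rid = hit.target_id
        mutual = best_for_ref.get(rid)
        if mutual is not None and mutual.query_id == oid:
            pairs.append((oid, rid, hit.identity_pct))
    specific = sorted(o.id for o in orf_peptides if o.id not in best_for_orf)
    return GeneContentReport(reference_name, pairs, specific, best_for_orf)


@dataclass
class CoreGeneLabels:
    labels: dict[str, str]  # orf id -> core-gene label
    unclassified: bool
    notes: list[str] = field(default_factory=list)


def classify_core_genes(
    report: GeneContentReport, core_labels: dict[str, str]
) -> CoreGeneLabels:
    """Propagate core-gene labels from best reference hits onto ORFs.

    The major capsid protein is single-copy: if several ORFs inherit the
    MCP label, only the highest-identity one keeps it (with a warning).
    A genome with no core hits at all is flagged unclassified.
    """
    labels: dict[str, str] = {}
    for oid, hit in report.per_orf_best.items():
        label = core_labels.get(hit.target_id)
        if label is not None:
            labels[oid] = label
    notes: list[str] = []
    mcp_orfs = [o for o, lab in labels.items() if lab == "MCP"]
    if len(mcp_orfs) > 1:
        keep = max(mcp_orfs, key=lambda o: report.per_orf_best[o].identity_pct)
        for o in mcp_orfs:
            if o != keep:
                del labels[o]
        msg = f"multiple MCP-like ORFs {mcp_orfs}; keeping highest-identity {keep}"
        notes.append(msg)
        warnings.warn(msg)
    return CoreGeneLabels(labels=labels, unclassified=not labels, notes=notes)


def genome_summary(genome: SequenceRecord, orfs: Sequence[OrfRecord]) -> dict:
    """Length, G+C, ORF count, coding fraction, and virophage-envelope flags."""
    L = len(genome)
    gc_pct = 100.0 * gc_content(genome)
    covered = set()
    for orf in orfs:
        for p in range(orf.start, orf.end):
            covered.add(p % L)
    return {
        "genome_id": genome.id,
        "length_bp": L,
        "gc_pct": gc_pct,
        "n_orfs": len(orfs),
        "coding_fraction": len(covered) / L if L else 0.0,
        "size_in_virophage_range": VIROPHAGE_SIZE_RANGE[0] <= L <= VIROPHAGE_SIZE_RANGE[1],
        "gc_in_virophage_range": VIROPHAGE_GC_RANGE[0] <= gc_pct <= VIROPHAGE_GC_RANGE[1],
    }


# -- exports -----------------------------------------------------------------


def orf_peptide_records(orfs: Sequence[OrfRecord]) -> list[SequenceRecord]:
    return [
        SequenceRecord(
            id=o.id,
            residues=o.peptide,
            description=f"start={o.start};end={o.end};strand={o.strand};",
            alphabet=PROTEIN,
        )
        for o in orfs
    ]


def write_gff3(
    genome: SequenceRecord, orfs: Sequence[OrfRecord], path: str | Path
) -> None:
    """GFF3 CDS features, 1-based inclusive; circular genomes declare
    Is_circular=true and origin-spanning features use end > region length."""
    L = len(genome)
    circular = genome.topology == "circular"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        attrs = f"ID={genome.id}" + (";Is_circular=true" if circular else "")
        fh.write(f"{genome.id}\tviroseek\tregion\t1\t{L}\t.\t+\t.\t{attrs}\n")
        for o in orfs:
            fh.write(
                f"{genome.id}\tviroseek\tCDS\t{o.start + 1}\t{o.end}\t.\t{o.strand}\t0\t"
                f"ID={o.id};length_aa={o.length_aa}\n"
            )


def write_gene_content_tsv(reports: Sequence[GeneContentReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reference\tshared_homologues\tmean_identity_pct\tspecific_orfs\n")
        for r in reports:
            fh.write(
                f"{r.reference_name}\t{r.shared_homologue_count}"
                f"\t{r.mean_identity_pct:.1f}\t{','.join(r.specific_orfs) or '-'}\n"
            )
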