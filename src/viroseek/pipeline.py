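"""Workflow orchestration: marker survey, genome reconstruction, host survey.

The three entry points mirror how a virophage-discovery study proceeds:

1. :func:`run_marker_survey` — screen translated reads against the
   conserved capsid-protein block and report per-dataset counts plus a
   pairwise identity matrix of the hit peptides (input for external tree
   building).
2. :func:`run_reconstruction` — find the MCP-encoding contig, recruit
   reads, link and chain contigs, merge, test circularity, canonicalize,
   and characterize the population (coverage, identity histogram,
   species-demarcation call) and the genome (ORFs, G+C, summary).
3. :func:`run_host_survey` — SSU rRNA V9 and phycodnavirus-MCP-block
   surveys for candidate eukaryotic and giant-virus hosts.

Every threshold actually applied is logged with its stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_survey import OrfRecord, find_orfs, genome_summary, orf_peptide_records
from .errors import NoVirophageSignal, ParameterError
from .genome_reconstruction import (
    ContigGraph,
    ContigPath,
    CoverageProfile,
    IdentityHistogram,
    PopulationCall,
    build_link_graph,
    call_population,
    canonical_rotation,
    chain_contigs,
    coverage_profile,
    detect_circularity,
    identity_histogram,
    merge_path,
)
from .homology_search import (
    GENE_CONTENT_FILTER,
    PHYCODNA_SURVEY_FILTER,
    RECRUITMENT_FILTER,
    SSU_SURVEY_FILTER,
    TRANSLATED_SURVEY_FILTER,
    AlignmentHit,
    FilterSpec,
    PROTEIN_SCORING,
    align_local,
    best_hit_per_read,
    recruit_reads,
    search_reads_translated,
    six_frame_translate,
    survey_nucleotide,
    survey_translated_block,
)
from .marker_block import ConservedBlock
from .records import SequenceRecord, revcomp

log = logging.getLogger("viroseek")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage cut-offs and reconstruction parameters with survey defaults."""

    translated_survey: FilterSpec = TRANSLATED_SURVEY_FILTER
    recruitment: FilterSpec = RECRUITMENT_FILTER
    ssu_survey: FilterSpec = SSU_SURVEY_FILTER
    phycodna_survey: FilterSpec = PHYCODNA_SURVEY_FILTER
    gene_content: FilterSpec = GENE_CONTENT_FILTER
    min_support: int = 2
    max_query_overlap: int = 10
    end_slack: int = 10
    min_junction_overlap: int = 20
    probe_arm: int | None = None
    min_orf_length_aa: int = 60
    rng_seed: int = 0

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        """Load from YAML (JSON accepted — it is a YAML subset)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for stage in ("translated_survey", "recruitment", "ssu_survey",
                      "phycodna_survey", "gene_content"):
            if stage in raw:
                kwargs[stage] = FilterSpec(**raw[stage])
        for key in ("min_support", "max_query_overlap", "end_slack",
                    "min_junction_overlap", "probe_arm", "min_orf_length_aa", "rng_seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return PipelineConfig(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def echo(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _log_filter(stage: str, spec: FilterSpec) -> None:
    log.info(
        "stage=%s min_identity_pct=%s min_match_length=%s "
        "min_query_cov_pct=%s min_target_cov_pct=%s",
        stage, spec.min_identity_pct, spec.min_match_length,
        spec.min_query_cov_pct, spec.min_target_cov_pct,
    )


# -- marker survey -----------------------------------------------------------


@dataclass
class MarkerSurveyReport:
    counts: dict[str, int]  # dataset -> surviving read count
    hits: dict[str, list[AlignmentHit]]
    identity_matrix: pd.DataFrame  # pairwise identities of hit peptides

    @property
    def total_hits(self) -> int:
        return sum(self.counts.values())


def hit_peptide(read: SequenceRecord, hit: AlignmentHit) -> str:
    """The translated read segment a translated hit aligned (query side)."""
    if hit.frame is None:
        raise ParameterError("hit has no frame; not a translated hit")
    for frame, pep in six_frame_translate(read):
        if frame == hit.frame:
            return pep.residues[hit.query_start : hit.query_end]
    raise ParameterError(f"frame {hit.frame} unavailable for read {read.id!r}")


def run_marker_survey(
    datasets: Mapping[str, Sequence[SequenceRecord]],
    block: ConservedBlock,
    config: PipelineConfig = PipelineConfig(),
) -> MarkerSurveyReport:
    """Translated marker-block screening over one or more read datasets.

    Datasets with zero hits are reported as zero, not as errors. The
    identity matrix covers all hit peptides across datasets.
    """
    _log_filter("translated_survey", config.translated_survey)
    counts: dict[str, int] = {}
    all_hits: dict[str, list[AlignmentHit]] = {}
    peptides: dict[str, str] = {}
    for name in sorted(datasets):
        reads = list(datasets[name])
        hits = search_reads_translated(reads, block, config.translated_survey)
        counts[name] = len(hits)
        all_hits[name] = hits
        by_id = {r.id: r for r in reads}
        for h in hits:
            peptides[h.query_id] = hit_peptide(by_id[h.query_id], h)
    ids = sorted(peptides)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            hit = align_local(peptides[a], peptides[b], PROTEIN_SCORING)
            ident = hit.identity_pct if hit is not None else 0.0
            mat.loc[a, b] = mat.loc[b, a] = ident
    return MarkerSurveyReport(counts, all_hits, mat)


# -- reconstruction ----------------------------------------------------------


@dataclass
class ReconstructionReport:
    mcp_contig_id: str
    path: ContigPath
    graph: ContigGraph
    genome: SequenceRecord  # canonical rotation, circular when confirmed
    is_circular: bool
    coverage: CoverageProfile
    contig_coverage: dict[str, CoverageProfile]
    histogram: IdentityHistogram
    population: PopulationCall
    orfs: list[OrfRecord]
    summary: dict

    def to_dict(self) -> dict:
        return {
            "mcp_contig": self.mcp_contig_id,
            "contig_path": [f"{c}{o}" for c, o in self.path.steps],
            "is_circular": self.is_circular,
            "genome_length_bp": len(self.genome),
            "n_recruited_reads": int(len(self.histogram.identities)),
            "coverage_mean": self.coverage.mean,
            "coverage_min": self.coverage.min,
            "coverage_max": self.coverage.max,
            "mean_identity_pct": self.population.mean_identity_pct,
            "intrapop_variation_pct": self.population.intrapop_variation_pct,
            "band_fraction_96_100": self.population.band_fraction_96_100,
            "verdict": self.population.verdict,
            "n_orfs": len(self.orfs),
            "summary": {k: (float(v) if isinstance(v, np.floating) else v)
                        for k, v in self.summary.items()},
        }


def _find_marker_orf(
    contig: SequenceRecord,
    block: ConservedBlock,
    filter: FilterSpec,
    min_orf_length_aa: int,
    circular: bool = False,
) -> tuple[OrfRecord, AlignmentHit] | None:
    """Best marker-block hit among the contig's ORFs, or None."""
    orfs = find_orfs(contig, min_length_aa=min_orf_length_aa, circular=circular)
    best: tuple[OrfRecord, AlignmentHit] | None = None
    targets = [
        SequenceRecord(id=rid, residues=seq, alphabet="protein")
        for rid, seq in block.block_sequences.items()
        if seq
    ]
    for orf in orfs:
        for tgt in targets:
            hit = align_local(orf.peptide, tgt.residues, PROTEIN_SCORING, orf.id, tgt.id)
            if hit is None or not filter.passes(hit):
                continue
            if best is None or hit.score > best[1].score:
                best = (orf, hit)
    return best


def run_reconstruction(
    reads: Sequence[SequenceRecord],
    contigs: Sequence[SequenceRecord],
    block: ConservedBlock,
    config: PipelineConfig = PipelineConfig(),
) -> ReconstructionReport:
    """Reconstruct and characterize a circular virophage genome.

    Raises :class:`NoVirophageSignal` when no contig encodes the marker
    block; chain ambiguities propagate with diagnostics.
    """
    _log_filter("translated_survey(contig ORFs)", config.translated_survey)
    mcp_contig = None
    mcp_best = None
    for contig in contigs:
        found = _find_marker_orf(
            contig, block, config.translated_survey, config.min_orf_length_aa
        )
        if found and (mcp_best is None or found[1].score > mcp_best[1].score):
            mcp_contig, mcp_best = contig, found
    if mcp_contig is None:
        raise NoVirophageSignal("no contig ORF matches the marker block")
    log.info("stage=mcp_contig contig=%s orf=%s", mcp_contig.id, mcp_best[0].id)

    _log_filter("recruitment", config.recruitment)
    recruitment = recruit_reads(reads, contigs, config.recruitment)
    contig_cov = {
        c.id: coverage_profile([h for h in recruitment.hits if h.target_id == c.id], c)
        for c in contigs
    }
    graph = build_link_graph(
        contigs,
        recruitment.all_alignments(),
        reads=reads,
        min_support=config.min_support,
        max_query_overlap=config.max_query_overlap,
        end_slack=config.end_slack,
    )
    log.info("stage=link_graph min_support=%d edges=%d", config.min_support, len(graph.edges))
    paths = chain_contigs(graph, anchor=mcp_contig.id)
    path = next(p for p in paths if any(c == mcp_contig.id for c, _ in p.steps))
    merged = merge_path(path, contigs, graph)

    linear_view = replace(merged, topology="linear")
    is_circular, junction = detect_circularity(
        linear_view,
        reads,
        filter=config.recruitment,
        min_junction_overlap=config.min_junction_overlap,
        min_support=config.min_support,
        probe_arm=config.probe_arm,
    )
    log.info(
        "stage=circularity min_junction_overlap=%d min_support=%d result=%s",
        config.min_junction_overlap, config.min_support, is_circular,
    )
    is_circular = is_circular or path.is_cycle
    genome = replace(merged, topology="circular" if is_circular else "linear")

    # canonical form anchored at the marker ORF when circular
    if is_circular:
        anchor = _find_marker_orf(
            genome, block, config.translated_survey, config.min_orf_length_aa, circular=True
        )
        if anchor is not None:
            orf = anchor[0]
            if orf.strand == "-":
                L = len(genome)
                genome = replace(genome, residues=revcomp(genome.residues))
                orf_start = (L - orf.end % L) % L
            else:
                orf_start = orf.start
            genome = canonical_rotation(genome, anchor_orf_start=orf_start)
        else:
            genome = canonical_rotation(genome)

    final_recruitment = recruit_reads(reads, [genome], config.recruitment)
    coverage = coverage_profile(final_recruitment.hits, genome)
    hist = identity_histogram(final_recruitment.hits)
    population = call_population(hist)
    orfs = find_orfs(genome, min_length_aa=config.min_orf_length_aa, circular=is_circular)
    summary = genome_summary(genome, orfs)
    return ReconstructionReport(
        mcp_contig_id=mcp_contig.id,
        path=path,
        graph=graph,
        genome=genome,
        is_circular=is_circular,
        coverage=coverage,
        contig_coverage=contig_cov,
        histogram=hist,
        population=population,
        orfs=orfs,
        summary=summary,
    )


# -- host survey -------------------------------------------------------------


@dataclass
class HostSurveyReport:
    ssu_hits: list[AlignmentHit]
    ssu_counts_by_taxon: dict[str, int]
    phycodna_hits: list[AlignmentHit]

    @property
    def phycodna_count(self) -> int:
        return len(self.phycodna_hits)


def _taxon_label(target_id: str) -> str:
    head, _, tail = target_id.rpartition("_")
    return head if head and tail.isdigit() else target_id


def run_host_survey(
    reads: Sequence[SequenceRecord],
    ssu_targets: Sequence[SequenceRecord],
    phycodna_block: ConservedBlock | Sequence[SequenceRecord] | None,
    config: PipelineConfig = PipelineConfig(),
) -> HostSurveyReport:
    """SSU V9 nucleotide survey plus translated phycodnavirus-block survey."""
    _log_filter("ssu_survey", config.ssu_survey)
    ssu_hits = survey_nucleotide(reads, ssu_targets, config.ssu_survey)
    counts: dict[str, int] = {}
    for h in ssu_hits:
        label = _taxon_label(h.target_id)
        counts[label] = counts.get(label, 0) + 1
    phyco_hits: list[AlignmentHit] = []
    if phycodna_block is not None:
        _log_filter("phycodna_survey", config.phycodna_survey)
        phyco_hits = survey_translated_block(reads, phycodna_block, config.phycodna_survey)
    return HostSurveyReport(ssu_hits, counts, phyco_hits)


# -- reporting ---------------------------------------------------------------


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
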