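"""Circular genome reconstruction from contigs plus recruited reads.

The reconstruction follows the read-recruitment logic of virophage genome
recovery: reads recruited at stringent identity that map simultaneously
onto two distinct contigs define links between contig ends; links with
enough read support form a graph whose unique chain (or cycle) orders and
orients the contigs; junction sequence is decided by majority vote over
the linking reads; terminal read overlap between the end and beginning of
the merged contig demonstrates circularity. Recruitment identities then
characterize the population: a narrow identity band near 100% and a mean
identity above the 90-95% species-demarcation band indicate a discrete,
species-like viral population whose intrapopulation variation is
100 - mean identity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AmbiguityError, ConsistencyError, MergeError, ParameterError
from .homology_search import (
    RECRUITMENT_FILTER,
    AlignmentHit,
    FilterSpec,
    RecruitmentResult,
    recruit_reads,
)
from .records import NUCLEOTIDE, SequenceRecord, revcomp

HEAD, TAIL = "head", "tail"
Port = tuple[str, str]  # (contig id, 'head' | 'tail')


# -- coverage ----------------------------------------------------------------


@dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray  # per-base integer coverage

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def min(self) -> int:
        return int(self.depth.min()) if len(self.depth) else 0

    @property
    def max(self) -> int:
        return int(self.depth.max()) if len(self.depth) else 0


def coverage_profile(hits: Iterable[AlignmentHit], contig: SequenceRecord) -> CoverageProfile:
    """Per-base depth from hit target intervals on one contig."""
    L = len(contig)
    diff = np.zeros(L + 1, dtype=np.int64)
    for h in hits:
        if h.target_id != contig.id:
            raise ConsistencyError(f"hit {h.query_id!r} targets {h.target_id!r}, not {contig.id!r}")
        if h.target_start < 0 or h.target_end > L or h.target_start > h.target_end:
            raise ConsistencyError(
                f"hit {h.query_id!r} interval [{h.target_start},{h.target_end}) outside {contig.id!r}"
            )
        diff[h.target_start] += 1
        diff[h.target_end] -= 1
    return CoverageProfile(contig.id, np.cumsum(diff[:-1]))


# -- link graph --------------------------------------------------------------


@dataclass
class LinkEdge:
    """A supported connection between two contig ends."""

    port_a: Port
    port_b: Port
    support: int
    link_read_ids: list[str]
    # junction inserts observed by linking reads, keyed by the port the read
    # leaves first, so merge_path can orient them
    inserts: list[tuple[Port, str]] = field(default_factory=list)

    def other(self, port: Port) -> Port:
        return self.port_b if port == self.port_a else self.port_a


@dataclass
class ContigGraph:
    nodes: dict[str, int]  # contig id -> length
    edges: list[LinkEdge]

    def edges_at(self, port: Port) -> list[LinkEdge]:
        return [e for e in self.edges if port in (e.port_a, e.port_b)]


def _junction_port(hit: AlignmentHit, read_extends: str) -> Port | None:
    """Which contig end a junction-crossing read runs off, or None.

    ``read_extends`` is 'right' when the read continues past the aligned
    query interval toward higher read coordinates, 'left' otherwise.
    """
    toward_tail = (read_extends == "right") == (hit.strand == "+")
    return (hit.target_id, TAIL if toward_tail else HEAD)


def build_link_graph(
    contigs: Sequence[SequenceRecord],
    hits: Iterable[AlignmentHit],
    reads: Sequence[SequenceRecord] | None = None,
    min_support: int = 2,
    max_query_overlap: int = 10,
    min_joint_query_cov: float = 0.9,
    end_slack: int = 10,
) -> ContigGraph:
    """Contig ends linked by reads that map onto two distinct contigs.

    A read links contigs A and B when its two alignments consume disjoint
    read intervals (overlap <= ``max_query_overlap``), jointly cover more
    than ``min_joint_query_cov`` of the read, and each alignment abuts its
    contig end within ``end_slack`` bases. Edges supported by fewer than
    ``min_support`` reads are dropped. Pass recruited hits *including*
    sub-threshold link evidence.
    """
    lengths = {c.id: len(c) for c in contigs}
    read_seqs = {r.id: r.residues for r in reads} if reads is not None else {}
    by_read: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_read[h.query_id].append(h)
    pending: dict[tuple[Port, Port], LinkEdge] = {}
    for read_id in sorted(by_read):
        read_hits = by_read[read_id]
        if len({h.target_id for h in read_hits}) < 2:
            continue
        read_hits.sort(key=lambda h: (h.query_start, h.target_id))
        for i, h1 in enumerate(read_hits):
            for h2 in read_hits[i + 1 :]:
                if h1.target_id == h2.target_id:
                    continue
                overlap = h1.query_end - h2.query_start
                if overlap > max_query_overlap:
                    continue
                joint = (h1.query_end - h1.query_start) + (h2.query_end - h2.query_start)
                joint -= max(0, overlap)
                if joint <= min_joint_query_cov * h1.query_length:
                    continue
                p1 = _junction_port(h1, "right")
                p2 = _junction_port(h2, "left")
                if not _abuts(h1, p1[1], lengths[h1.target_id], end_slack):
                    continue
                if not _abuts(h2, p2[1], lengths[h2.target_id], end_slack):
                    continue
                # read bases between the two alignments become the junction
                # insert candidate (empty when the alignments abut or overlap)
                gap_seq = ""
                if overlap < 0 and read_id in read_seqs:
                    gap_seq = read_seqs[read_id][h1.query_end : h2.query_start]
                key = tuple(sorted((p1, p2)))
                edge = pending.get(key)
                if edge is None:
                    edge = LinkEdge(key[0], key[1], 0, [])
                    pending[key] = edge
                edge.support += 1
                edge.link_read_ids.append(read_id)
                edge.inserts.append((p1, gap_seq))
    edges = [e for e in pending.values() if e.support >= min_support]
    edges.sort(key=lambda e: (e.port_a, e.port_b))
    return ContigGraph(nodes=dict(lengths), edges=edges)


def _abuts(hit: AlignmentHit, end: str, contig_len: int, slack: int) -> bool:
    if end == TAIL:
        return hit.target_end >= contig_len - slack
    return hit.target_start <= slack


# -- chaining ----------------------------------------------------------------


@dataclass
class ContigPath:
    """Ordered, oriented contigs; a cycle closes tail-to-head on itself."""

    steps: list[tuple[str, str]]  # (contig id, '+' | '-')
    is_cycle: bool


def chain_contigs(graph: ContigGraph, anchor: str | None = None) -> list[ContigPath]:
    """Maximal simple paths/cycles through the link graph.

    Every contig end may carry at most one edge; a branching end raises an
    ambiguity error naming the branch. Orientation propagates from the
    anchor contig ('+' by convention; default anchor = longest contig of
    each component).
    """
    port_edges: dict[Port, list[LinkEdge]] = defaultdict(list)
    for e in graph.edges:
        port_edges[e.port_a].append(e)
        port_edges[e.port_b].append(e)
    for port, edges in port_edges.items():
        if len(edges) > 1:
            raise AmbiguityError(
                f"contig end {port} has {len(edges)} links: "
                + "; ".join(f"{e.port_a}-{e.port_b} (support {e.support})" for e in edges)
            )
    # connected components over contigs
    seen: set[str] = set()
    paths: list[ContigPath] = []
    order = sorted(graph.nodes, key=lambda c: (-graph.nodes[c], c))
    if anchor is not None:
        if anchor not in graph.nodes:
            raise ParameterError(f"anchor contig {anchor!r} not in graph")
        order = [anchor] + [c for c in order if c != anchor]
    for start in order:
        if start in seen:
            continue
        component = _component(start, port_edges)
        seen |= component
        free_ports = [
            (c, e)
            for c in sorted(component)
            for e in (HEAD, TAIL)
            if not port_edges.get((c, e))
        ]
        is_cycle = not free_ports
        if is_cycle:
            first, entry = (start, HEAD)
        else:
            # prefer starting at the anchor if it has a free port
            anchored = [(c, e) for c, e in free_ports if c == start]
            first, entry = (anchored or free_ports)[0]
        steps = _walk(first, entry, port_edges, is_cycle)
        if anchor is not None and any(c == anchor for c, _ in steps):
            steps = _normalize_to_anchor(steps, anchor, is_cycle)
        paths.append(ContigPath(steps, is_cycle))
    return paths


def _component(start: str, port_edges: dict[Port, list[LinkEdge]]) -> set[str]:
    todo, out = [start], {start}
    while todo:
        c = todo.pop()
        for end in (HEAD, TAIL):
            for e in port_edges.get((c, end), []):
                nxt = e.other((c, end))[0]
                if nxt not in out:
                    out.add(nxt)
                    todo.append(nxt)
    return out


def _walk(
    contig: str, entry: str, port_edges: dict[Port, list[LinkEdge]], is_cycle: bool
) -> list[tuple[str, str]]:
    steps: list[tuple[str, str]] = []
    first = contig
    while True:
        orientation = "+" if entry == HEAD else "-"
        steps.append((contig, orientation))
        exit_port: Port = (contig, TAIL if entry == HEAD else HEAD)
        edges = port_edges.get(exit_port, [])
        if not edges:
            break
        nxt = edges[0].other(exit_port)
        if nxt[0] == first:
            if not is_cycle:
                raise AmbiguityError("walk returned to start of a non-cycle component")
            expected_entry = HEAD if steps[0][1] == "+" else TAIL
            if nxt[1] != expected_entry:
                raise AmbiguityError(
                    f"orientation conflict closing cycle at {first}: "
                    f"re-entry via {nxt[1]}, expected {expected_entry}"
                )
            break
        contig, entry = nxt[0], nxt[1]
    return steps


def _normalize_to_anchor(
    steps: list[tuple[str, str]], anchor: str, is_cycle: bool
) -> list[tuple[str, str]]:
    idx = next(i for i, (c, _) in enumerate(steps) if c == anchor)
    if is_cycle:
        steps = steps[idx:] + steps[:idx]
        idx = 0
    if steps[idx][1] == "-":
        steps = [(c, "+" if o == "-" else "-") for c, o in reversed(steps)]
        if is_cycle:
            idx = next(i for i, (c, _) in enumerate(steps) if c == anchor)
            steps = steps[idx:] + steps[:idx]
    return steps


# -- merging -----------------------------------------------------------------


def merge_path(
    path: ContigPath,
    contigs: Sequence[SequenceRecord],
    graph: ContigGraph | None = None,
    merged_id: str = "merged_genome",
) -> SequenceRecord:
    """Join consecutive contigs along the path into one record.

    Junction sequence between two contigs is the majority insert observed
    by the linking reads (per-column majority at equal lengths; the most
    common length otherwise, ties to the shorter). Contigs produced by an
    assembler that fractured a circle abut exactly, so the common case is
    an empty insert. A cyclic path yields a circular record.
    """
    by_id = {c.id: c for c in contigs}
    oriented = []
    for cid, orient in path.steps:
        if cid not in by_id:
            raise MergeError(f"contig {cid!r} missing from sequence set")
        seq = by_id[cid].residues
        oriented.append(seq if orient == "+" else revcomp(seq))
    edge_lookup: dict[tuple[Port, Port], LinkEdge] = {}
    if graph is not None:
        for e in graph.edges:
            edge_lookup[tuple(sorted((e.port_a, e.port_b)))] = e
    n = len(path.steps)
    pieces: list[str] = []
    junctions = range(n if path.is_cycle else n - 1)
    for i in range(n):
        pieces.append(oriented[i])
        if i in junctions:
            j = (i + 1) % n
            exit_port = _oriented_exit(path.steps[i])
            entry_port = _oriented_entry(path.steps[j])
            edge = edge_lookup.get(tuple(sorted((exit_port, entry_port))))
            pieces.append(_junction_consensus(edge, exit_port))
    merged = "".join(pieces)
    return SequenceRecord(
        id=merged_id,
        residues=merged,
        description="assembled from " + ",".join(f"{c}{o}" for c, o in path.steps) + ";",
        topology="circular" if path.is_cycle else "linear",
        alphabet=NUCLEOTIDE,
    )


def _oriented_exit(step: tuple[str, str]) -> Port:
    cid, orient = step
    return (cid, TAIL if orient == "+" else HEAD)


def _oriented_entry(step: tuple[str, str]) -> Port:
    cid, orient = step
    return (cid, HEAD if orient == "+" else TAIL)


def _junction_consensus(edge: LinkEdge | None, exit_port: Port) -> str:
    if edge is None or not edge.inserts:
        return ""
    oriented = [
        ins if port == exit_port else revcomp(ins) if ins else ""
        for port, ins in edge.inserts
    ]
    length_votes = Counter(len(s) for s in oriented)
    top = max(length_votes.values())
    length = min(l for l, v in length_votes.items() if v == top)
    same_len = [s for s in oriented if len(s) == length]
    out = []
    for i in range(length):
        votes = Counter(s[i] for s in same_len)
        best = max(votes.values())
        out.append(min(b for b, v in votes.items() if v == best))
    return "".join(out)


# -- circularity -------------------------------------------------------------


def detect_circularity(
    contig: SequenceRecord,
    reads: Sequence[SequenceRecord],
    filter: FilterSpec = RECRUITMENT_FILTER,
    min_junction_overlap: int = 20,
    min_support: int = 2,
    probe_arm: int | None = None,
) -> tuple[bool, tuple[int, int] | None]:
    """Do reads successively overlap the end and beginning of the contig?

    A probe is built from the last K plus the first K bases (K defaults to
    twice the longest read); reads recruited across the probe's seam with
    at least ``min_junction_overlap`` aligned bases on each side count as
    junction support. Circularity requires ``min_support`` such reads.
    """
    if not reads:
        return False, None
    if probe_arm is None:
        probe_arm = 2 * max(len(r) for r in reads)
    K = min(probe_arm, len(contig) // 2)
    probe = SequenceRecord(
        id="__circular_probe__",
        residues=contig.residues[-K:] + contig.residues[:K],
        alphabet=NUCLEOTIDE,
    )
    result = recruit_reads(reads, [probe], filter)
    n_span = sum(
        1
        for h in result.hits
        if h.target_start <= K - min_junction_overlap and h.target_end >= K + min_junction_overlap
    )
    if n_span >= min_support:
        return True, (len(contig), 0)
    return False, None


# -- canonical rotation ------------------------------------------------------


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(
    genome: SequenceRecord, anchor_orf_start: int | None = None
) -> SequenceRecord:
    """Rotation-and-strand canonical form of a circular sequence.

    With an anchor (e.g. the MCP ORF start) the genome is rotated so the
    anchor sits at position 0 on the forward strand. Without one, the
    lexicographically minimal rotation of min(seq, revcomp(seq)) is chosen,
    so all rotations and both strands of the same circle map to one string.
    """
    s = genome.residues
    if genome.topology != "circular":
        raise ParameterError(f"{genome.id!r} is not circular")
    if anchor_orf_start is not None:
        k = anchor_orf_start % len(s)
        canon = s[k:] + s[:k]
    else:
        rc = revcomp(s)
        cand_f = s[_least_rotation(s) :] + s[: _least_rotation(s)]
        cand_r = rc[_least_rotation(rc) :] + rc[: _least_rotation(rc)]
        canon = min(cand_f, cand_r)
    return SequenceRecord(
        id=genome.id,
        residues=canon,
        description=genome.description + "canonical=1;",
        topology="circular",
        alphabet=NUCLEOTIDE,
    )


# -- population characterization ---------------------------------------------


@dataclass
class IdentityHistogram:
    """Distribution of recruitment identities (percent)."""

    identities: np.ndarray  # raw per-hit identity percentages
    bin_edges: np.ndarray
    counts: np.ndarray

    def band_fraction(self, lo: float, hi: float) -> float:
        """Fraction of hits with identity in the closed interval [lo, hi]."""
        if len(self.identities) == 0:
            return 0.0
        inside = (self.identities >= lo) & (self.identities <= hi)
        return float(inside.mean())

    @property
    def mean_identity_pct(self) -> float:
        return float(self.identities.mean()) if len(self.identities) else 0.0


def identity_histogram(hits: Iterable[AlignmentHit], bin_width: float = 1.0) -> IdentityHistogram:
    ids = np.array([h.identity_pct for h in hits], dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(ids, bins=edges)
    return IdentityHistogram(ids, edges, counts)


@dataclass
class PopulationCall:
    """Species-demarcation verdict from recruitment identities.

    ``species_like`` requires the mean recruitment identity to exceed the
    upper bound of the 90-95% demarcation band; intrapopulation variation
    is 100 minus the mean identity.
    """

    mean_identity_pct: float
    band_fraction_96_100: float
    demarcation_band: tuple[float, float] = (90.0, 95.0)

    @property
    def intrapop_variation_pct(self) -> float:
        return 100.0 - self.mean_identity_pct

    @property
    def verdict(self) -> str:
        return "species_like" if self.mean_identity_pct > self.demarcation_band[1] else "mixed"


def call_population(
    histogram: IdentityHistogram, mean_identity: float | None = None
) -> PopulationCall:
    if mean_identity is None:
        mean_identity = histogram.mean_identity_pct
    return PopulationCall(
        mean_identity_pct=float(mean_identity),
        band_fraction_96_100=histogram.band_fraction(96.0, 100.0),
    )


# -- exports -----------------------------------------------------------------


def write_gfa(graph: ContigGraph, contigs: Sequence[SequenceRecord], path: str | Path) -> None:
    """GFA 1.0: contigs as segments, supported junctions as links."""
    by_id = {c.id: c for c in contigs}
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for cid in sorted(graph.nodes):
            seq = by_id[cid].residues if cid in by_id else "*"
            fh.write(f"S\t{cid}\t{seq}\tLN:i:{graph.nodes[cid]}\n")
        for e in graph.edges:
            # leaving via tail = '+', via head = '-'; entering head = '+', tail = '-'
            oa = "+" if e.port_a[1] == TAIL else "-"
            ob = "+" if e.port_b[1] == HEAD else "-"
            fh.write(f"L\t{e.port_a[0]}\t{oa}\t{e.port_b[0]}\t{ob}\t0M\tRC:i:{e.support}\n")


def write_edges_tsv(graph: ContigGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tend_a\tcontig_b\tend_b\tsupport\tlink_reads\n")
        for e in graph.edges:
            fh.write(
                f"{e.port_a[0]}\t{e.port_a[1]}\t{e.port_b[0]}\t{e.port_b[1]}"
                f"\t{e.support}\t{','.join(e.link_read_ids)}\n"
            )


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    """BED-graph-like runs (contig, start, end, depth; 0-based half-open)."""
    depth = profile.depth
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tdepth\n")
        if len(depth) == 0:
            return
        run_start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[run_start]:
                fh.write(f"{profile.contig_id}\t{run_start}\t{i}\t{depth[run_start]}\n")
                run_start = i


def write_histogram_tsv(hist: IdentityHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tcount\n")
        for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
            fh.write(f"{lo:g}\t{hi:g}\t{c}\n")
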