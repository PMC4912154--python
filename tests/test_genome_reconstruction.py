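"""Link graph geometry, chaining, junction merging, circularity detection
and population characterization, against ground-truth synthetic circles."""

import random

import numpy as np
import pytest

from viroseek.errors import AmbiguityError, ConsistencyError
from viroseek.genome_reconstruction import (
    HEAD,
    TAIL,
    ContigGraph,
    ContigPath,
    IdentityHistogram,
    LinkEdge,
    build_link_graph,
    call_population,
    canonical_rotation,
    chain_contigs,
    coverage_profile,
    detect_circularity,
    identity_histogram,
    merge_path,
)
from viroseek.homology_search import AlignmentHit, recruit_reads
from viroseek.records import SequenceRecord, revcomp
from viroseek.synthetic_community import (
    CommunityConfig,
    fragment_genome,
    generate_reference_genome,
    simulate_reads,
)


def _nt(rid, seq, topology="linear"):
    return SequenceRecord(id=rid, residues=seq, topology=topology)


def _hit(qid, tid, ts, te, qs=0, qlen=None, strand="+", ident=None):
    span = te - ts
    qlen = qlen if qlen is not None else span
    ident = ident if ident is not None else span
    return AlignmentHit(
        query_id=qid, target_id=tid, score=2.0 * span, identities=ident,
        mismatches=span - ident, gap_opens=0, aligned_length=span,
        query_start=qs, query_end=qs + span, target_start=ts, target_end=te,
        query_length=qlen, target_length=10**9, strand=strand,
    )


class TestCoverageProfile:
    def test_no_hits_zero_depth(self):
        contig = _nt("c", "ACGT" * 25)
        prof = coverage_profile([], contig)
        assert prof.mean == 0.0 and prof.max == 0

    def test_exact_tiling_depth_one(self):
        contig = _nt("c", "ACGT" * 25)
        hits = [_hit("r1", "c", 0, 50), _hit("r2", "c", 50, 100)]
        prof = coverage_profile(hits, contig)
        assert prof.min == prof.max == 1

    def test_depth_sum_equals_aligned_bases(self):
        rng = random.Random(4)
        contig = _nt("c", "ACGT" * 250)
        hits = []
        for i in range(30):
            s = rng.randint(0, 900)
            hits.append(_hit(f"r{i}", "c", s, s + rng.randint(10, 100)))
        prof = coverage_profile(hits, contig)
        assert prof.depth.sum() == sum(h.target_end - h.target_start for h in hits)

    def test_out_of_bounds_hit_rejected(self):
        contig = _nt("c", "ACGT" * 10)
        with pytest.raises(ConsistencyError):
            coverage_profile([_hit("r", "c", 30, 50)], contig)


def _junction_fixture():
    """Two abutting contigs cut from one sequence, with junction reads."""
    rng = random.Random(42)
    genome = "".join(rng.choice("ACGT") for _ in range(2_000))
    a, b = genome[:1_200], genome[1_200:]
    contigs = [_nt("A", a), _nt("B", b)]
    reads = [
        _nt(f"j{i}", genome[1_200 - 200 + i * 7 : 1_200 + 200 + i * 7]) for i in range(3)
    ]
    return genome, contigs, reads


class TestBuildLinkGraph:
    def test_junction_reads_create_tail_head_edge(self):
        _, contigs, reads = _junction_fixture()
        rec = recruit_reads(reads, contigs)
        graph = build_link_graph(contigs, rec.all_alignments(), reads=reads)
        (edge,) = graph.edges
        assert {edge.port_a, edge.port_b} == {("A", TAIL), ("B", HEAD)}
        assert edge.support == 3

    def test_min_support_drops_weak_edges(self):
        _, contigs, reads = _junction_fixture()
        rec = recruit_reads(reads[:1], contigs)
        graph = build_link_graph(contigs, rec.all_alignments(), reads=reads[:1], min_support=2)
        assert graph.edges == []

    def test_two_hits_within_one_contig_no_edge(self):
        contig = _nt("A", "ACGT" * 300)
        hits = [
            _hit("r", "A", 0, 200, qs=0, qlen=400),
            _hit("r", "A", 900, 1100, qs=200, qlen=400),
        ]
        graph = build_link_graph([contig], hits)
        assert graph.edges == []

    def test_four_contig_circle_yields_single_cycle(self, small_community):
        com = small_community
        rec = recruit_reads(com.all_reads, com.contigs)
        graph = build_link_graph(com.contigs, rec.all_alignments(), reads=com.all_reads)
        assert len(graph.edges) == len(com.contigs)
        paths = chain_contigs(graph)
        assert len(paths) == 1 and paths[0].is_cycle
        assert len(paths[0].steps) == len(com.contigs)

    def test_removing_reads_never_adds_edges(self, small_community):
        com = small_community
        rec = recruit_reads(com.all_reads, com.contigs)
        full = build_link_graph(com.contigs, rec.all_alignments(), reads=com.all_reads)
        half_ids = {r.id for r in com.all_reads[::2]}
        subset = [h for h in rec.all_alignments() if h.query_id in half_ids]
        sub = build_link_graph(com.contigs, subset, reads=com.all_reads)
        full_keys = {(e.port_a, e.port_b) for e in full.edges}
        sub_keys = {(e.port_a, e.port_b) for e in sub.edges}
        assert sub_keys <= full_keys


class TestChainContigs:
    @staticmethod
    def _graph(edges, lengths=None):
        nodes = lengths or {}
        for e in edges:
            for c, _ in (e.port_a, e.port_b):
                nodes.setdefault(c, 1_000)
        return ContigGraph(nodes=nodes, edges=edges)

    def test_linear_chain_resolved(self):
        g = self._graph(
            [
                LinkEdge(("A", TAIL), ("B", HEAD), 2, []),
                LinkEdge(("B", TAIL), ("C", HEAD), 2, []),
            ],
            lengths={"A": 3_000, "B": 2_000, "C": 1_000},
        )
        (path,) = chain_contigs(g)
        assert not path.is_cycle
        assert path.steps == [("A", "+"), ("B", "+"), ("C", "+")]

    def test_flipped_contig_gets_minus_orientation(self):
        g = self._graph(
            [LinkEdge(("A", TAIL), ("B", TAIL), 2, [])],
            lengths={"A": 3_000, "B": 2_000},
        )
        (path,) = chain_contigs(g)
        assert path.steps == [("A", "+"), ("B", "-")]

    def test_star_graph_is_ambiguous(self):
        g = self._graph(
            [
                LinkEdge(("A", TAIL), ("B", HEAD), 2, []),
                LinkEdge(("A", TAIL), ("C", HEAD), 2, []),
            ]
        )
        with pytest.raises(AmbiguityError, match="A"):
            chain_contigs(g)

    def test_anchor_starts_cycle_oriented_forward(self):
        g = self._graph(
            [
                LinkEdge(("A", TAIL), ("B", HEAD), 2, []),
                LinkEdge(("B", TAIL), ("C", HEAD), 2, []),
                LinkEdge(("C", TAIL), ("A", HEAD), 2, []),
            ]
        )
        (path,) = chain_contigs(g, anchor="B")
        assert path.is_cycle
        assert path.steps[0] == ("B", "+")


class TestMergePath:
    def test_single_contig_identity(self):
        contig = _nt("A", "ACGTACGT")
        merged = merge_path(ContigPath([("A", "+")], is_cycle=False), [contig])
        assert merged.residues == contig.residues

    def test_abutting_fixture_merges_exactly(self):
        genome, contigs, reads = _junction_fixture()
        rec = recruit_reads(reads, contigs)
        graph = build_link_graph(contigs, rec.all_alignments(), reads=reads)
        merged = merge_path(ContigPath([("A", "+"), ("B", "+")], False), contigs, graph)
        assert merged.residues == genome

    def test_majority_vote_insert(self):
        a, b = _nt("A", "ACGTACGTAC"), _nt("B", "TTGGCCAATT")
        edge = LinkEdge(
            ("A", TAIL), ("B", HEAD), 3, ["r1", "r2", "r3"],
            inserts=[(("A", TAIL), "G"), (("A", TAIL), "G"), (("A", TAIL), "C")],
        )
        graph = ContigGraph(nodes={"A": 10, "B": 10}, edges=[edge])
        merged = merge_path(ContigPath([("A", "+"), ("B", "+")], False), [a, b], graph)
        assert merged.residues == a.residues + "G" + b.residues


class TestDetectCircularity:
    def _community(self, seed=31):
        cfg = CommunityConfig(
            genome_length=4_000, mean_coverage=25, n_variants=1, divergence=0.0,
            read_length=200, background_reads=0, rng_seed=seed,
        )
        ref = generate_reference_genome(cfg)
        reads = simulate_reads([ref], 25, 200, 0.0, seed)
        return ref, reads

    def test_circular_genome_detected(self):
        ref, reads = self._community()
        linear = _nt("contig", ref.residues)
        is_circ, junction = detect_circularity(linear, reads)
        assert is_circ and junction == (4_000, 0)

    def test_linear_genome_not_detected(self):
        ref, reads = self._community()
        # reads that never wrap the origin cannot support a seam
        non_wrapping = [r for r in reads if int(r.provenance()["end"]) <= 4_000]
        linear = _nt("contig", ref.residues)
        # shuffle the origin away from any read boundary effect by rotating 180 deg
        assert detect_circularity(linear, non_wrapping)[0] is False

    def test_seam_read_ablation_flips_call(self):
        ref, reads = self._community()
        linear = _nt("contig", ref.residues)
        assert detect_circularity(linear, reads)[0] is True
        kept = [r for r in reads if int(r.provenance()["end"]) <= 4_000]
        assert detect_circularity(linear, kept)[0] is False


class TestCanonicalRotation:
    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_and_strand_invariance(self, seed):
        rng = random.Random(seed)
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(50, 400)))
        base = canonical_rotation(_nt("g", s, "circular"))
        k = rng.randrange(len(s))
        rot = canonical_rotation(_nt("g", s[k:] + s[:k], "circular"))
        rc = canonical_rotation(_nt("g", revcomp(s), "circular"))
        assert base.residues == rot.residues == rc.residues

    def test_anchored_rotation_starts_at_anchor(self):
        s = "AAACCCGGGTTT"
        out = canonical_rotation(_nt("g", s, "circular"), anchor_orf_start=6)
        assert out.residues == s[6:] + s[:6]


class TestPopulationCall:
    def test_band_fractions(self):
        hits = [_hit("r1", "c", 0, 100, ident=94), _hit("r2", "c", 0, 100, ident=97),
                _hit("r3", "c", 0, 100, ident=99)]
        hist = identity_histogram(hits)
        assert hist.band_fraction(96, 100) == pytest.approx(2 / 3)
        all100 = identity_histogram([_hit("r", "c", 0, 50)])
        assert all100.band_fraction(96, 100) == 1.0

    @pytest.mark.parametrize(
        "mean,verdict,variation",
        [(98.0, "species_like", 2.0), (93.0, "mixed", 7.0), (95.0, "mixed", 5.0)],
    )
    def test_demarcation_verdict(self, mean, verdict, variation):
        call = call_population(IdentityHistogram(np.array([mean]), np.array([0, 100]), np.array([1])), mean)
        assert call.verdict == verdict
        assert call.intrapop_variation_pct == pytest.approx(variation)

    def test_counts_sum_to_hits(self):
        hits = [_hit(f"r{i}", "c", 0, 100, ident=90 + i % 10) for i in range(25)]
        hist = identity_histogram(hits)
        assert hist.counts.sum() == 25


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_fragmented_circle_recovered_exactly(self, seed, marker_msa):
        from viroseek.marker_block import MultipleAlignment, extract_conserved_block
        from viroseek.pipeline import run_reconstruction
        from viroseek.synthetic_community import simulate_community

        cfg = CommunityConfig(
            genome_length=8_000, mean_coverage=30, n_variants=1, divergence=0.0,
            background_reads=100, n_contigs=4, rng_seed=seed,
        )
        com = simulate_community(cfg, marker_peptide=marker_msa.consensus_block)
        block = extract_conserved_block(MultipleAlignment(marker_msa.records), ref_id="MCP01")
        report = run_reconstruction(com.all_reads, com.contigs, block)
        assert report.is_circular
        assert (
            canonical_rotation(report.genome).residues
            == canonical_rotation(com.reference).residues
        )
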