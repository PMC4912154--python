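"""Alignment engine and filter semantics: translation frames, optimal
local alignment against a full-DP oracle, recruitment geometry, strict
cut-off behavior, and best-hit tie rules."""

import random

import pytest
from Bio.Align import substitution_matrices

from _oracles import gotoh_local_score
from viroseek.errors import ParameterError
from viroseek.homology_search import (
    NUCLEOTIDE_SCORING,
    PROTEIN_SCORING,
    RECRUITMENT_FILTER,
    AlignmentHit,
    FilterSpec,
    align_local,
    best_hit_per_read,
    recruit_reads,
    search_reads_translated,
    six_frame_translate,
    survey_nucleotide,
    survey_translated_block,
    write_hits_tsv,
)
from viroseek.records import SequenceRecord, revcomp
from viroseek.synthetic_community import embed_in_read

_B62 = substitution_matrices.load("BLOSUM62")
AAS = "ACDEFGHIKLMNPQRSTVWY"


def _nt_record(rid, seq):
    return SequenceRecord(id=rid, residues=seq)


class TestSixFrameTranslate:
    def test_codon_table(self):
        frames = dict(six_frame_translate(_nt_record("r", "ATGAAA")))
        assert frames[1].residues == "MK"
        assert frames[2].residues == "*"  # TGA... -> wait, offset 1 = TGA AA -> '*'
        assert set(frames) == {1, 2, 3, -1, -2, -3}

    def test_short_read_empty(self):
        assert six_frame_translate(_nt_record("r", "AT")) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complement_symmetry(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 90)))
        fwd = dict(six_frame_translate(_nt_record("a", seq)))
        rc = dict(six_frame_translate(_nt_record("b", revcomp(seq))))
        for f in (1, 2, 3):
            assert fwd[-f].residues == rc[f].residues


class TestAlignLocal:
    def test_identical_sequences(self):
        pep = "".join(random.Random(0).choice(AAS) for _ in range(60))
        hit = align_local(pep, pep, PROTEIN_SCORING)
        assert hit.identity_pct == 100.0
        assert hit.aligned_length == 60
        assert hit.query_cov_pct == 100.0

    def test_single_substitution_identity(self):
        pep = "".join(random.Random(1).choice(AAS) for _ in range(60))
        mutated = pep[:30] + ("A" if pep[30] != "A" else "C") + pep[31:]
        hit = align_local(pep, mutated, PROTEIN_SCORING)
        assert hit.identities == 59
        assert hit.aligned_length == 60
        assert round(hit.identity_pct, 2) == 98.33

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            align_local("", "MKV", PROTEIN_SCORING)

    @pytest.mark.parametrize("seed", range(8))
    def test_self_alignment_full_identity(self, seed):
        rng = random.Random(seed)
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 150)))
        hit = align_local(s, s, NUCLEOTIDE_SCORING)
        assert hit.identity_pct == 100.0 and hit.query_cov_pct == 100.0

    @pytest.mark.parametrize("alphabet", ["protein", "nucleotide"])
    def test_score_equals_full_dp_oracle(self, alphabet):
        """Spot check against the independent Gotoh DP (bulk run lives in
        the acceptance suite)."""
        rng = random.Random(99 if alphabet == "protein" else 98)
        if alphabet == "protein":
            letters, scoring = AAS, PROTEIN_SCORING
            sub = lambda x, y: float(_B62[x][y])
            go, ge, max_len = 11, 1, 80
        else:
            letters, scoring = "ACGT", NUCLEOTIDE_SCORING
            sub = lambda x, y: 2.0 if x == y else -3.0
            go, ge, max_len = 5, 2, 300
        for _ in range(40):
            a = "".join(rng.choice(letters) for _ in range(rng.randint(5, max_len)))
            b = "".join(rng.choice(letters) for _ in range(rng.randint(5, max_len)))
            hit = align_local(a, b, scoring)
            got = hit.score if hit is not None else 0.0
            assert got == pytest.approx(gotoh_local_score(a, b, sub, go, ge))


class TestFilterSemantics:
    @staticmethod
    def _hit(identities, aligned_length, qspan, qlen, tspan=None, tlen=100):
        tspan = tspan if tspan is not None else aligned_length
        return AlignmentHit(
            query_id="q", target_id="t", score=1.0,
            identities=identities, mismatches=aligned_length - identities,
            gap_opens=0, aligned_length=aligned_length,
            query_start=0, query_end=qspan, target_start=0, target_end=tspan,
            query_length=qlen, target_length=tlen,
        )

    @pytest.mark.parametrize(
        "spec,hit_kwargs,expected",
        [
            # translated survey >30% identity and >55 aligned columns
            (FilterSpec(30, 55), dict(identities=17, aligned_length=56, qspan=56, qlen=60), True),
            (FilterSpec(30, 55), dict(identities=30, aligned_length=100, qspan=100, qlen=100), False),
            (FilterSpec(30, 55), dict(identities=55, aligned_length=55, qspan=55, qlen=60), False),
            # recruitment >95% identity and >50% query coverage
            (FilterSpec(95, None, 50), dict(identities=381, aligned_length=400, qspan=400, qlen=400), True),
            (FilterSpec(95, None, 50), dict(identities=380, aligned_length=400, qspan=400, qlen=400), False),
            (FilterSpec(95, None, 50), dict(identities=200, aligned_length=200, qspan=200, qlen=400), False),
            (FilterSpec(95, None, 50), dict(identities=201, aligned_length=201, qspan=201, qlen=400), True),
            # SSU survey >70% identity and >90% target coverage
            (FilterSpec(70, None, None, 90), dict(identities=85, aligned_length=120, qspan=120, qlen=400, tspan=120, tlen=120), True),
            (FilterSpec(70, None, None, 90), dict(identities=84, aligned_length=120, qspan=120, qlen=400, tspan=120, tlen=120), False),
            (FilterSpec(70, None, None, 90), dict(identities=108, aligned_length=108, qspan=108, qlen=400, tspan=108, tlen=120), False),
            # phycodnavirus block >30% identity and >90% target coverage
            (FilterSpec(30, None, None, 90), dict(identities=24, aligned_length=60, qspan=60, qlen=130, tspan=60, tlen=60), True),
            (FilterSpec(30, None, None, 90), dict(identities=18, aligned_length=60, qspan=60, qlen=130, tspan=60, tlen=60), False),
            (FilterSpec(30, None, None, 90), dict(identities=30, aligned_length=54, qspan=54, qlen=130, tspan=54, tlen=60), False),
            # gene content >30% identity and >50% query coverage
            (FilterSpec(30, None, 50), dict(identities=40, aligned_length=100, qspan=100, qlen=150), True),
            (FilterSpec(30, None, 50), dict(identities=40, aligned_length=100, qspan=75, qlen=150), False),
        ],
    )
    def test_strict_inequality_boundaries(self, spec, hit_kwargs, expected):
        assert spec.passes(self._hit(**hit_kwargs)) is expected

    def test_raising_threshold_never_adds_hits(self):
        rng = random.Random(5)
        hits = [
            self._hit(
                identities=rng.randint(10, 100),
                aligned_length=100,
                qspan=rng.randint(50, 100),
                qlen=100,
            )
            for _ in range(50)
        ]
        loose = FilterSpec(30, None, 40)
        tight = FilterSpec(50, None, 60)
        kept_loose = {id(h) for h in hits if loose.passes(h)}
        kept_tight = {id(h) for h in hits if tight.passes(h)}
        assert kept_tight <= kept_loose

    def test_at_least_one_criterion_required(self):
        with pytest.raises(ParameterError):
            FilterSpec()


class TestRecruitReads:
    def _contigs(self, seed=21):
        rng = random.Random(seed)
        a = "".join(rng.choice("ACGT") for _ in range(1_500))
        b = "".join(rng.choice("ACGT") for _ in range(1_200))
        return [_nt_record("ctgA", a), _nt_record("ctgB", b)]

    def test_verbatim_read_recruited(self):
        contigs = self._contigs()
        read = _nt_record("r1", contigs[0].residues[200:600])
        result = recruit_reads([read], contigs)
        (hit,) = result.hits
        assert hit.identity_pct == 100.0 and hit.query_cov_pct == 100.0
        assert hit.target_id == "ctgA"

    def test_reverse_strand_read_recruited(self):
        contigs = self._contigs()
        read = _nt_record("r1", revcomp(contigs[0].residues[200:600]))
        (hit,) = recruit_reads([read], contigs).hits
        assert hit.strand == "-" and hit.identity_pct == 100.0

    def test_diverged_read_excluded(self):
        contigs = self._contigs()
        rng = random.Random(3)
        seq = list(contigs[0].residues[200:600])
        for i in rng.sample(range(2, 398), 32):  # 8% divergence
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        result = recruit_reads([_nt_record("r1", "".join(seq))], contigs)
        assert result.hits == []

    def test_junction_read_keeps_major_side_and_link_evidence(self):
        contigs = self._contigs()
        # 240 bp off ctgA's tail + 160 bp off ctgB's head
        read = _nt_record(
            "jr", contigs[0].residues[-240:] + contigs[1].residues[:160]
        )
        result = recruit_reads([read], contigs)
        assert [h.target_id for h in result.hits] == ["ctgA"]
        assert result.hits[0].query_cov_pct == 60.0
        assert [h.target_id for h in result.link_evidence] == ["ctgB"]
        assert result.link_evidence[0].query_cov_pct == pytest.approx(40.0)

    def test_seeded_matches_exact_method(self):
        contigs = self._contigs()
        rng = random.Random(13)
        reads = []
        for i in range(15):
            src = contigs[i % 2]
            start = rng.randint(0, len(src) - 300)
            seq = list(src.residues[start : start + 300])
            for p in rng.sample(range(2, 298), rng.choice([0, 3, 6])):
                seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
            s = "".join(seq)
            if rng.random() < 0.5:
                s = revcomp(s)
            reads.append(_nt_record(f"r{i}", s))
        seeded = recruit_reads(reads, contigs, method="seeded")
        exact = recruit_reads(reads, contigs, method="exact")
        key = lambda h: (h.query_id, h.target_id, h.score, h.identities)
        assert sorted(map(key, seeded.hits)) == sorted(map(key, exact.hits))


class TestTranslatedSearch:
    def test_marker_read_found_background_not(self, marker_msa, marker_block_obj):
        from viroseek.synthetic_community import embed_peptide_in_read, generate_background

        planted = [
            embed_peptide_in_read(
                marker_msa.consensus_block, 400, 0.33, seed=50 + i, read_id=f"mk{i}"
            )
            for i in range(3)
        ]
        background = generate_background(30, 400, 0.33, seed=51)
        hits = search_reads_translated(planted + background, marker_block_obj)
        assert sorted(h.query_id for h in hits) == ["mk0", "mk1", "mk2"]
        assert all(h.identity_pct > 90 for h in hits)

    def test_minus_strand_read_found_with_negative_frame(self, marker_msa, marker_block_obj):
        from viroseek.synthetic_community import embed_peptide_in_read

        read = embed_peptide_in_read(
            marker_msa.consensus_block, 400, 0.33, seed=60, read_id="rc", strand="-"
        )
        (hit,) = search_reads_translated([read], marker_block_obj)
        assert hit.frame < 0 and hit.strand == "-"


class TestSurveyNucleotide:
    def test_full_target_copy_hits(self):
        rng = random.Random(8)
        target = _nt_record("v9_01", "".join(rng.choice("ACGT") for _ in range(120)))
        read = embed_in_read(target.residues, 400, 0.5, seed=8, read_id="r1")
        (hit,) = survey_nucleotide([read], [target])
        assert hit.target_cov_pct == 100.0 and hit.identity_pct == 100.0

    def test_partial_target_coverage_rejected(self):
        rng = random.Random(9)
        target = _nt_record("v9_01", "".join(rng.choice("ACGT") for _ in range(120)))
        read = embed_in_read(target.residues[:96], 400, 0.5, seed=9, read_id="r1")
        assert survey_nucleotide([read], [target]) == []


class TestSurveyTranslatedBlock:
    def test_full_block_kept_half_block_rejected(self, marker_msa, marker_block_obj):
        from viroseek.synthetic_community import embed_peptide_in_read

        full = embed_peptide_in_read(
            marker_msa.consensus_block, 400, 0.33, seed=70, read_id="full"
        )
        half = embed_peptide_in_read(
            marker_msa.consensus_block[:30], 400, 0.33, seed=71, read_id="half"
        )
        hits = survey_translated_block([full, half], marker_block_obj)
        assert [h.query_id for h in hits] == ["full"]
        assert hits[0].target_cov_pct > 90


class TestBestHitPerRead:
    def _hit(self, qid, tid, score, ident, frame=None):
        return AlignmentHit(
            query_id=qid, target_id=tid, score=score, identities=ident,
            mismatches=100 - ident, gap_opens=0, aligned_length=100,
            query_start=0, query_end=100, target_start=0, target_end=100,
            query_length=100, target_length=100, frame=frame,
        )

    def test_single_hit_unchanged(self):
        h = self._hit("q", "t", 50, 90)
        assert best_hit_per_read([h]) == [h]

    def test_equal_score_higher_identity_wins(self):
        a = self._hit("q", "t1", 50, 90)
        b = self._hit("q", "t2", 50, 95)
        assert best_hit_per_read([a, b]) == [b]

    def test_full_tie_lexicographic_target(self):
        a = self._hit("q", "tB", 50, 90)
        b = self._hit("q", "tA", 50, 90)
        assert best_hit_per_read([a, b]) == [b]

    def test_frame_order_breaks_final_tie(self):
        a = self._hit("q", "t", 50, 90, frame=-1)
        b = self._hit("q", "t", 50, 90, frame=3)
        assert best_hit_per_read([a, b]) == [b]


def test_tabular_output_coordinates(tmp_path):
    hit = AlignmentHit(
        query_id="q", target_id="t", score=42, identities=95, mismatches=5,
        gap_opens=0, aligned_length=100, query_start=0, query_end=100,
        target_start=10, target_end=110, query_length=120, target_length=200,
    )
    out = tmp_path / "hits.tsv"
    write_hits_tsv([hit], out)
    line = out.read_text().splitlines()[1].split("\t")
    assert line[:2] == ["q", "t"]
    assert line[6:10] == ["1", "100", "11", "110"]  # 1-based inclusive
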