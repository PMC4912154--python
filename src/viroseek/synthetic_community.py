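"""Ground-truth synthetic metagenomes for virophage discovery.

This module builds communities with the statistical structure the analysis
assumes: one circular virophage-like genome present as a species-like
population of slightly diverged variants, sequenced to a chosen mean
coverage, embedded in unrelated background reads, plus assembler-style
fragmented contigs tiling the genome. Every output carries provenance in
its description line so downstream stages can be scored against truth.

All randomness flows from one seeded NumPy generator per operation call;
identical seed + configuration gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import AlphabetError, ConfigurationError, EncodingError, ParameterError
from .records import NUCLEOTIDE, PROTEIN, SequenceRecord, format_provenance, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate("ACGT")}

# aa -> codons, standard genetic code (no stop codons appear as values)
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for _codons in _CODONS_BY_AA.values():
    _codons.sort()

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of one synthetic community.

    Defaults describe the study conditions this package targets: a
    23,379 bp circular genome at 33.2% G+C carried by a ten-variant
    population with 2% per-site divergence, sequenced to 56x mean coverage
    with 400 bp error-free reads, fragmented into four contigs and mixed
    with 2,000 unrelated background reads.
    """

    genome_length: int = 23_379
    gc_fraction: float = 0.332
    n_variants: int = 10
    divergence: float = 0.02
    mean_coverage: float = 56.0
    read_length: int | tuple[int, int] = 400
    seq_error_rate: float = 0.0
    background_reads: int = 2_000
    n_contigs: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("genome_length", self.genome_length > 0),
            ("gc_fraction", 0.0 <= self.gc_fraction <= 1.0),
            ("n_variants", self.n_variants >= 1),
            ("divergence", 0.0 <= self.divergence <= 0.5),
            ("mean_coverage", self.mean_coverage >= 0),
            ("seq_error_rate", 0.0 <= self.seq_error_rate <= 0.1),
            ("background_reads", self.background_reads >= 0),
            ("n_contigs", self.n_contigs >= 1),
        ]
        if isinstance(self.read_length, tuple):
            checks.append(("read_length", 0 < self.read_length[0] <= self.read_length[1]))
        else:
            checks.append(("read_length", self.read_length > 0))
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"invalid CommunityConfig.{name}: {getattr(self, name)!r}")

    @property
    def mean_read_length(self) -> float:
        if isinstance(self.read_length, tuple):
            return (self.read_length[0] + self.read_length[1]) / 2.0
        return float(self.read_length)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """One generator per (seed, named stream) so sibling operations do not couple."""
    return np.random.default_rng([int(seed), *stream])


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _as_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def generate_reference_genome(cfg: CommunityConfig) -> SequenceRecord:
    """Circular random genome of exactly ``cfg.genome_length`` bases.

    The base multiset is fixed by count — ``round(gc * L)`` G/C bases, split
    evenly between G and C (ditto A/T) — and then shuffled, so the realized
    G+C equals the requested fraction to within half a base.
    """
    rng = _rng(cfg.rng_seed, 1)
    L = cfg.genome_length
    n_gc = int(round(cfg.gc_fraction * L))
    n_g, n_c = n_gc // 2, n_gc - n_gc // 2
    n_at = L - n_gc
    n_a, n_t = n_at // 2, n_at - n_at // 2
    pool = np.repeat(_BASES, [n_a, n_c, n_g, n_t])
    rng.shuffle(pool)
    return SequenceRecord(
        id="ref_genome",
        residues=_as_str(pool),
        description=format_provenance(seed=cfg.rng_seed, gc=cfg.gc_fraction),
        topology="circular",
        alphabet=NUCLEOTIDE,
    )


def mutate_population(
    ref: SequenceRecord, n_variants: int, divergence: float, seed: int
) -> list[SequenceRecord]:
    """Derive a species-like population by i.i.d. per-site substitution.

    Substitutions only (no indels), each site flipped with probability
    ``divergence`` to one of the three other bases; expected pairwise
    distance to the reference equals ``divergence``.
    """
    if ref.alphabet != NUCLEOTIDE:
        raise AlphabetError("mutate_population requires a nucleotide reference")
    if not 0.0 <= divergence <= 0.5:
        raise ParameterError(f"divergence out of range: {divergence}")
    rng = _rng(seed, 2)
    arr = _as_array(ref.residues)
    idx = np.array([_BASE_INDEX.get(chr(c), -1) for c in arr], dtype=np.int64)
    variants = []
    for i in range(n_variants):
        mask = (rng.random(len(arr)) < divergence) & (idx >= 0)
        n_mut = int(mask.sum())
        shift = rng.integers(1, 4, size=n_mut)
        new_idx = (idx[mask] + shift) % 4
        out = arr.copy()
        out[mask] = _BASES[new_idx]
        variants.append(
            replace(
                ref,
                id=f"{ref.id}_v{i + 1}",
                residues=_as_str(out),
                description=format_provenance(
                    parent=ref.id, divergence=divergence, seed=seed, variant=i + 1
                ),
            )
        )
    return variants


def simulate_reads(
    genomes: Sequence[SequenceRecord],
    mean_coverage: float,
    read_length: int | tuple[int, int],
    seq_error_rate: float,
    seed: int,
) -> list[SequenceRecord]:
    """Uniform shotgun reads over the (circular) genomes.

    Read count is ``round(mean_coverage * genome_length / mean_read_length)``
    with the source genome for each read drawn uniformly. Start positions are
    uniform; circular genomes wrap reads across the origin; strands are
    uniform. Per-base substitution errors occur at ``seq_error_rate``.
    Provenance (source, start, end, strand) is stored on the forward strand
    of the source, 0-based half-open; ``end > genome_length`` marks a
    wrapped read.
    """
    if not genomes:
        raise ParameterError("simulate_reads: genomes must be non-empty")
    L = len(genomes[0])
    if isinstance(read_length, tuple):
        lo, hi = read_length
        mean_rl = (lo + hi) / 2.0
    else:
        lo = hi = int(read_length)
        mean_rl = float(read_length)
    if hi > L:
        raise ParameterError(f"read_length {hi} exceeds genome length {L}")
    rng = _rng(seed, 3)
    n_reads = int(round(mean_coverage * L / mean_rl))
    arrays = [_as_array(g.residues) for g in genomes]
    doubled = [np.concatenate([a, a]) for a in arrays]
    reads: list[SequenceRecord] = []
    for i in range(n_reads):
        gi = int(rng.integers(0, len(genomes)))
        genome = genomes[gi]
        rl = int(rng.integers(lo, hi + 1)) if lo != hi else lo
        if genome.topology == "circular":
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, L - rl + 1))
        chunk = doubled[gi][start : start + rl].copy()
        n_err = 0
        if seq_error_rate > 0:
            err_mask = rng.random(rl) < seq_error_rate
            n_err = int(err_mask.sum())
            if n_err:
                cur = np.array([_BASE_INDEX.get(chr(c), 0) for c in chunk[err_mask]])
                shift = rng.integers(1, 4, size=n_err)
                chunk[err_mask] = _BASES[(cur + shift) % 4]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _as_str(chunk)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(
            SequenceRecord(
                id=f"read_{i + 1:06d}",
                residues=seq,
                description=format_provenance(
                    source=genome.id,
                    start=start,
                    end=start + rl,
                    strand=strand,
                    errors=n_err,
                    background=0,
                    seed=seed,
                ),
                alphabet=NUCLEOTIDE,
            )
        )
    return reads


def fragment_genome(
    ref: SequenceRecord,
    n_contigs: int,
    seed: int,
    min_contig_length: int | None = None,
    avoid_intervals: Sequence[tuple[int, int]] = (),
) -> list[SequenceRecord]:
    """Cut a circular reference into linear contigs that tile it exactly.

    Contigs abut with zero overlap — junction points are covered only by
    reads, emulating an assembler that broke the circle. Output order is
    shuffled and each contig's orientation is random; provenance records the
    arc (start, end on the forward reference), orientation, and ground-truth
    order so tests can reassemble the rotation. ``avoid_intervals`` are
    half-open intervals (wrapping allowed) that no cut may fall inside —
    used to keep the planted marker gene intact on one contig, mirroring
    communities whose assembler yielded an intact marker-encoding contig.
    """
    L = len(ref)
    if n_contigs > L:
        raise ParameterError(f"n_contigs {n_contigs} exceeds genome length {L}")
    if min_contig_length is None:
        min_contig_length = min(1_000, max(1, L // (2 * n_contigs)))
    forbidden = np.zeros(L, dtype=bool)
    for lo, hi in avoid_intervals:
        for p in range(lo, hi):
            forbidden[p % L] = True
    rng = _rng(seed, 4)
    cuts = None
    for _ in range(1_000):
        cand = np.sort(rng.choice(L, size=n_contigs, replace=False))
        if forbidden[cand].any():
            continue
        arc_lengths = np.diff(np.concatenate([cand, [cand[0] + L]]))
        if np.all(arc_lengths >= min_contig_length):
            cuts = cand
            break
    if cuts is None:
        raise ParameterError(
            f"could not place {n_contigs} contigs of >= {min_contig_length} bp on {L} bp"
        )
    doubled = ref.residues + ref.residues
    order = rng.permutation(n_contigs)
    contigs: list[SequenceRecord] = []
    for name_idx, truth_idx in enumerate(order):
        start = int(cuts[truth_idx])
        end = int(cuts[(truth_idx + 1) % n_contigs])
        if end <= start:
            end += L
        seq = doubled[start:end]
        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            seq = revcomp(seq)
        contigs.append(
            SequenceRecord(
                id=f"contig_{name_idx + 1:04d}",
                residues=seq,
                description=format_provenance(
                    source=ref.id,
                    start=start,
                    end=end,
                    orientation=orientation,
                    order=int(truth_idx),
                    seed=seed,
                ),
                alphabet=NUCLEOTIDE,
            )
        )
    return contigs


# -- reverse translation and marker planting --------------------------------


def encode_peptide(peptide: str, gc_fraction: float, rng: np.random.Generator) -> str:
    """Reverse-translate, preferring codons whose G+C is closest to target."""
    if "*" in peptide:
        raise EncodingError("peptide contains a stop symbol; cannot encode in frame")
    codons = []
    for aa in peptide:
        if aa not in _CODONS_BY_AA:
            raise EncodingError(f"cannot encode residue {aa!r}")
        options = _CODONS_BY_AA[aa]
        dist = [abs(sum(c in "GC" for c in codon) / 3.0 - gc_fraction) for codon in options]
        best = min(dist)
        tied = [c for c, d in zip(options, dist) if d == best]
        codons.append(tied[int(rng.integers(0, len(tied)))])
    return "".join(codons)


def plant_marker_orf(
    ref: SequenceRecord,
    peptide: str | SequenceRecord,
    position: int,
    strand: str = "+",
    gc_fraction: float | None = None,
    seed: int = 0,
    add_stop: bool = True,
) -> SequenceRecord:
    """Overwrite part of the genome with an in-frame encoding of ``peptide``.

    Guarantees the translated search a true positive: after planting, the
    interval at ``position`` (plus strand) or its reverse complement (minus
    strand) translates exactly to the peptide. ``add_stop`` appends a stop
    codon so a start-to-stop ORF caller terminates the gene.
    """
    pep = peptide.residues if isinstance(peptide, SequenceRecord) else peptide
    rng = _rng(seed, 5)
    if gc_fraction is None:
        gc_fraction = _gc_of(ref.residues)
    coding = encode_peptide(pep, gc_fraction, rng)
    if add_stop:
        coding += "TAA"
    span = len(coding)
    L = len(ref)
    if span > L:
        raise ParameterError("peptide does not fit in genome")
    if ref.topology != "circular" and position + span > L:
        raise ParameterError("peptide does not fit at position on a linear genome")
    if strand == "-":
        coding = revcomp(coding)
    arr = list(ref.residues)
    for k, base in enumerate(coding):
        arr[(position + k) % L] = base
    return replace(
        ref, residues="".join(arr), description=ref.description + f"marker_at={position}{strand};"
    )


def generate_background(n_reads: int, read_length: int, gc: float, seed: int) -> list[SequenceRecord]:
    """Unrelated i.i.d. reads — the non-virophage community (true negatives)."""
    if n_reads < 0:
        raise ParameterError(f"n_reads must be >= 0, got {n_reads}")
    rng = _rng(seed, 6)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reads = []
    for i in range(n_reads):
        arr = _BASES[rng.choice(4, size=read_length, p=p)]
        reads.append(
            SequenceRecord(
                id=f"bg_{i + 1:06d}",
                residues=_as_str(arr),
                description=format_provenance(source="background", background=1, seed=seed),
                alphabet=NUCLEOTIDE,
            )
        )
    return reads


def _rebalance_gc(
    ref: SequenceRecord,
    gc_fraction: float,
    protected: tuple[int, int],
    seed: int,
) -> SequenceRecord:
    """Flip bases outside ``protected`` until the G+C count is exact."""
    L = len(ref)
    arr = list(ref.residues)
    target = int(round(gc_fraction * L))
    current = sum(b in "GC" for b in arr)
    delta = target - current  # >0: need more G/C; <0: need more A/T
    if delta == 0:
        return ref
    rng = _rng(seed, 11)
    shielded = {p % L for p in range(protected[0], protected[1])}
    donor = "AT" if delta > 0 else "GC"
    acceptor = "GC" if delta > 0 else "AT"
    candidates = [i for i in range(L) if i not in shielded and arr[i] in donor]
    picks = rng.choice(len(candidates), size=abs(delta), replace=False)
    for k in picks:
        i = candidates[int(k)]
        arr[i] = acceptor[int(rng.integers(0, 2))]
    return replace(ref, residues="".join(arr))


def _gc_of(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


# -- synthetic reference marker alignments ----------------------------------


class SyntheticMsa(NamedTuple):
    """A synthetic stand-in for a reference capsid-protein alignment."""

    records: list[SequenceRecord]
    consensus_block: str
    block_start: int
    block_length: int


def generate_marker_msa(
    seed: int,
    n_records: int = 9,
    n_columns: int = 470,
    block_start: int = 344,
    block_length: int = 60,
    block_divergence: float = 0.05,
    flank_divergence: float = 0.55,
    gap_fraction: float = 0.08,
    id_prefix: str = "MCP",
) -> SyntheticMsa:
    """Synthetic protein MSA with one strongly conserved gap-free block.

    Emulates an alignment of major-capsid proteins: a contiguous
    ``block_length``-column region (default columns [344, 404), echoing the
    345-404 residue convention on a gap-free reference row) is nearly
    identical across rows, flanks are divergent and gappy. Row 1 is gap-free
    throughout and serves as the coordinate reference. The consensus of the
    block starts with 'M' so it can be planted as an ORF directly.
    """
    rng = _rng(seed, 7)
    consensus = [_AA20[i] for i in rng.integers(0, 20, size=n_columns)]
    consensus[block_start] = "M"
    block_cols = range(block_start, block_start + block_length)
    rows = []
    for r in range(n_records):
        row = []
        for c in range(n_columns):
            aa = consensus[c]
            in_block = c in block_cols
            div = block_divergence if in_block else flank_divergence
            if r > 0 or not in_block:  # reference row keeps the exact block
                if rng.random() < div:
                    aa = _AA20[int(rng.integers(0, 20))]
            if r > 0 and not in_block and rng.random() < gap_fraction:
                aa = "-"
            row.append(aa)
        rows.append(
            SequenceRecord(
                id=f"{id_prefix}{r + 1:02d}",
                residues="".join(row),
                description="synthetic reference marker alignment row",
                alphabet=PROTEIN,
            )
        )
    block_consensus = "".join(consensus[block_start : block_start + block_length])
    return SyntheticMsa(rows, block_consensus, block_start, block_length)


def generate_host_targets(
    seed: int, n_chloroplast: int = 4, n_euk18s: int = 2, length: int = 120, gc: float = 0.5
) -> list[SequenceRecord]:
    """Short V9-scale nucleotide marker targets with taxon-labelled ids."""
    rng = _rng(seed, 8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for kind, count in (("chloroplast_16S_V9", n_chloroplast), ("euk_18S_V9", n_euk18s)):
        for i in range(count):
            arr = _BASES[rng.choice(4, size=length, p=p)]
            out.append(
                SequenceRecord(
                    id=f"{kind}_{i + 1:02d}",
                    residues=_as_str(arr),
                    description="synthetic marker target",
                    alphabet=NUCLEOTIDE,
                )
            )
    return out


def embed_in_read(
    insert: str,
    read_length: int,
    gc: float,
    seed: int,
    read_id: str,
    strand: str = "+",
    source: str = "planted",
) -> SequenceRecord:
    """A background-like read carrying one exact copy of ``insert``."""
    if len(insert) > read_length:
        raise ParameterError("insert longer than read")
    rng = _rng(seed, 9)
    pad = read_length - len(insert)
    left = int(rng.integers(0, pad + 1))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    flanks = _as_str(_BASES[rng.choice(4, size=pad, p=p)])
    seq = flanks[:left] + insert + flanks[left:]
    if strand == "-":
        seq = revcomp(seq)
    return SequenceRecord(
        id=read_id,
        residues=seq,
        description=format_provenance(source=source, insert_at=left, strand=strand, background=0),
        alphabet=NUCLEOTIDE,
    )


def embed_peptide_in_read(
    peptide: str,
    read_length: int,
    gc: float,
    seed: int,
    read_id: str,
    strand: str = "+",
    source: str = "planted_marker",
) -> SequenceRecord:
    """A read whose one frame encodes ``peptide`` exactly (for translated surveys)."""
    rng = _rng(seed, 10)
    coding = encode_peptide(peptide, gc, rng)
    return embed_in_read(coding, read_length, gc, seed + 1, read_id, strand, source)


# -- one-call community ------------------------------------------------------


@dataclass
class Community:
    """Everything one synthetic run produces, with ground truth attached."""

    config: CommunityConfig
    reference: SequenceRecord
    variants: list[SequenceRecord]
    reads: list[SequenceRecord]
    contigs: list[SequenceRecord]
    background: list[SequenceRecord]
    marker_peptide: str | None = None
    marker_position: int | None = None

    @property
    def all_reads(self) -> list[SequenceRecord]:
        return self.reads + self.background


def simulate_community(
    cfg: CommunityConfig,
    marker_peptide: str | None = None,
    marker_position: int = 1_200,
    marker_strand: str = "+",
) -> Community:
    """Generate a complete community under one configuration.

    If ``marker_peptide`` is given it is planted as an in-frame ORF before
    the population, reads and contigs are derived, so every downstream
    product carries the marker.
    """
    ref = generate_reference_genome(cfg)
    pos = None
    if marker_peptide is not None:
        ref = plant_marker_orf(
            ref, marker_peptide, marker_position, marker_strand,
            gc_fraction=cfg.gc_fraction, seed=cfg.rng_seed,
        )
        pos = marker_position
        # planting draws codons near the target G+C but not exactly at it;
        # rebalance bases outside the gene so the whole genome keeps the
        # configured base composition
        span = 3 * len(marker_peptide) + 3
        ref = _rebalance_gc(ref, cfg.gc_fraction, (pos, pos + span), cfg.rng_seed)
    if cfg.n_variants == 1 and cfg.divergence == 0.0:
        variants = [ref]
    else:
        variants = mutate_population(ref, cfg.n_variants, cfg.divergence, cfg.rng_seed)
    reads = simulate_reads(
        variants, cfg.mean_coverage, cfg.read_length, cfg.seq_error_rate, cfg.rng_seed
    )
    avoid = []
    if marker_peptide is not None:
        # keep the marker gene intact on a single contig (incl. stop codon)
        avoid.append((marker_position, marker_position + 3 * len(marker_peptide) + 3))
    contigs = fragment_genome(ref, cfg.n_contigs, cfg.rng_seed, avoid_intervals=avoid)
    rl = cfg.read_length if isinstance(cfg.read_length, int) else cfg.read_length[1]
    background = generate_background(cfg.background_reads, rl, cfg.gc_fraction, cfg.rng_seed)
    return Community(cfg, ref, variants, reads, contigs, background, marker_peptide, pos)
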