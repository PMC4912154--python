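# Methods

## Problem and approach

`viroseek` re-implements, as a tested pipeline, the analysis by which a
virophage population can be discovered and reconstructed from a shotgun
metagenome without cultivation:

1. **Marker survey.** Virophages share five core genes; the major capsid
   protein (MCP) is single-copy and carries a strongly conserved
   60-residue region, which makes it a usable survey marker. From a
   multiple alignment of reference MCPs the pipeline extracts the best
   gap-free 60-column window and screens six-frame-translated reads
   against it at >30% amino-acid identity over >55 aligned columns.
2. **Genome reconstruction.** Reads are recruited to assembled contigs at
   >95% nucleotide identity and >50% read coverage. Reads that map
   simultaneously onto two distinct contigs link contig ends; links with
   enough read support order and orient the contigs into a chain or
   cycle, which is merged. Terminal read overlap between the end and the
   beginning of the merged contig demonstrates a circular replicon.
3. **Population characterization.** The distribution of recruitment
   identities measures population structure: a mean identity above the
   90–95% band conventionally used for phage species demarcation, with
   most reads concentrated near 100%, indicates a single species-like
   population whose intrapopulation variation is `100 − mean identity`.
4. **Annotation and host surveys.** ORFs, G+C and gene content (shared
   homologues by reciprocal best hit at >30% identity / >50% query
   coverage) characterize the genome; SSU rRNA V9 (>70% / >90% target
   coverage) and a conserved phycodnavirus MCP block (>30% / >90% target
   coverage) survey the same community for candidate eukaryotic and
   giant-virus hosts.

Because the real lake metagenome is not redistributable at desk scale,
every stage is exercised end-to-end on synthetic communities with known
ground truth; the generator is first-class, tested code.

## Synthetic community model

`CommunityConfig` defaults encode the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 23,379 bp | circular virophage genome size |
| `gc_fraction` | 0.332 | genome G+C (exact by construction) |
| `n_variants` | 10 | genomes in the species-like population |
| `divergence` | 0.02 | per-site substitution rate, variant vs reference |
| `mean_coverage` | 56× | sequencing depth over the genome |
| `read_length` | 400 bp | fixed (a min/max pair draws uniform lengths) |
| `seq_error_rate` | 0.0 | per-base substitution error |
| `background_reads` | 2,000 | unrelated i.i.d. reads (true negatives) |
| `n_contigs` | 4 | fragments tiling the circle with zero overlap |

Choices the sources leave open, fixed here once: read length 400 bp (the
platform is not stated; 400 bp is typical of the pyrosequencing-era
datasets this kind of survey used), 10 population variants, and 2,000
background reads (enough for meaningful false-positive exposure without
dominating runtime). Reads are error-free by default so recruitment
identities reflect population divergence alone — this mirrors how the
98±2% identity band is interpreted as intrapopulation variation.

The model is deliberately idealized: substitutions only (no indels, so
identity algebra is exact), uniform read starts (the 9–100× coverage
spread emerges from Poisson fluctuation, not bias), no chimeras, no
quality model. Two scenario guarantees are built in because they are
premises of the emulated analysis, not outcomes of it: the planted
marker gene is kept intact on a single contig (the analysis starts from
an MCP-encoding contig), and after planting, bases outside the gene are
rebalanced so the configured G+C holds exactly. Consequently, passing
tests show the *pipeline logic* is correct under its stated assumptions;
they do not show robustness to indel divergence, coverage bias or
assembler chimeras in real data.

All randomness flows from one seeded NumPy generator per operation, with
distinct stream offsets per operation, so identical seed + configuration
is byte-identical and sibling operations do not couple.

## Marker block

Per-column conservation is mean pairwise identity among non-gap residues
(0 when fewer than two residues) — order-independent and exactly
checkable by enumeration. The block is the best strictly contiguous
window of exactly 60 columns whose every column satisfies the gap cap
(default: gap-free, because the marker is a single consecutive segment);
ties go to the leftmost window. Reference coordinates are reported
1-based inclusive on the ungapped reference row, in the style
"positions 345–404"; the mapped span is ≤ 60 with equality iff the
reference is gap-free in the block.

## Alignment engine and filters

Protein scoring is BLOSUM62 with affine gaps (open 11, extend 1);
nucleotide scoring is +2/−3 with gaps (open 5, extend 2) — widespread
defaults, since the emulated searches name tools, not parameters.
Percent identity is counted over all alignment columns *including gap
columns*, and every cut-off is a strict inequality (the filters are
quoted as ">30%", ">55", ">95%", …). E-values are deliberately not
computed; identity cut-offs are database-size-independent.

`align_local` computes optimal Smith–Waterman local alignment
(Biopython's pairwise aligner). Read recruitment against long contigs
would be prohibitively slow that way, so `recruit_reads` uses an exact
15-mer seeded gapless extension: candidate (contig, strand, diagonal)
triples come from a k-mer index, and the optimal *ungapped* local
alignment on the best-supported diagonal is found by max-sum subarray.
Under the substitution-only community model this equals the full gapped
optimum; when the gapless hit misses the identity cut-off by <5 points,
or seed support is scattered across diagonals (possible indels), the
read is realigned with full windowed dynamic programming. An exhaustive
`method="exact"` path exists for verification, and the test suite checks
the production aligner against an independent full Gotoh DP oracle on
hundreds of random instances.

Recruitment keeps the top alignment per (read, contig) but lets a read
retain hits on several contigs — contig linking depends on reads mapped
to two contigs at once. Alignments failing *only* the query-coverage
criterion (the short side of a junction-spanning read) are kept
separately as link evidence instead of being discarded.

## Reconstruction

A read links two contig ends when its two alignments consume disjoint
read intervals (≤10 bp overlap), jointly cover >90% of the read, and
each alignment abuts its contig end within 10 bp. These tolerances are
small relative to 400 bp reads and configurable; the sources give none.
Edges need ≥2 supporting reads (plural "reads", no number stated; 2
guards against single chimeras). Any contig end with more than one edge
is an ambiguity *error*, not a heuristic resolution — silent branch
resolution would hide chimeras.

Merging concatenates oriented contigs; junction sequence is the
per-column majority over the linking reads' inter-alignment bases (empty
for abutting contigs, the constructed case). Circularity requires ≥2
reads aligning across the seam of an end⧺start probe (arm length
2× read length) with ≥20 aligned bases on each side, at the recruitment
thresholds — this operationalizes "reads successively overlapped between
the end and beginning of the contig". Circular outputs are canonicalized
by rotating the marker ORF to position 0 on the forward strand, or,
anchorless, to the lexicographically minimal rotation of
min(seq, revcomp(seq)) (Booth's algorithm), so any two reconstructions
of the same circle compare equal as strings.

The identity band "98±2%" is read as the closed interval [96, 100]; the
species verdict requires mean identity strictly above 95.

## Annotation

The ORF caller is a deterministic stand-in for heuristic-model gene
predictors: maximal stop-bounded segments in all six frames, from the
first ATG under strict-start mode, ≥60 aa by default, with wrap-around
handled by scanning the doubled sequence and deduplicating on
(strand, start mod L, span). On random synthetic genomes at 33% G+C this
yields few ORFs (~8 at 23 kb) because random sequence is stop-dense —
the published gene count of a real virophage genome is a property of
real coding sequence and of the predictor, and is not reproduced here.
Shared gene homologues are counted by reciprocal best hit (the counting
procedure is not otherwise specified); "average amino acid identity" is
the unweighted mean over homologue pairs. The genome summary flags size
and G+C against the virophage envelope (17–28 kbp, 26–38%).

## Numerical and degenerate-input choices

- Window means in block extraction compare with a 1e-12 guard; column
  scores are small-denominator rationals, so genuine near-ties below
  ~1e-4 do not occur and exact ties resolve leftmost.
- Best-hit ties break by identity, then lexicographic target id, then
  frame order (+1,+2,+3,−1,−2,−3); strand ties prefer '+'.
- Reads shorter than one codon translate to nothing; alignments with
  score ≤0 are "no hit"; a survey over an empty dataset reports zero,
  not an error; a genome with no unambiguous bases has undefined G+C
  (error).
- `identity_pct` is computed as `100*identities/columns` in one float
  expression, so integral percentages (95.0, 30.0) are exact and strict
  cut-off comparisons at the boundary are reliable.

## Problem sizes

Test and acceptance runs use the full study scale where it matters: the
exact-recovery check runs 20 independent 23,379 bp communities at 56×
(≈3,270 reads each), and the population-characterization run uses the
default 2%-divergence community. Unit tests use 2–8 kb genomes. The
whole suite runs in ~1.5 min on one CPU; `scripts/acceptance.py` in
~1.5 min.

## Known limitations

- No indel handling in the population model, and the seeded recruiter is
  only guaranteed optimal for substitution-only divergence.
- Branching link graphs abort rather than resolve; repeat-rich genomes
  are out of scope (no de novo assembly, no mate pairs).
- The ORF caller has no coding-potential model; gene counts on real
  genomes will differ from heuristic-model predictors.
- Host-survey taxon labels come from target id prefixes, not taxonomy.
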