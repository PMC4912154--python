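import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from viroseek.marker_block import MultipleAlignment, extract_conserved_block
from viroseek.synthetic_community import (
    CommunityConfig,
    generate_marker_msa,
    simulate_community,
)

MSA_SEED = 11


@pytest.fixture(scope="session")
def marker_msa():
    return generate_marker_msa(MSA_SEED)


@pytest.fixture(scope="session")
def marker_block_obj(marker_msa):
    msa = MultipleAlignment(marker_msa.records)
    return extract_conserved_block(msa, ref_id="MCP01")


@pytest.fixture(scope="session")
def small_community(marker_msa):
    """A fast community: 6 kb genome, no divergence, light background."""
    cfg = CommunityConfig(
        genome_length=6_000,
        mean_coverage=30,
        n_variants=1,
        divergence=0.0,
        background_reads=100,
        n_contigs=3,
        rng_seed=7,
    )
    return simulate_community(cfg, marker_peptide=marker_msa.consensus_block)


@pytest.fixture(scope="session")
def diverged_community(marker_msa):
    """Full study conditions: 23,379 bp, 2% divergence, 56x, 400 bp reads."""
    cfg = CommunityConfig(rng_seed=101)
    return simulate_community(cfg, marker_peptide=marker_msa.consensus_block)
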