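from __future__ import annotations

import numpy as np
import pytest

from enuscan.datasets import load_reported_filter_counts, load_reported_region_splits
from enuscan.fixture import fixture_from_tables
from enuscan.io import ReferenceSequence
from enuscan.model import GeneModel
from enuscan.simulate import ScreenConfig, simulate_screen


@pytest.fixture(scope="session")
def sim_screen():
    """One error-free default-condition simulated screen."""
    return simulate_screen(ScreenConfig(seed=5, error_rate=0.0))


@pytest.fixture(scope="session")
def table_fixtures():
    """Deterministic fixtures laid out from the bundled worked-example tables."""
    return fixture_from_tables(
        load_reported_filter_counts(), load_reported_region_splits()
    )


@pytest.fixture(scope="session")
def tri_locus():
    """A hand-built three-transcript locus for annotator stress tests.

    Two overlapping coding transcripts on opposite strands (different
    frames) plus one non-coding transcript, over a seeded random
    reference; intergenic sequence on both ends.
    """
    rng = np.random.default_rng(424242)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
    ref = ReferenceSequence({"locus": seq})
    genes = [
        GeneModel(
            gene_id="gA", transcript_id="gA.t1", chrom="locus", strand="+",
            exons=((200, 500), (700, 1000), (1200, 1400)),
            cds_start=300, cds_end=1300,  # spliced CDS: 200+300+100 = 600 bp
        ),
        GeneModel(
            gene_id="gB", transcript_id="gB.t1", chrom="locus", strand="-",
            exons=((800, 1100), (1500, 2000)),
            cds_start=901, cds_end=1900,  # spliced CDS: 199+400... adjusted below
        ),
        GeneModel(
            gene_id="gC", transcript_id="gC.t1", chrom="locus", strand="+",
            exons=((2100, 2300), (2500, 2700)),
            cds_start=2100, cds_end=2100,  # non-coding
        ),
    ]
    # make both CDS lengths multiples of 3
    assert sum(
        max(0, min(e, 1300) - max(s, 300)) for s, e in genes[0].exons
    ) % 3 == 0
    cds_len_b = sum(max(0, min(e, 1900) - max(s, 901)) for s, e in genes[1].exons)
    trim = cds_len_b % 3
    if trim:
        genes[1] = GeneModel(
            gene_id="gB", transcript_id="gB.t1", chrom="locus", strand="-",
            exons=((800, 1100), (1500, 2000)),
            cds_start=901, cds_end=1900 - trim,
        )
    return ref, genes
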