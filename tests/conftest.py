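"""Shared fixtures: small deterministic genomes and alignment records."""
from __future__ import annotations

import numpy as np
import pytest

from ampliconcn import AlignmentRecord, FamilyAnnotation, GeneInterval, GenomeBundle


def random_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_record(
    start: int = 0,
    chrom: str = "chr",
    proper: bool = True,
    n_mismatch_prefix: int = 0,
    read_len: int = 101,
    prefix_len: int = 90,
    **kwargs,
) -> AlignmentRecord:
    """A synthetic alignment with the given number of mismatches in the prefix."""
    profile = np.ones(read_len, dtype=bool)
    profile[:n_mismatch_prefix] = False
    assert n_mismatch_prefix <= prefix_len
    return AlignmentRecord(
        read_id=kwargs.pop("read_id", f"r{start}"),
        chrom=chrom,
        start=start,
        is_proper_pair=proper,
        match_profile=profile,
        **kwargs,
    )


@pytest.fixture
def two_gene_bundle() -> GenomeBundle:
    """~6 kb toy: unique flanks around a 2-copy family (exact duplicates)."""
    gene = random_seq(400, 7)
    flank_a = random_seq(2000, 1)
    flank_b = random_seq(1200, 2)
    flank_c = random_seq(2000, 3)
    seq = flank_a + gene + flank_b + gene + flank_c
    g1 = (len(flank_a), len(flank_a) + len(gene))
    g2 = (g1[1] + len(flank_b), g1[1] + len(flank_b) + len(gene))
    ann = FamilyAnnotation(
        {
            "FAM": [
                GeneInterval("FAM_1", "chrT", *g1),
                GeneInterval("FAM_2", "chrT", *g2),
            ]
        }
    )
    return GenomeBundle({"chrT": seq}, "chrT", ann)
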