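"""Control/informative site selection and build artifacts."""
from __future__ import annotations

import numpy as np
import pytest

from ampliconcn import (
    FamilyAnnotation,
    GeneInterval,
    GenomeBundle,
    RunConfig,
    compute_kmer_uniqueness,
    enumerate_kmer_hits,
    read_build_artifacts,
    run_build,
    select_control_sites,
    select_informative_sites,
    write_build_artifacts,
)

from conftest import random_seq

K = 31
CFG = RunConfig(k=K)


def build_bundle(n_copies: int, with_repeat: bool = False, extra_unannotated: bool = False):
    """Flank + n exact gene copies (+ optional repeat interval / stray copy)."""
    gene = random_seq(300, 70)
    parts = [random_seq(1500, 71)]
    genes = []
    pos = len(parts[0])
    for j in range(n_copies):
        genes.append(GeneInterval(f"G{j+1}", "chrT", pos, pos + len(gene)))
        parts.append(gene)
        pos += len(gene)
        spacer = random_seq(400, 72 + j)
        parts.append(spacer)
        pos += len(spacer)
    repeats = []
    if with_repeat:
        block = "ACGTG" * 80  # 400 bp low-complexity
        repeats.append(("chrT", pos, pos + len(block)))
        parts.append(block)
        pos += len(block)
    if extra_unannotated:
        parts.append(gene)  # a third, unannotated copy
        pos += len(gene)
    parts.append(random_seq(1500, 99))
    ann = FamilyAnnotation({"FAM": genes}) if genes else None
    return GenomeBundle({"chrT": "".join(parts)}, "chrT", ann, repeats)


def test_control_sites_exclude_repeats_and_genes():
    gb = build_bundle(2, with_repeat=True)
    track = compute_kmer_uniqueness(gb, k=K, max_edits=2)
    control = select_control_sites(track, gb)
    # independent set-difference oracle
    expected = set(np.nonzero(track.unique)[0])
    expected -= set(np.nonzero(gb.repeat_mask())[0])
    expected -= set(np.nonzero(gb.family_mask())[0])
    assert set(control.tolist()) == expected
    assert expected, "toy genome should retain control sites"
    # sortedness
    assert np.all(np.diff(control) > 0)


def test_no_control_baseline_raises():
    gb = build_bundle(0)
    track = compute_kmer_uniqueness(gb, k=K, max_edits=2)
    track.unique[:] = False
    with pytest.raises(ValueError, match="control baseline"):
        select_control_sites(track, gb)


def test_informative_requires_one_hit_per_gene(two_gene_bundle):
    sites = run_build(two_gene_bundle, CFG)
    inf = sites.informative_sites["FAM"]
    # exact duplicate copies: interior positions hit both copies -> informative
    assert inf["FAM_1"].size > 0 and inf["FAM_2"].size > 0
    hits = enumerate_kmer_hits(two_gene_bundle, k=K, max_mismatches=2, max_hits=15)
    for p in inf["FAM_1"][:20]:
        assert len(hits.hits(int(p))) == 2


def test_positions_in_repeats_are_never_informative():
    gb = build_bundle(2)
    # re-annotate: declare a repeat covering half of gene 1
    g1 = gb.family_annotation.intervals("FAM")[0]
    gb2 = GenomeBundle(
        gb.sequences,
        "chrT",
        gb.family_annotation,
        [("chrT", g1.start, g1.start + 150)],
    )
    sites = run_build(gb2, CFG)
    inf = sites.informative_sites["FAM"]["G1"]
    assert inf.size > 0
    assert not np.any(inf < g1.start + 150)


def test_hit_outside_family_disqualifies():
    # a third unannotated copy: every in-gene k-mer now has 3 hits, one of
    # them outside the family's intervals -> nothing is informative
    gb = build_bundle(2, extra_unannotated=True)
    sites = run_build(gb, CFG)
    with_extra = sum(v.size for v in sites.informative_sites["FAM"].values())
    assert with_extra == 0
    # sanity: without the stray copy the same construction is informative
    gb0 = build_bundle(2)
    sites0 = run_build(gb0, CFG)
    assert sum(v.size for v in sites0.informative_sites["FAM"].values()) > 0


def test_adding_identical_copy_shrinks_informative_and_control(two_gene_bundle):
    """Monotonicity: an extra identical copy can only remove sites."""
    sites2 = run_build(two_gene_bundle, CFG)
    gene = two_gene_bundle.sequences["chrT"][
        slice(*[
            getattr(two_gene_bundle.family_annotation.intervals("FAM")[0], a)
            for a in ("start", "end")
        ])
    ]
    seq3 = two_gene_bundle.sequences["chrT"] + random_seq(300, 88) + gene + random_seq(300, 89)
    base = len(two_gene_bundle.sequences["chrT"]) + 300
    genes = list(two_gene_bundle.family_annotation.intervals("FAM"))
    genes.append(GeneInterval("FAM_3", "chrT", base, base + len(gene)))
    gb3 = GenomeBundle({"chrT": seq3}, "chrT", FamilyAnnotation({"FAM": genes}))
    sites3 = run_build(gb3, CFG)
    for gid in ("FAM_1", "FAM_2"):
        assert set(sites3.informative_sites["FAM"][gid]) <= set(
            sites2.informative_sites["FAM"][gid]
        )
    # control positions on the shared prefix of the chromosome only shrink
    L = len(two_gene_bundle.sequences["chrT"]) - K
    c2 = set(p for p in sites2.control_sites.tolist() if p < L - 300)
    c3 = set(p for p in sites3.control_sites.tolist() if p < L - 300)
    assert c3 <= c2


def test_control_and_informative_are_disjoint_and_contained(two_gene_bundle):
    sites = run_build(two_gene_bundle, CFG)
    control = set(sites.control_sites.tolist())
    ann = two_gene_bundle.family_annotation
    for fam, genes in sites.informative_sites.items():
        for gid, pos in genes.items():
            g = next(x for x in ann.intervals(fam) if x.gene_id == gid)
            assert np.all((pos >= g.start) & (pos < g.end))
            assert not control & set(pos.tolist())


def test_family_with_no_informative_sites_warns():
    gb = build_bundle(2, extra_unannotated=True)
    track_hits = enumerate_kmer_hits(gb, k=K, max_mismatches=2, max_hits=15)
    with pytest.warns(UserWarning, match="no informative positions"):
        select_informative_sites(track_hits, gb)


def test_artifact_round_trip_and_determinism(two_gene_bundle, tmp_path):
    sites = run_build(two_gene_bundle, CFG)
    # add an empty family to exercise the zero-row case
    sites.informative_sites["EMPTY"] = {"E1": np.zeros(0, dtype=np.int64)}
    p1 = tmp_path / "a" / "build"
    p2 = tmp_path / "b" / "build"
    write_build_artifacts(sites, p1)
    write_build_artifacts(sites, p2)
    for suffix in (".sites.tsv", ".manifest.json"):
        assert p1.with_suffix(suffix).read_bytes() == p2.with_suffix(suffix).read_bytes()
    back = read_build_artifacts(p1)
    assert back.target_chrom == sites.target_chrom
    assert back.config == sites.config
    np.testing.assert_array_equal(back.control_sites, sites.control_sites)
    assert set(back.informative_sites) == set(sites.informative_sites)
    for fam in sites.informative_sites:
        for gid in sites.informative_sites[fam]:
            np.testing.assert_array_equal(
                back.informative_sites[fam][gid], sites.informative_sites[fam][gid]
            )
    import json

    manifest = json.loads(p1.with_suffix(".manifest.json").read_text())
    assert manifest["config"]["k"] == K
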