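"""Depth counting, GC correction and copy-number calling."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ampliconcn import (
    DepthTrack,
    GCBinStats,
    GCProfile,
    GenomeBundle,
    SiteTables,
    call_copy_numbers,
    compute_gc_profile,
    compute_start_depth,
    filter_alignment,
    fit_gc_bins,
    gc_correct_depth,
    qc_sample,
)
from ampliconcn.count import CopyNumberTable, gc_bin_of

from conftest import make_record, random_seq


# -- alignment filter ---------------------------------------------------
@pytest.mark.parametrize(
    "proper,n_mm,keep",
    [
        (True, 0, True),    # 90/90 matches
        (True, 2, True),    # 88/90: at the threshold
        (True, 3, False),   # 87/90: one below
        (False, 0, False),  # perfect but not a proper pair
    ],
)
def test_filter_alignment_boundary(proper, n_mm, keep):
    rec = make_record(proper=proper, n_mismatch_prefix=n_mm)
    assert filter_alignment(rec, min_matches=88, prefix_len=90) is keep


def test_filter_discards_short_and_flagged_reads():
    short = make_record(read_len=60)
    assert not filter_alignment(short)
    dup = make_record()
    dup.is_duplicate = True
    assert not filter_alignment(dup)
    sec = make_record()
    sec.is_secondary = True
    assert not filter_alignment(sec)


# -- start depth --------------------------------------------------------
def test_start_depth_counts_alignment_starts():
    gb = GenomeBundle({"chr": random_seq(500, 5)}, "chr")
    records = [make_record(10), make_record(10), make_record(11)]
    depth = compute_start_depth(records, gb)
    assert depth.values[10] == 2 and depth.values[11] == 1
    assert depth.values[12] == 0


def test_start_depth_masks_repeats_and_errors_when_empty():
    gb = GenomeBundle({"chr": random_seq(500, 5)}, "chr", repeat_intervals=[("chr", 100, 120)])
    depth = compute_start_depth([make_record(10)], gb)
    assert np.isnan(depth.values[100:120]).all()
    with pytest.raises(ValueError, match="empty sample"):
        compute_start_depth([], gb)


# -- GC profile ---------------------------------------------------------
def test_gc_profile_constant_and_alternating():
    gb = GenomeBundle({"g": "G" * 600}, "g")
    prof = compute_gc_profile(gb, 501)
    assert np.allclose(prof.gc_percent, 100.0)
    gb2 = GenomeBundle({"a": "AC" * 300}, "a")
    prof2 = compute_gc_profile(gb2, 501)
    # alternating bases: 50% up to the one-base asymmetry of an odd window
    assert np.allclose(prof2.gc_percent[260:340], 50.0, atol=100 / 501)


def test_gc_profile_hand_counted_window5():
    seq = "ACGTACGTACGTACGTACGT"  # GC at odd positions pattern: C,G alternate
    gb = GenomeBundle({"t": seq}, "t")
    prof = compute_gc_profile(gb, 5, chrom="t")
    # window centred at 2: ACGTA -> 2 GC of 5
    assert prof.gc_percent[2] == pytest.approx(100 * 2 / 5)
    # truncated left edge, centred at 0: ACG -> 2/3
    assert prof.gc_percent[0] == pytest.approx(100 * 2 / 3)
    with pytest.raises(ValueError, match="odd"):
        compute_gc_profile(gb, 500)


# -- GC bins ------------------------------------------------------------
def _stats_from(depths, gcs, n_bins=100):
    L = len(depths)
    depth = DepthTrack("c", np.asarray(depths, float))
    gc = GCProfile("c", np.asarray(gcs, float))
    return fit_gc_bins(depth, gc, np.arange(L), n_bins)


def test_gc_bins_single_bin_mean():
    stats = _stats_from([10.0, 20.0], [50.2, 50.7])
    assert stats.global_mean == 15.0
    assert stats.bin_means[50] == 15.0
    assert stats.bin_counts[50] == 2


def test_gc_bins_two_bins():
    stats = _stats_from([10.0, 20.0], [40.5, 60.5])
    assert stats.global_mean == 15.0
    assert stats.bin_means[40] == 10.0 and stats.bin_means[60] == 20.0
    # weighted bin means reproduce the global mean
    ok = stats.bin_counts > 0
    recon = (stats.bin_means[ok] * stats.bin_counts[ok]).sum() / stats.bin_counts.sum()
    assert recon == pytest.approx(stats.global_mean, rel=1e-12)


def test_gc_bin_of_boundaries():
    assert gc_bin_of(np.array([0.0, 99.99, 100.0]), 100).tolist() == [0, 99, 99]


def test_gc_correction_formula_and_identity():
    # D=10, mu=15, mu_b=10 -> 15
    stats = GCBinStats(100, np.full(100, np.nan), np.zeros(100, int), 15.0)
    stats.bin_means[50] = 10.0
    stats.bin_counts[50] = 5
    depth = DepthTrack("c", np.array([10.0]))
    gc = GCProfile("c", np.array([50.5]))
    corr = gc_correct_depth(depth, gc, stats)
    assert corr.values[0] == pytest.approx(15.0)


def test_gc_correction_single_bin_is_identity():
    rng = np.random.default_rng(0)
    d = rng.poisson(5, 200).astype(float)
    gc = np.full(200, 50.0)
    depth = DepthTrack("c", d)
    prof = GCProfile("c", gc)
    stats = fit_gc_bins(depth, prof, np.arange(200), 100)
    corr = gc_correct_depth(depth, prof, stats)
    np.testing.assert_allclose(corr.values, d, rtol=1e-12)


def test_gc_correction_conserves_control_mean():
    """Mean corrected depth over control sites equals mu exactly."""
    rng = np.random.default_rng(1)
    n = 5000
    gc = rng.uniform(30, 70, n)
    d = rng.poisson(4 + gc / 20, n).astype(float)  # GC-biased depth
    depth = DepthTrack("c", d)
    prof = GCProfile("c", gc)
    control = np.arange(n)
    stats = fit_gc_bins(depth, prof, control, 100)
    corr = gc_correct_depth(depth, prof, stats)
    assert np.nanmean(corr.values[control]) == pytest.approx(
        stats.global_mean, rel=1e-9
    )


def test_empty_bins_borrow_nearest_with_low_tie():
    stats = GCBinStats(10, np.full(10, np.nan), np.zeros(10, int), 3.0)
    stats.bin_means[[2, 6]] = [2.0, 4.0]
    stats.bin_counts[[2, 6]] = [1, 1]
    depth = DepthTrack("c", np.ones(5))
    gc = GCProfile("c", np.array([5.0, 25.0, 45.0, 65.0, 85.0]))  # bins 0,2,4,6,8
    corr = gc_correct_depth(depth, gc, stats)
    # bin0 -> borrows bin2 (2.0); bin4 equidistant to 2 and 6 -> lower GC
    # wins (2.0); bin8 -> borrows bin6 (4.0)
    assert corr.values[0] == pytest.approx(3.0 / 2.0)  # bin 0
    assert corr.values[1] == pytest.approx(3.0 / 2.0)  # bin 2 (populated)
    assert corr.values[2] == pytest.approx(3.0 / 2.0)  # bin 4 tie -> bin 2
    assert corr.values[3] == pytest.approx(3.0 / 4.0)  # bin 6 (populated)
    assert corr.values[4] == pytest.approx(3.0 / 4.0)  # bin 8 -> bin 6


def test_zero_mean_populated_bin_yields_nan_with_warning():
    stats = GCBinStats(10, np.full(10, np.nan), np.zeros(10, int), 3.0)
    stats.bin_means[[2, 6]] = [0.0, 4.0]
    stats.bin_counts[[2, 6]] = [5, 5]
    depth = DepthTrack("c", np.ones(2))
    gc = GCProfile("c", np.array([25.0, 65.0]))
    with pytest.warns(UserWarning, match="zero mean control depth"):
        corr = gc_correct_depth(depth, gc, stats)
    assert np.isnan(corr.values[0]) and np.isfinite(corr.values[1])


# -- copy calls ---------------------------------------------------------
def _sites(informative):
    return SiteTables("c", np.arange(10), informative)


def test_copy_call_identity_and_additivity():
    mu = 4.0
    corrected = DepthTrack("c", np.full(100, mu), kind="gc_corrected")
    stats = GCBinStats(100, np.full(100, np.nan), np.zeros(100, int), mu)
    sites = _sites(
        {"FAM": {"G1": np.arange(20, 30), "G2": np.arange(40, 50)}}
    )
    cn = call_copy_numbers(corrected, sites, stats)
    assert cn.gene_copy("G1") == pytest.approx(1.0)
    assert cn.family_copy("FAM") == pytest.approx(2.0)
    # additivity is exact
    assert cn.family_copy("FAM") == cn.genes["copy_count"].sum()


def test_gene_without_sites_is_missing_not_zero():
    mu = 4.0
    corrected = DepthTrack("c", np.full(100, mu), kind="gc_corrected")
    stats = GCBinStats(100, np.full(100, np.nan), np.zeros(100, int), mu)
    sites = _sites({"FAM": {"G1": np.arange(20, 30), "G2": np.zeros(0, np.int64)}})
    cn = call_copy_numbers(corrected, sites, stats)
    assert np.isnan(cn.gene_copy("G2"))
    assert cn.family_copy("FAM") == pytest.approx(1.0)  # G2 excluded, not zero
    assert cn.families["n_genes_used"].iloc[0] == 1


def test_scale_invariance_under_record_duplication():
    """Doubling every alignment doubles depths but leaves copy calls unchanged."""
    gb = GenomeBundle({"chr": random_seq(3000, 9)}, "chr")
    rng = np.random.default_rng(3)
    starts = rng.integers(0, 2800, 400)
    records = [make_record(int(s), read_id=f"r{i}") for i, s in enumerate(starts)]
    sites = SiteTables(
        "chr", np.arange(1000, 2000), {"FAM": {"G1": np.arange(100, 600)}}
    )
    prof = compute_gc_profile(gb, 501, chrom="chr")

    def call(recs):
        depth = compute_start_depth(recs, gb)
        stats = fit_gc_bins(depth, prof, sites.control_sites, 100)
        corr = gc_correct_depth(depth, prof, stats)
        return call_copy_numbers(corr, sites, stats), stats

    cn1, st1 = call(records)
    cn2, st2 = call(records + records)
    assert st2.global_mean == pytest.approx(2 * st1.global_mean, rel=1e-12)
    assert cn2.gene_copy("G1") == pytest.approx(cn1.gene_copy("G1"), rel=1e-9)


# -- sample QC ----------------------------------------------------------
def _cn_table(fam_values, sc_values=()):
    fams = pd.DataFrame(
        {
            "family": [f"F{i}" for i in range(len(fam_values))],
            "n_genes": 2,
            "n_genes_used": 2,
            "family_copy_count": fam_values,
        }
    )
    genes = pd.DataFrame(
        {
            "family": [f"S{i}" for i in range(len(sc_values))],
            "gene_id": [f"S{i}" for i in range(len(sc_values))],
            "n_informative": 10,
            "copy_count": sc_values,
        }
    )
    return CopyNumberTable(genes=genes, families=fams, control_mean_depth=1.0)


@pytest.mark.parametrize(
    "fam_values,sc_values,expect_pass",
    [
        ([3.0, 2.0, 4.0], [1.0, 1.0, 1.0], True),   # reference-like
        ([0.1, 0.2, 4.0], [1.0, 1.0, 1.0], False),  # two families near zero
        ([0.1, 2.0, 4.0], [1.0, 1.0, 1.0], True),   # one near zero tolerated
        ([3.0, 2.0, 4.0], [0.2, 0.3, 0.1], False),  # several low single-copy genes
        ([3.0, 2.0, 4.0], [0.2, 0.3, 1.0], True),   # only two low singles
    ],
)
def test_qc_rule_truth_table(fam_values, sc_values, expect_pass):
    amp = _cn_table(fam_values)
    sc = _cn_table([], sc_values)
    flag = qc_sample(amp, sc, near_zero_threshold=0.5, single_copy_floor=0.75, floor_count=3)
    assert flag.passed is expect_pass
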