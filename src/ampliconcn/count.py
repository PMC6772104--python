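"""Count stage: alignment filtering, start-depth, GC correction, copy calls.

The depth statistic is the number of retained alignments *starting* at each
position (D_i).  Retained means: part of a properly mapping pair, with at
least ``min_matches`` perfect matches among the first ``prefix_len`` bases of
the read (read orientation).  Depth is GC-corrected against the control
baseline: control depths are binned by the GC percentage of the 501-bp window
centred on each position; with bin means mu_b and global control mean mu, the
corrected depth is mu * D_i / mu_b.  A gene's copy number is the mean
corrected depth over its informative positions divided by mu; a family's copy
number is the sum over its genes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import RunConfig
from .genome import GenomeBundle

logger = logging.getLogger(__name__)


@dataclass
class AlignmentRecord:
    """One primary read alignment in 0-based coordinates.

    ``match_profile`` holds, per base of the read *in read orientation*,
    whether that base is aligned and identical to the reference (soft-clipped,
    inserted and mismatched bases are False; deletions consume no read
    bases).
    """

    read_id: str
    chrom: str
    start: int
    is_proper_pair: bool
    match_profile: np.ndarray
    is_reverse: bool = False
    mapped: bool = True
    is_secondary: bool = False
    is_duplicate: bool = False
    nm: int = 0
    seq: str | None = None
    is_first: bool = True
    mate_chrom: str | None = None
    mate_start: int = -1
    mate_is_reverse: bool = False
    tlen: int = 0

    @property
    def read_length(self) -> int:
        return len(self.match_profile)


@dataclass
class DepthTrack:
    """Per-position start-depth; NaN at repeat-masked (undefined) positions."""

    chrom: str
    values: np.ndarray
    kind: str = "raw"  # "raw" | "gc_corrected"


@dataclass
class GCProfile:
    """GC percentage of the window centred at each position (NaN if all-N)."""

    chrom: str
    gc_percent: np.ndarray
    window: int = 501


@dataclass
class GCBinStats:
    """Mean control depth per GC bin (mu_b) and the global control mean (mu)."""

    n_bins: int
    bin_means: np.ndarray   # NaN where the bin holds no control position
    bin_counts: np.ndarray
    global_mean: float


@dataclass
class SampleQCFlag:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        return "PASS" if self.passed else "FAIL"


@dataclass
class CopyNumberTable:
    """Per-gene copy counts, per-family sums, and sample-level QC.

    ``genes`` columns: family, gene_id, n_informative, copy_count (NaN when a
    gene has no informative site with a defined corrected depth — missing,
    not zero, to distinguish "undetectable" from "deleted").
    ``families`` columns: family, n_genes, n_genes_used, family_copy_count.
    """

    genes: pd.DataFrame
    families: pd.DataFrame
    control_mean_depth: float
    qc: SampleQCFlag | None = None

    def family_copy(self, family: str) -> float:
        row = self.families.loc[self.families["family"] == family]
        return float(row["family_copy_count"].iloc[0])

    def gene_copy(self, gene_id: str) -> float:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        return float(row["copy_count"].iloc[0])


# ----------------------------------------------------------------------
def filter_alignment(
    record: AlignmentRecord, min_matches: int = 88, prefix_len: int = 90
) -> bool:
    """Keep only proper-pair alignments with enough perfect leading matches."""
    if not record.mapped or record.is_secondary or record.is_duplicate:
        return False
    if not record.is_proper_pair:
        return False
    if record.read_length < prefix_len:
        return False
    return int(record.match_profile[:prefix_len].sum()) >= min_matches


def compute_start_depth(
    records: Iterable[AlignmentRecord],
    genome: GenomeBundle,
    chrom: str | None = None,
) -> DepthTrack:
    """Count retained alignments starting at each non-repeat-masked position."""
    chrom = chrom or genome.target_chrom
    L = genome.chrom_length(chrom)
    counts = np.zeros(L, dtype=np.int64)
    n_used = 0
    starts = []
    for rec in records:
        if rec.chrom != chrom:
            continue
        starts.append(rec.start)
        n_used += 1
        if len(starts) >= 1_000_000:
            np.add.at(counts, np.asarray(starts, dtype=np.int64), 1)
            starts = []
    if starts:
        np.add.at(counts, np.asarray(starts, dtype=np.int64), 1)
    if n_used == 0:
        raise ValueError("empty sample: no retained alignments on " + chrom)
    values = counts.astype(np.float64)
    values[genome.repeat_mask(chrom)] = np.nan
    return DepthTrack(chrom=chrom, values=values, kind="raw")


def compute_gc_profile(
    genome: GenomeBundle, window: int = 501, chrom: str | None = None
) -> GCProfile:
    """GC% of the centred window at every position; truncated at chromosome ends."""
    if window % 2 == 0:
        raise ValueError("GC window must be odd so it can be centred")
    chrom = chrom or genome.target_chrom
    codes = genome.encoded(chrom)
    L = codes.size
    half = window // 2
    is_gc = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2), dtype=np.int64)))
    is_base = np.concatenate(([0], np.cumsum(codes != 4, dtype=np.int64)))
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, L)
    num = is_gc[hi] - is_gc[lo]
    den = is_base[hi] - is_base[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(den > 0, 100.0 * num / np.maximum(den, 1), np.nan)
    return GCProfile(chrom=chrom, gc_percent=gc, window=window)


def gc_bin_of(gc_percent: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index: min(floor(gc * n_bins / 100), n_bins - 1); -1 for NaN."""
    out = np.full(gc_percent.shape, -1, dtype=np.int64)
    ok = np.isfinite(gc_percent)
    out[ok] = np.minimum(
        np.floor(gc_percent[ok] * n_bins / 100.0).astype(np.int64), n_bins - 1
    )
    return out


def fit_gc_bins(
    depth: DepthTrack,
    gc: GCProfile,
    control_sites: np.ndarray,
    n_bins: int = 100,
) -> GCBinStats:
    """Mean control depth per GC bin plus the global control mean."""
    if control_sites is None or len(control_sites) == 0:
        raise ValueError("no control sites supplied")
    if depth.chrom != gc.chrom:
        raise ValueError("depth and GC profile are on different chromosomes")
    d = depth.values[control_sites]
    g = gc.gc_percent[control_sites]
    ok = np.isfinite(d) & np.isfinite(g)
    if not ok.any():
        raise ValueError(
            "all control sites fall in repeat-masked or undefined positions"
        )
    d, g = d[ok], g[ok]
    bins = gc_bin_of(g, n_bins)
    bin_counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=d, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_means = np.where(bin_counts > 0, sums / np.maximum(bin_counts, 1), np.nan)
    return GCBinStats(
        n_bins=n_bins,
        bin_means=bin_means,
        bin_counts=bin_counts,
        global_mean=float(d.mean()),
    )


def _filled_bin_means(stats: GCBinStats) -> np.ndarray:
    """mu_b with empty bins borrowing from the nearest populated bin.

    Ties between equally near bins resolve toward lower GC; positive-count
    bins with mu_b == 0 stay NaN (depth there is undefined) with a warning.
    """
    means = stats.bin_means.copy()
    populated = np.nonzero(stats.bin_counts > 0)[0]
    if populated.size == 0:
        raise ValueError("no populated GC bins")
    zero_bins = populated[means[populated] == 0]
    if zero_bins.size:
        warnings.warn(
            f"{zero_bins.size} populated GC bin(s) have zero mean control depth; "
            "positions in them are undefined"
        )
        means[zero_bins] = np.nan
        populated = populated[means[populated] > 0]
        if populated.size == 0:
            raise ValueError("every populated GC bin has zero mean control depth")
    empty = np.nonzero(stats.bin_counts == 0)[0]
    if empty.size:
        right = np.searchsorted(populated, empty)
        left = np.clip(right - 1, 0, populated.size - 1)
        right = np.clip(right, 0, populated.size - 1)
        d_left = np.abs(empty - populated[left])
        d_right = np.abs(populated[right] - empty)
        nearest = np.where(d_left <= d_right, populated[left], populated[right])
        means[empty] = means[nearest]
    return means


def gc_correct_depth(
    depth: DepthTrack, gc: GCProfile, stats: GCBinStats
) -> DepthTrack:
    """Corrected depth mu * D_i / mu_b(i); undefined positions stay NaN."""
    means = _filled_bin_means(stats)
    bins = gc_bin_of(gc.gc_percent, stats.n_bins)
    mu_b = np.where(bins >= 0, means[np.maximum(bins, 0)], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = stats.global_mean * depth.values / mu_b
    return DepthTrack(chrom=depth.chrom, values=corrected, kind="gc_corrected")


def call_copy_numbers(
    corrected: DepthTrack,
    sites,  # SiteTables
    stats: GCBinStats,
) -> CopyNumberTable:
    """Per-gene copy = mean corrected depth at informative sites / mu; family = sum."""
    mu = stats.global_mean
    gene_rows = []
    fam_rows = []
    for fam in sorted(sites.informative_sites):
        genes = sites.informative_sites[fam]
        fam_total = 0.0
        n_used = 0
        for gene_id in sorted(genes):
            pos = genes[gene_id]
            vals = corrected.values[pos] if pos.size else np.zeros(0)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                copy = np.nan
            else:
                copy = float(vals.mean() / mu)
                fam_total += copy
                n_used += 1
            gene_rows.append(
                {
                    "family": fam,
                    "gene_id": gene_id,
                    "n_informative": int(pos.size),
                    "copy_count": copy,
                }
            )
        fam_rows.append(
            {
                "family": fam,
                "n_genes": len(genes),
                "n_genes_used": n_used,
                "family_copy_count": fam_total if n_used else np.nan,
            }
        )
        if n_used < len(genes):
            logger.warning(
                "family %s: %d gene(s) had no usable informative site and were "
                "excluded from the family sum",
                fam,
                len(genes) - n_used,
            )
    return CopyNumberTable(
        genes=pd.DataFrame(
            gene_rows, columns=["family", "gene_id", "n_informative", "copy_count"]
        ),
        families=pd.DataFrame(
            fam_rows,
            columns=["family", "n_genes", "n_genes_used", "family_copy_count"],
        ),
        control_mean_depth=mu,
    )


def qc_sample(
    cn: CopyNumberTable,
    single_copy_cn: CopyNumberTable | None = None,
    near_zero_threshold: float = 0.5,
    single_copy_floor: float = 0.75,
    floor_count: int = 3,
) -> SampleQCFlag:
    """Flag samples with implausible estimates.

    FAIL when two or more ampliconic families are close to zero, or when at
    least ``floor_count`` single-copy genes fall below ``single_copy_floor``.
    """
    reasons = []
    fam_vals = cn.families["family_copy_count"].to_numpy(float)
    n_near_zero = int(np.sum(np.nan_to_num(fam_vals, nan=np.inf) < near_zero_threshold))
    if n_near_zero >= 2:
        reasons.append(
            f"{n_near_zero} gene families with copy number < {near_zero_threshold}"
        )
    if single_copy_cn is not None:
        sc_vals = single_copy_cn.genes["copy_count"].to_numpy(float)
        n_low = int(np.sum(np.nan_to_num(sc_vals, nan=np.inf) < single_copy_floor))
        if n_low >= floor_count:
            reasons.append(
                f"{n_low} single-copy genes with copy number < {single_copy_floor}"
            )
    return SampleQCFlag(passed=not reasons, reasons=reasons)


# ----------------------------------------------------------------------
def split_single_copy(sites) -> tuple[list[str], list[str]]:
    """Partition families into (multi-copy, single-copy) panels by annotation."""
    multi, single = [], []
    for fam, genes in sites.informative_sites.items():
        (single if len(genes) == 1 else multi).append(fam)
    return sorted(multi), sorted(single)


def _subset_table(cn: CopyNumberTable, fams: list[str]) -> CopyNumberTable:
    return CopyNumberTable(
        genes=cn.genes[cn.genes["family"].isin(fams)].reset_index(drop=True),
        families=cn.families[cn.families["family"].isin(fams)].reset_index(drop=True),
        control_mean_depth=cn.control_mean_depth,
        qc=cn.qc,
    )


def run_count(
    genome: GenomeBundle,
    sites,  # SiteTables
    records: Iterable[AlignmentRecord],
    config: RunConfig | None = None,
) -> CopyNumberTable:
    """Full count stage: filter, depth, GC-correct, call, QC."""
    config = config or RunConfig()
    retained = (
        r
        for r in records
        if filter_alignment(r, config.min_matches, config.prefix_len)
    )
    depth = compute_start_depth(retained, genome)
    gc = compute_gc_profile(genome, config.gc_window)
    stats = fit_gc_bins(depth, gc, sites.control_sites, config.gc_bins)
    corrected = gc_correct_depth(depth, gc, stats)
    cn = call_copy_numbers(corrected, sites, stats)
    multi, single = split_single_copy(sites)
    cn.qc = qc_sample(
        _subset_table(cn, multi),
        _subset_table(cn, single) if single else None,
        config.near_zero_threshold,
        config.single_copy_floor,
        config.single_copy_floor_count,
    )
    return cn


def write_copy_number_table(
    cn: CopyNumberTable, path: str | Path, config: RunConfig | None = None
) -> Path:
    """TSV with one row per gene and a `gene_id="*"` summary row per family."""
    path = Path(path)
    fam_copy = dict(
        zip(cn.families["family"], cn.families["family_copy_count"])
    )
    rows = []
    for fam in sorted(fam_copy):
        sub = cn.genes[cn.genes["family"] == fam]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "family": fam,
                    "gene_id": r["gene_id"],
                    "n_informative": int(r["n_informative"]),
                    "gene_copy": r["copy_count"],
                    "family_copy": fam_copy[fam],
                    "control_mean_depth": cn.control_mean_depth,
                    "qc_flag": str(cn.qc) if cn.qc else "NA",
                }
            )
        rows.append(
            {
                "family": fam,
                "gene_id": "*",
                "n_informative": int(sub["n_informative"].sum()),
                "gene_copy": np.nan,
                "family_copy": fam_copy[fam],
                "control_mean_depth": cn.control_mean_depth,
                "qc_flag": str(cn.qc) if cn.qc else "NA",
            }
        )
    out = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if config is not None:
            import json

            fh.write("# config: " + json.dumps(config.to_dict(), sort_keys=True) + "\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path
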