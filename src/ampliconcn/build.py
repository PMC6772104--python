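"""Build stage: derive control and informative positions from a reference.

Copy number is later read off per-position depth, so the build stage must
pick positions where depth is interpretable:

* *control* positions calibrate the depth of copy number one.  A position
  qualifies when the k-mer starting there occurs nowhere else in the genome
  within the edit budget (substitutions), and it lies outside annotated
  repeats and outside every annotated gene copy.
* *informative* positions are where depth predicts a gene's copy number.  A
  position inside a gene copy qualifies when (1) it is outside annotated
  repeats, (2) every location its k-mer matches (<= the mismatch budget,
  capped at ``max_hits``) falls within the gene copies of its own family, and
  (3) the number of such matches equals the number of copies in the family —
  i.e. the k-mer occurs exactly once per copy.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .genome import GenomeBundle
from .kmer import scan_hits

logger = logging.getLogger(__name__)

CONTROL_LABEL = "CONTROL"


@dataclass
class MappabilityTrack:
    """Per-position k-mer uniqueness on one chromosome.

    ``unique[p]`` is True iff the k-mer starting at p occurs nowhere else in
    the genome (either strand) within ``max_edits`` substitutions.  Positions
    whose window runs off the chromosome or contains N are False.
    """

    chrom: str
    k: int
    max_edits: int
    unique: np.ndarray


@dataclass
class KmerHitIndex:
    """All (<= max_hits) genome locations matched by each target k-mer.

    Stored in CSR form over ``positions`` (local coordinates on ``chrom``);
    hit loci are (chrom_name, local_pos, mismatches), ordered by (chromosome
    order, position), with the self-hit always retained when truncation
    applies.
    """

    chrom: str
    k: int
    max_mismatches: int
    max_hits: int
    positions: np.ndarray          # sorted local positions with an N-free k-mer
    hit_ptr: np.ndarray            # CSR pointers, len(positions)+1
    hit_chrom: list[str] = field(repr=False, default_factory=list)
    hit_pos: np.ndarray = field(repr=False, default=None)
    hit_mm: np.ndarray = field(repr=False, default=None)

    _pos_lookup: dict = field(repr=False, default=None)

    def n_hits(self) -> np.ndarray:
        return np.diff(self.hit_ptr)

    def hits(self, pos: int) -> list[tuple[str, int, int]]:
        if self._pos_lookup is None:
            object.__setattr__(
                self, "_pos_lookup", {int(p): i for i, p in enumerate(self.positions)}
            )
        i = self._pos_lookup.get(int(pos))
        if i is None:
            return []
        sl = slice(self.hit_ptr[i], self.hit_ptr[i + 1])
        return [
            (self.hit_chrom[j], int(self.hit_pos[j]), int(self.hit_mm[j]))
            for j in range(sl.start, sl.stop)
        ]


@dataclass
class SiteTables:
    """Output of the build stage: where depth will be measured."""

    target_chrom: str
    control_sites: np.ndarray
    informative_sites: dict[str, dict[str, np.ndarray]]
    config: RunConfig = field(default_factory=RunConfig)

    def n_informative(self, family: str) -> int:
        return int(sum(v.size for v in self.informative_sites[family].values()))


# ----------------------------------------------------------------------
def compute_kmer_uniqueness(
    genome: GenomeBundle,
    k: int = 101,
    max_edits: int = 2,
    chrom: str | None = None,
) -> MappabilityTrack:
    """Mark positions whose k-mer is unique in the genome within max_edits.

    Both strands are considered; a reverse-complement occurrence elsewhere
    makes a position non-unique.  Windows containing N are non-unique.
    """
    if k < 1 or max_edits < 0:
        raise ValueError("k must be >= 1 and max_edits >= 0")
    chrom = chrom or genome.target_chrom
    L = genome.chrom_length(chrom)
    unique = np.zeros(L, dtype=bool)
    if L < k:
        warnings.warn(
            f"chromosome {chrom} shorter than k={k}; empty mappability track"
        )
        return MappabilityTrack(chrom, k, max_edits, unique)
    index = genome.kmer_index(k)
    queries = index.query_positions(chrom, k)
    counts, _ = scan_hits(index, k, max_edits, queries)
    local = queries - index.offsets[chrom]
    unique[local[counts == 1]] = True
    return MappabilityTrack(chrom, k, max_edits, unique)


def _cap_hits(
    pq: np.ndarray,
    pc: np.ndarray,
    pm: np.ndarray,
    query_concat: np.ndarray,
    max_hits: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncate per-query hit lists (sorted by locus) at max_hits, keeping self.

    pq must be sorted by (query, locus), as produced by scan_hits.
    """
    if pq.size == 0:
        return pq, pc, pm
    n_q = int(pq.max()) + 1
    counts = np.bincount(pq, minlength=n_q)
    starts = np.concatenate(([0], np.cumsum(counts)))
    rank = np.arange(pq.size) - starts[pq]
    keep = rank < max_hits
    # force-include the self-hit where truncation would drop it
    is_self = pc == query_concat[pq]
    dropped_self = is_self & ~keep
    if dropped_self.any():
        for row in np.nonzero(dropped_self)[0]:
            q = pq[row]
            last_kept = starts[q] + max_hits - 1
            keep[last_kept] = False
            keep[row] = True
    return pq[keep], pc[keep], pm[keep]


def enumerate_kmer_hits(
    genome: GenomeBundle,
    k: int = 101,
    max_mismatches: int = 2,
    max_hits: int = 15,
    positions: np.ndarray | None = None,
    chrom: str | None = None,
) -> KmerHitIndex:
    """List every genome location each target k-mer matches within the budget.

    Emulates mapping all k-mers of the target chromosome back to the genome,
    keeping at most ``max_hits`` alignments per k-mer and discarding any with
    more than ``max_mismatches`` substitutions.  Hit lists are ordered by
    (chromosome order, position) before the cap is applied; the self-hit is
    always retained.
    """
    chrom = chrom or genome.target_chrom
    index = genome.kmer_index(k)
    if positions is None:
        q_concat = index.query_positions(chrom, k)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        q_concat = positions + index.offsets[chrom]
        ok = index.valid_start(k)[q_concat] & index.window_n_free(k)[q_concat]
        q_concat = np.sort(q_concat[ok])
    counts, (pq, pc, pm) = scan_hits(index, k, max_mismatches, q_concat)
    pq, pc, pm = _cap_hits(pq, pc, pm, q_concat, max_hits)
    n_q = q_concat.size
    ptr = np.zeros(n_q + 1, dtype=np.int64)
    np.cumsum(np.bincount(pq, minlength=n_q), out=ptr[1:])
    cid, local_hits = index.to_local(pc)
    return KmerHitIndex(
        chrom=chrom,
        k=k,
        max_mismatches=max_mismatches,
        max_hits=max_hits,
        positions=q_concat - index.offsets[chrom],
        hit_ptr=ptr,
        hit_chrom=[index.names[c] for c in cid],
        hit_pos=local_hits,
        hit_mm=pm,
    )


def select_control_sites(
    mappability: MappabilityTrack, genome: GenomeBundle
) -> np.ndarray:
    """Unique positions outside repeats and outside annotated gene copies.

    These model copy number one: the depth baseline must come from sequence
    present exactly once, so even a unique position inside an annotated gene
    copy is excluded.
    """
    chrom = mappability.chrom
    ok = mappability.unique & ~genome.repeat_mask(chrom) & ~genome.family_mask(chrom)
    sites = np.nonzero(ok)[0].astype(np.int64)
    if sites.size == 0:
        raise ValueError("no control baseline: zero positions survive filtering")
    return sites


def select_informative_sites(
    hits: KmerHitIndex, genome: GenomeBundle
) -> dict[str, dict[str, np.ndarray]]:
    """Per-family, per-gene informative positions from a k-mer hit index."""
    chrom = hits.chrom
    index = genome.kmer_index(hits.k)
    repeat = genome.repeat_mask(chrom)
    pos = hits.positions
    nh = hits.n_hits()
    # hit loci in concatenated coordinates for fast mask lookup
    name_off = {n: index.offsets[n] for n in index.names}
    hit_concat = np.array(
        [name_off[c] for c in hits.hit_chrom], dtype=np.int64
    ) + hits.hit_pos if hits.hit_pos is not None and len(hits.hit_chrom) else np.zeros(0, np.int64)

    out: dict[str, dict[str, np.ndarray]] = {}
    for fam in genome.family_annotation:
        genes = genome.family_annotation.intervals(fam)
        n_genes = len(genes)
        fam_mask = np.zeros(index.length, dtype=bool)
        for g in genes:
            off = name_off[g.chrom]
            fam_mask[off + g.start : off + g.end] = True
        # a hit is family-specific when its start lies inside the family's copies
        bad_hit = ~fam_mask[hit_concat] if hit_concat.size else np.zeros(0, bool)
        if pos.size:
            # CSR reduction: per-row count of out-of-family hits
            csum = np.concatenate(([0], np.cumsum(bad_hit, dtype=np.int64)))
            n_bad = csum[hits.hit_ptr[1:]] - csum[hits.hit_ptr[:-1]]
        else:
            n_bad = np.zeros(0, dtype=np.int64)
        family_specific = (n_bad == 0) & (nh == n_genes)
        fam_out: dict[str, np.ndarray] = {}
        for g in genes:
            if g.chrom != chrom:
                fam_out[g.gene_id] = np.zeros(0, dtype=np.int64)
                continue
            lo = np.searchsorted(pos, g.start)
            hi = np.searchsorted(pos, g.end)
            in_gene = pos[lo:hi]
            ok = family_specific[lo:hi] & ~repeat[in_gene]
            fam_out[g.gene_id] = in_gene[ok]
        if all(v.size == 0 for v in fam_out.values()):
            warnings.warn(
                f"family {fam}: no informative positions in any gene copy; "
                "its estimate will be reported as missing"
            )
        out[fam] = fam_out
    return out


def run_build(genome: GenomeBundle, config: RunConfig | None = None) -> SiteTables:
    """Full build stage with a single shared k-mer scan.

    Equivalent to compute_kmer_uniqueness + enumerate_kmer_hits +
    select_control_sites + select_informative_sites, but the genome is
    scanned once: uniqueness needs only match counts, and per-hit detail is
    kept only for positions inside annotated gene copies.
    """
    config = config or RunConfig()
    chrom = genome.target_chrom
    if config.max_edits != config.max_mismatches:
        # distinct budgets need two scans; compose the individual operations
        track = compute_kmer_uniqueness(genome, config.k, config.max_edits, chrom)
        control = select_control_sites(track, genome)
        fam_pos = np.nonzero(genome.family_mask(chrom))[0]
        hit_index = enumerate_kmer_hits(
            genome, config.k, config.max_mismatches, config.max_hits, positions=fam_pos
        )
        informative = select_informative_sites(hit_index, genome)
        return SiteTables(chrom, control, informative, config)
    index = genome.kmer_index(config.k)
    queries = index.query_positions(chrom, config.k)
    if queries.size == 0:
        raise ValueError(f"chromosome {chrom} yields no valid {config.k}-mers")
    fam_mask_local = genome.family_mask(chrom)
    collect = fam_mask_local[queries - index.offsets[chrom]]
    counts, (pq, pc, pm) = scan_hits(
        index, config.k, config.max_edits, queries, collect_mask=collect
    )
    local = queries - index.offsets[chrom]
    unique = np.zeros(genome.chrom_length(chrom), dtype=bool)
    unique[local[counts == 1]] = True
    track = MappabilityTrack(chrom, config.k, config.max_edits, unique)
    control = select_control_sites(track, genome)

    pq, pc, pm = _cap_hits(pq, pc, pm, queries, config.max_hits)
    sel = np.nonzero(collect)[0]
    remap = -np.ones(queries.size, dtype=np.int64)
    remap[sel] = np.arange(sel.size)
    ptr = np.zeros(sel.size + 1, dtype=np.int64)
    np.cumsum(np.bincount(remap[pq], minlength=sel.size), out=ptr[1:])
    cid, local_hits = index.to_local(pc)
    hit_index = KmerHitIndex(
        chrom=chrom,
        k=config.k,
        max_mismatches=config.max_mismatches,
        max_hits=config.max_hits,
        positions=local[sel],
        hit_ptr=ptr,
        hit_chrom=[index.names[c] for c in cid],
        hit_pos=local_hits,
        hit_mm=pm,
    )
    informative = select_informative_sites(hit_index, genome)
    return SiteTables(
        target_chrom=chrom,
        control_sites=control,
        informative_sites=informative,
        config=config,
    )


# ----------------------------------------------------------------------
def write_build_artifacts(
    sites: SiteTables, prefix: str | Path, extra_manifest: dict | None = None
) -> tuple[Path, Path]:
    """Serialise site tables to `<prefix>.sites.tsv` + `<prefix>.manifest.json`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "chrom": sites.target_chrom,
            "pos": int(p),
            "family": CONTROL_LABEL,
            "gene_id": "*",
        }
        for p in sites.control_sites
    ]
    for fam in sorted(sites.informative_sites):
        for gene_id in sorted(sites.informative_sites[fam]):
            for p in sites.informative_sites[fam][gene_id]:
                rows.append(
                    {
                        "chrom": sites.target_chrom,
                        "pos": int(p),
                        "family": fam,
                        "gene_id": gene_id,
                    }
                )
    table = pd.DataFrame(rows, columns=["chrom", "pos", "family", "gene_id"])
    sites_path = prefix.with_suffix(".sites.tsv")
    table.to_csv(sites_path, sep="\t", index=False)
    manifest = {
        "target_chrom": sites.target_chrom,
        "config": sites.config.to_dict(),
        "n_control": int(sites.control_sites.size),
        "n_informative": {
            fam: sites.n_informative(fam) for fam in sorted(sites.informative_sites)
        },
        "genes": {
            fam: sorted(sites.informative_sites[fam])
            for fam in sorted(sites.informative_sites)
        },
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = prefix.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return sites_path, manifest_path


def read_build_artifacts(prefix: str | Path) -> SiteTables:
    """Inverse of write_build_artifacts."""
    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".manifest.json").read_text())
    table = pd.read_csv(prefix.with_suffix(".sites.tsv"), sep="\t")
    control = table.loc[table["family"] == CONTROL_LABEL, "pos"].to_numpy(np.int64)
    informative: dict[str, dict[str, np.ndarray]] = {}
    fam_rows = table[table["family"] != CONTROL_LABEL]
    for (fam, gene_id), sub in fam_rows.groupby(["family", "gene_id"], sort=True):
        informative.setdefault(fam, {})[gene_id] = np.sort(
            sub["pos"].to_numpy(np.int64)
        )
    for fam, gene_ids in manifest.get("genes", {}).items():
        fam_tab = informative.setdefault(fam, {})
        for gene_id in gene_ids:
            fam_tab.setdefault(gene_id, np.zeros(0, dtype=np.int64))
    return SiteTables(
        target_chrom=manifest["target_chrom"],
        control_sites=np.sort(control),
        informative_sites=informative,
        config=RunConfig.from_dict(manifest.get("config", {})),
    )
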