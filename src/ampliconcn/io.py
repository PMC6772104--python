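"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, SAM/BAM via pysam, BED/TSV via pandas.  All intervals
are 0-based half-open; SAM's 1-based positions are converted on read and
write.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .count import AlignmentRecord
from .genome import FamilyAnnotation, GeneInterval, GenomeBundle, merge_intervals

logger = logging.getLogger(__name__)


# -- FASTA --------------------------------------------------------------
def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a multi-record FASTA; names to first whitespace, sequences uppercased."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA at line 1 (expected '>')")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# -- BED ----------------------------------------------------------------
def read_bed(path: str | Path, kind: str = "repeats"):
    """Read a BED file.

    kind="genes": requires 5 columns (chrom, start, end, gene_id, family);
    returns a FamilyAnnotation.  kind="repeats": 3+ columns; returns merged
    (chrom, start, end) intervals.
    """
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    if kind == "genes":
        if table.shape[1] < 5:
            raise ValueError(
                f"{path}: gene BED needs 5 columns (chrom, start, end, gene_id, family)"
            )
        fams: dict[str, list[GeneInterval]] = {}
        for _, row in table.iterrows():
            chrom, start, end, gene_id, family = (
                str(row[0]),
                int(row[1]),
                int(row[2]),
                str(row[3]),
                str(row[4]),
            )
            if start >= end:
                raise ValueError(f"{path}: interval start >= end for {gene_id}")
            fams.setdefault(family, []).append(GeneInterval(gene_id, chrom, start, end))
        return FamilyAnnotation(fams)
    if kind == "repeats":
        if table.shape[1] < 3:
            raise ValueError(f"{path}: repeat BED needs at least 3 columns")
        ivs = [
            (str(r[0]), int(r[1]), int(r[2]))
            for r in table.itertuples(index=False)
        ]
        for chrom, s, e in ivs:
            if s >= e:
                raise ValueError(f"{path}: interval start >= end at {chrom}:{s}-{e}")
        return merge_intervals(ivs)
    raise ValueError(f"unknown BED kind {kind!r}")


def write_gene_bed(annotation: FamilyAnnotation, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for fam in sorted(annotation.families):
            for g in annotation.intervals(fam):
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{fam}\n")
    return path


def write_repeat_bed(
    intervals: Sequence[tuple[str, int, int]], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    return path


def load_genome_bundle(
    fasta: str | Path,
    genes_bed: str | Path | None,
    repeats_bed: str | Path | None,
    target_chrom: str,
) -> GenomeBundle:
    sequences = read_fasta(fasta)
    annotation = read_bed(genes_bed, "genes") if genes_bed else None
    repeats = read_bed(repeats_bed, "repeats") if repeats_bed else ()
    return GenomeBundle(
        sequences=sequences,
        target_chrom=target_chrom,
        family_annotation=annotation,
        repeat_intervals=repeats,
    )


# -- SAM/BAM ------------------------------------------------------------
def _match_profile_from_sam(read: pysam.AlignedSegment) -> np.ndarray:
    """Per-read-base matched status from CIGAR + MD (read orientation)."""
    qlen = read.query_length or (len(read.query_sequence) if read.query_sequence else 0)
    prof = np.zeros(qlen, dtype=bool)
    try:
        pairs = read.get_aligned_pairs(with_seq=True)
    except ValueError:
        nm = read.get_tag("NM") if read.has_tag("NM") else None
        if nm == 0:
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                prof[qpos] = True
            if read.is_reverse:
                prof = prof[::-1]
            return prof
        raise ValueError(
            f"read {read.query_name}: no MD tag (and NM absent or nonzero); "
            "realign with an aligner that emits MD/NM, or use the bundled aligner"
        )
    qseq = read.query_sequence or ""
    for qpos, rpos, ref_base in pairs:
        if qpos is None or rpos is None or ref_base is None:
            continue
        prof[qpos] = ref_base.upper() == qseq[qpos].upper()
    if read.is_reverse:
        prof = prof[::-1]
    return prof


def read_alignments(
    path: str | Path, target_chrom: str | None = None
) -> Iterator[AlignmentRecord]:
    """Stream primary alignments from a coordinate-sorted SAM/BAM.

    Secondary, supplementary, duplicate-flagged and unmapped records are
    skipped (each read must contribute one start at most).  Raises on
    out-of-order input.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    last: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            chrom = read.reference_name
            if target_chrom is not None and chrom != target_chrom:
                continue
            if last.get(chrom, -1) > read.reference_start:
                raise ValueError(f"{path}: alignments are not coordinate-sorted")
            last[chrom] = read.reference_start
            yield AlignmentRecord(
                read_id=read.query_name,
                chrom=chrom,
                start=read.reference_start,
                is_proper_pair=read.is_proper_pair,
                match_profile=_match_profile_from_sam(read),
                is_reverse=read.is_reverse,
                nm=read.get_tag("NM") if read.has_tag("NM") else 0,
                seq=read.query_sequence,
                is_first=not read.is_read2,
                mate_chrom=read.next_reference_name,
                mate_start=read.next_reference_start
                if read.next_reference_start is not None
                else -1,
                mate_is_reverse=read.mate_is_reverse if read.is_paired else False,
                tlen=read.template_length,
            )


def _md_from_profile(rec: AlignmentRecord, ref_seq: str) -> str:
    """MD string for a full-length match/mismatch alignment."""
    md = []
    run = 0
    L = rec.read_length
    window = ref_seq[rec.start : rec.start + L]
    prof = rec.match_profile[::-1] if rec.is_reverse else rec.match_profile
    for i in range(L):
        if prof[i]:
            run += 1
        else:
            md.append(str(run))
            md.append(window[i])
            run = 0
    md.append(str(run))
    return "".join(md)


def write_sam(
    records: Iterable[AlignmentRecord],
    genome: GenomeBundle,
    path: str | Path,
) -> Path:
    """Write coordinate-sorted records as SAM with NM and MD tags."""
    path = Path(path)
    names = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": genome.chrom_length(n)} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            flag = 1  # paired
            if rec.is_proper_pair:
                flag |= 2
            if rec.is_reverse:
                flag |= 16
            if rec.mate_is_reverse:
                flag |= 32
            flag |= 64 if rec.is_first else 128
            if rec.mate_chrom is None:
                flag |= 8  # mate unmapped
            seg.flag = flag
            seg.reference_id = tid[rec.chrom]
            seg.reference_start = rec.start
            seg.mapping_quality = 60
            L = rec.read_length
            seg.cigarstring = f"{L}M"
            if rec.seq is not None:
                seg.query_sequence = rec.seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * L)
            if rec.mate_chrom is not None:
                seg.next_reference_id = tid[rec.mate_chrom]
                seg.next_reference_start = rec.mate_start
            else:
                seg.next_reference_id = tid[rec.chrom]
                seg.next_reference_start = rec.start
            seg.template_length = rec.tlen
            tags = [("NM", int(rec.nm))]
            tags.append(("MD", _md_from_profile(rec, genome.sequences[rec.chrom])))
            seg.tags = tags
            out.write(seg)
    return path


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
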