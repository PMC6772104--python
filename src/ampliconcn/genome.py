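"""Shared coordinate frame: reference sequences, gene-family and repeat annotation.

All coordinates are 0-based half-open throughout the package; BED input maps
directly, SAM positions are converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmer import BASES, GenomeIndex, encode_sequence


@dataclass(frozen=True)
class GeneInterval:
    """One gene copy: 0-based half-open interval on a chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


class FamilyAnnotation:
    """Gene copies grouped by family.

    Within a family, copies must not overlap one another and gene ids must be
    unique.  Families with a single copy are legitimate (e.g. X-degenerate
    genes used as a copy-number-1 sanity check) and flow through the caller
    identically.
    """

    def __init__(self, families: Mapping[str, Sequence[GeneInterval]]):
        self.families: dict[str, list[GeneInterval]] = {}
        for fam, genes in families.items():
            genes = sorted(genes, key=lambda g: (g.chrom, g.start))
            if not genes:
                raise ValueError(f"family {fam} has no gene copies")
            ids = [g.gene_id for g in genes]
            if len(set(ids)) != len(ids):
                raise ValueError(f"family {fam}: duplicate gene ids")
            for a, b in zip(genes, genes[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(
                        f"family {fam}: overlapping gene copies "
                        f"{a.gene_id} and {b.gene_id}"
                    )
            self.families[fam] = list(genes)

    def n_genes(self, family: str) -> int:
        return len(self.families[family])

    def intervals(self, family: str) -> list[GeneInterval]:
        return self.families[family]

    def all_intervals(self) -> Iterable[tuple[str, GeneInterval]]:
        for fam, genes in self.families.items():
            for g in genes:
                yield fam, g

    def __iter__(self):
        return iter(self.families)

    def __len__(self):
        return len(self.families)

    def __eq__(self, other):
        return isinstance(other, FamilyAnnotation) and self.families == other.families


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Sort and merge possibly overlapping (chrom, start, end) intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if start < 0 or end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


class GenomeBundle:
    """Reference sequences plus the annotation everything else keys off.

    Parameters
    ----------
    sequences
        chromosome name -> nucleotide string (A/C/G/T/N, any case; stored
        uppercase).
    target_chrom
        The chromosome on which copy number is called.
    family_annotation
        Gene copies grouped by family; may be empty for simple mappability
        use cases.
    repeat_intervals
        (chrom, start, end) intervals of annotated repeats (RepeatMasker /
        tandem-repeat style); merged and sorted on construction.  Positions
        inside them are excluded from control, informative and depth tracks.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        target_chrom: str,
        family_annotation: FamilyAnnotation | None = None,
        repeat_intervals: Iterable[tuple[str, int, int]] = (),
    ):
        if target_chrom not in sequences:
            raise ValueError(f"target chromosome {target_chrom!r} not in sequences")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self.sequences.items():
            bad = set(seq) - set(BASES)
            if bad:
                raise ValueError(
                    f"chromosome {name}: invalid nucleotide character "
                    f"{sorted(bad)[0]!r}; expected one of {BASES}"
                )
        self.target_chrom = target_chrom
        self.family_annotation = family_annotation or FamilyAnnotation({})
        self.repeat_intervals = merge_intervals(repeat_intervals)
        for chrom, start, end in self.repeat_intervals:
            if chrom in self.sequences and end > len(self.sequences[chrom]):
                raise ValueError(
                    f"repeat interval {chrom}:{start}-{end} exceeds chromosome bounds"
                )
        for fam, g in self.family_annotation.all_intervals():
            if g.chrom not in self.sequences:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > len(self.sequences[g.chrom]):
                raise ValueError(f"gene {g.gene_id} exceeds chromosome bounds")
        self._indexes: dict[int, GenomeIndex] = {}

    # ------------------------------------------------------------------
    def chrom_length(self, chrom: str | None = None) -> int:
        return len(self.sequences[chrom or self.target_chrom])

    def encoded(self, chrom: str | None = None) -> np.ndarray:
        return encode_sequence(self.sequences[chrom or self.target_chrom])

    def kmer_index(self, k: int) -> GenomeIndex:
        """Shared GenomeIndex whose inter-chromosome gap is safe for this k."""
        gap = max(160, k)
        key = gap
        if key not in self._indexes:
            self._indexes[key] = GenomeIndex(self.sequences, gap=gap)
        return self._indexes[key]

    # -- masks on a chromosome ------------------------------------------
    def repeat_mask(self, chrom: str | None = None) -> np.ndarray:
        """Boolean array: True at positions inside a repeat interval."""
        chrom = chrom or self.target_chrom
        mask = np.zeros(self.chrom_length(chrom), dtype=bool)
        for c, s, e in self.repeat_intervals:
            if c == chrom:
                mask[s:e] = True
        return mask

    def family_mask(self, chrom: str | None = None) -> np.ndarray:
        """Boolean array: True at positions inside any annotated gene copy."""
        chrom = chrom or self.target_chrom
        mask = np.zeros(self.chrom_length(chrom), dtype=bool)
        for _fam, g in self.family_annotation.all_intervals():
            if g.chrom == chrom:
                mask[g.start : g.end] = True
        return mask
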