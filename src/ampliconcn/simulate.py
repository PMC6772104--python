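"""Synthetic ampliconic references and error-free paired-end reads.

The generator emulates the architecture the method targets: a Y-like
chromosome carrying gene families whose copies are >99% identical, arranged
as tandem arrays (amplicon repeat units), flanked by long unique single-copy
sequence, with optional tandem-repeat intervals and single-copy
(X-degenerate-like) genes whose expected copy number is one.

Every sequence element is drawn from its own seed-stable substream keyed by
(seed, element identity), *not* by genome layout.  Two references built with
the same seed but different copy numbers therefore share their flanks,
spacers, ancestral gene sequences and common copies exactly — the only
difference is the added copies.  That mirrors the validation design where
reads are simulated from an edited reference but counted against site tables
built on the unedited one.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import FamilyAnnotation, GeneInterval, GenomeBundle
from .kmer import decode_sequence, revcomp_codes


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic gene family.

    ``gene_length`` is the size of the duplicated unit (real amplicon repeat
    units are tens of kb; the default keeps desk-scale genomes while leaving
    thousands of informative positions per copy).  ``divergence`` is the
    substitution rate between each copy and the family's ancestral sequence;
    the default 0.002 keeps all pairwise copy identities >99%.  ``tandem``
    copies are directly adjacent (tandem array); ``dispersed`` copies are
    separated by unique spacers.  ``decoy_identity`` optionally places a
    diverged, unannotated paralog on a separate chromosome (modelling a
    cross-chromosome homolog that erodes family specificity).

    ``template_copies`` caps the number of *distinct* copy sequences: copies
    beyond it duplicate existing ones cyclically.  This emulates editing a
    reference by inserting extra copies of its annotated genes (the
    validation design), rather than inventing new paralogs — reads from an
    added copy then match their source copy exactly, as they do when a real
    tandem duplication is sequenced against the unedited reference.
    """

    name: str
    n_copies: int
    gene_length: int = 50_000
    divergence: float = 0.002
    arrangement: str = "tandem"  # "tandem" | "dispersed"
    decoy_identity: float | None = None
    template_copies: int | None = None

    def __post_init__(self):
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        if self.template_copies is not None and self.template_copies < 1:
            raise ValueError("template_copies must be >= 1 when given")
        if not (0.0 <= self.divergence < 0.01):
            raise ValueError(
                "divergence must stay in [0, 0.01) to keep copies >99% identical"
            )
        if self.arrangement not in ("tandem", "dispersed"):
            raise ValueError("arrangement must be 'tandem' or 'dispersed'")


#: Copy numbers of the three families in the unedited reference.
BASELINE_COPIES: dict[str, int] = {"TSPY": 9, "RBMY": 6, "VCY": 2}

#: Copy configurations of the three simulated validation sets.
SET_CONFIGS: dict[int, dict[str, int]] = {
    1: {"TSPY": 22, "RBMY": 7, "VCY": 4},
    2: {"TSPY": 29, "RBMY": 12, "VCY": 2},
    3: {"TSPY": 23, "RBMY": 9, "VCY": 3},
}


def baseline_specs(**overrides) -> list[FamilySpec]:
    """Family specs matching the unedited reference (9/6/2 copies)."""
    return [
        FamilySpec(name=n, n_copies=c, **overrides)
        for n, c in BASELINE_COPIES.items()
    ]


def set_specs(set_id: int, **overrides) -> list[FamilySpec]:
    """Family specs for one of the three validation copy configurations.

    Extra copies beyond the baseline duplicate baseline copy sequences
    (``template_copies``), emulating a reference edited by gene-copy
    insertion.
    """
    return [
        FamilySpec(
            name=n,
            n_copies=c,
            template_copies=min(c, BASELINE_COPIES[n]),
            **overrides,
        )
        for n, c in SET_CONFIGS[set_id].items()
    ]


@dataclass
class SyntheticGenomeBundle:
    """A GenomeBundle plus the truth table the simulation was built from."""

    genome: GenomeBundle
    truth: dict[str, int]
    seed: int


@dataclass
class ReadPairSet:
    """Error-free (or uniformly mutated) paired reads with recorded origins.

    Mate 1 is the forward strand of the fragment start; mate 2 is the
    reverse complement of the fragment end; the outer distance is drawn per
    pair.  Reads are stored encoded (uint8 codes) for fast downstream use.
    """

    r1: np.ndarray
    r2: np.ndarray
    origin_chrom: list[str]
    origin_start: np.ndarray
    fragment: np.ndarray
    read_len: int = 101
    outer_mean: float = 260.0
    outer_sd: float = 25.0
    error_rate: float = 0.0
    seed: int = 0

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def names(self) -> list[str]:
        return [
            f"sim_{i}:{self.origin_chrom[i]}:{int(self.origin_start[i])}:{int(self.fragment[i])}"
            for i in range(self.n_pairs)
        ]

    def to_fastq(self, path1: str | Path, path2: str | Path) -> None:
        qual = "I" * self.read_len
        names = self.names()
        for path, mat, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            with open(path, "w") as fh:
                for i in range(self.n_pairs):
                    fh.write(
                        f"@{names[i]}/{mate}\n{decode_sequence(mat[i])}\n+\n{qual}\n"
                    )


# ----------------------------------------------------------------------
def _stream(seed: int, *ids: int) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, ids); layout-independent."""
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(i) for i in ids]))


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode())


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8) if n else np.zeros(0, np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    if rate > 0:
        hit = rng.random(codes.size) < rate
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


# stream tags (arbitrary, fixed, disjoint per element class)
_T_LEFT, _T_REPEAT_MOTIF, _T_FAM_ANC, _T_FAM_COPY, _T_FAM_SPACER, _T_FAM_GAP = 1, 2, 3, 4, 5, 6
_T_SCG, _T_SCG_PAD, _T_RIGHT, _T_DECOY = 7, 8, 9, 10


def build_synthetic_reference(
    specs: Sequence[FamilySpec],
    flank_length: int = 700_000,
    spacer_length: int = 100_000,
    n_single_copy: int = 3,
    single_copy_length: int = 2_000,
    single_copy_pad: int = 5_000,
    tandem_repeats: int = 2,
    tandem_repeat_length: int = 2_000,
    dispersed_spacer: int = 2_000,
    seed: int = 9,
    target_chrom: str = "chrY_sim",
) -> SyntheticGenomeBundle:
    """Assemble a synthetic target chromosome and its annotation.

    Layout: left unique flank (with ``tandem_repeats`` annotated short
    tandem-repeat blocks) + one array per family + unique inter-family
    spacers + single-copy genes + right unique flank.  Optional decoy
    chromosomes carry diverged unannotated paralogs.  Fully deterministic
    given (specs, parameters, seed).
    """
    parts: list[np.ndarray] = []
    families: dict[str, list[GeneInterval]] = {}
    repeats: list[tuple[str, int, int]] = []
    pos = 0

    def emit(codes: np.ndarray) -> tuple[int, int]:
        nonlocal pos
        parts.append(codes)
        start = pos
        pos += codes.size
        return start, pos

    # left flank with embedded tandem-repeat blocks
    n_rep = max(0, tandem_repeats)
    seg_len = max(0, flank_length - n_rep * tandem_repeat_length) // (n_rep + 1)
    for i in range(n_rep + 1):
        emit(_random_codes(_stream(seed, _T_LEFT, i), seg_len))
        if i < n_rep:
            motif = _random_codes(_stream(seed, _T_REPEAT_MOTIF, i), 5)
            block = np.tile(motif, tandem_repeat_length // motif.size + 1)[
                :tandem_repeat_length
            ]
            s, e = emit(block)
            repeats.append((target_chrom, s, e))

    decoys: dict[str, np.ndarray] = {}
    for spec in specs:
        key = _name_key(spec.name)
        ancestral = _random_codes(_stream(seed, _T_FAM_ANC, key), spec.gene_length)
        genes: list[GeneInterval] = []
        for j in range(spec.n_copies):
            tj = j if spec.template_copies is None else j % spec.template_copies
            copy = _mutate(ancestral, spec.divergence, _stream(seed, _T_FAM_COPY, key, tj))
            if spec.arrangement == "dispersed" and j > 0:
                emit(_random_codes(_stream(seed, _T_FAM_SPACER, key, j), dispersed_spacer))
            s, e = emit(copy)
            genes.append(GeneInterval(f"{spec.name}_{j + 1}", target_chrom, s, e))
        if genes:
            families[spec.name] = genes
        emit(_random_codes(_stream(seed, _T_FAM_GAP, key), spacer_length))
        if spec.decoy_identity is not None:
            pad1 = _random_codes(_stream(seed, _T_DECOY, key, 0), 20_000)
            body = _mutate(
                ancestral, 1.0 - spec.decoy_identity, _stream(seed, _T_DECOY, key, 1)
            )
            pad2 = _random_codes(_stream(seed, _T_DECOY, key, 2), 20_000)
            decoys[f"decoy_{spec.name}"] = np.concatenate([pad1, body, pad2])

    for j in range(n_single_copy):
        name = f"XDG{j + 1}"
        body = _random_codes(_stream(seed, _T_SCG, j), single_copy_length)
        s, e = emit(body)
        families[name] = [GeneInterval(name, target_chrom, s, e)]
        emit(_random_codes(_stream(seed, _T_SCG_PAD, j), single_copy_pad))

    emit(_random_codes(_stream(seed, _T_RIGHT, 0), flank_length))

    target = decode_sequence(np.concatenate(parts))
    sequences = {target_chrom: target}
    for name, codes in decoys.items():
        sequences[name] = decode_sequence(codes)
    genome = GenomeBundle(
        sequences=sequences,
        target_chrom=target_chrom,
        family_annotation=FamilyAnnotation(families),
        repeat_intervals=repeats,
    )
    truth = {spec.name: spec.n_copies for spec in specs if spec.n_copies > 0}
    truth.update({f"XDG{j + 1}": 1 for j in range(n_single_copy)})
    return SyntheticGenomeBundle(genome=genome, truth=truth, seed=seed)


def simulate_paired_reads(
    bundle: SyntheticGenomeBundle | GenomeBundle,
    coverage: float | None = None,
    n_pairs: int | None = None,
    read_len: int = 101,
    outer_mean: float = 260.0,
    outer_sd: float = 25.0,
    error_rate: float = 0.0,
    seed: int = 9,
) -> ReadPairSet:
    """Draw paired reads uniformly from the genome (wgsim-style geometry).

    ``n_pairs = round(coverage * genome_length / (2 * read_len))`` when
    coverage is given.  With ``error_rate`` 0, every read is an exact
    substring of its source (mate 2 reverse-complemented).
    """
    genome = bundle.genome if isinstance(bundle, SyntheticGenomeBundle) else bundle
    chroms = list(genome.sequences)
    lengths = np.array([genome.chrom_length(c) for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    if read_len > int(lengths.max()):
        raise ValueError("read length exceeds every chromosome length")
    if n_pairs is None:
        if coverage is None or coverage <= 0:
            raise ValueError("provide coverage > 0 or n_pairs > 0")
        n_pairs = int(round(coverage * total / (2 * read_len)))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    frag = np.round(rng.normal(outer_mean, outer_sd, n_pairs)).astype(np.int64)
    frag = np.clip(frag, read_len, None)
    # chromosome chosen per pair with probability proportional to usable starts
    usable = np.maximum(lengths[None, :] - frag[:, None] + 1, 0)
    pick = rng.random(n_pairs) * usable.sum(axis=1)
    cidx = (pick[:, None] >= np.cumsum(usable, axis=1)).sum(axis=1)
    frag = np.minimum(frag, lengths[cidx])
    start = (rng.random(n_pairs) * (lengths[cidx] - frag + 1)).astype(np.int64)

    r1 = np.empty((n_pairs, read_len), dtype=np.uint8)
    r2 = np.empty((n_pairs, read_len), dtype=np.uint8)
    ar = np.arange(read_len)
    for ci, chrom in enumerate(chroms):
        rows = np.nonzero(cidx == ci)[0]
        if rows.size == 0:
            continue
        codes = genome.encoded(chrom)
        r1[rows] = codes[start[rows, None] + ar]
        tail = start[rows] + frag[rows] - read_len
        r2[rows] = revcomp_codes(codes)[  # rc genome: position maps L-1-p
            (codes.size - tail[:, None] - read_len) + ar
        ]
    if error_rate > 0:
        for mat in (r1, r2):
            hit = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            mat[hit] = (mat[hit] + shift) % 4
    return ReadPairSet(
        r1=r1,
        r2=r2,
        origin_chrom=[chroms[i] for i in cidx],
        origin_start=start,
        fragment=frag,
        read_len=read_len,
        outer_mean=outer_mean,
        outer_sd=outer_sd,
        error_rate=error_rate,
        seed=seed,
    )
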