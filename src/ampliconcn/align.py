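"""Minimal exact-placement aligner for simulator output.

Places each read by pigeonhole-chunked hash lookup against the reference
(the same machinery the build stage uses), verifies candidates by Hamming
distance, and pairs mates jointly: among proper forward/reverse combinations
within the expected outer distance, the pair with the fewest total mismatches
wins, with ties broken uniformly at random (seeded).  Guaranteed to find
every placement with at most ``n_chunks - 1`` mismatches; placements up to
``max_mismatches`` are found whenever a chunk is exact (always the case for
the error-free, low-divergence reads it is designed for).  Emits full-length
match alignments (no indels), with NM and per-base match information.
"""
from __future__ import annotations

import logging

import numpy as np

from .count import AlignmentRecord
from .genome import GenomeBundle
from .kmer import GenomeIndex, chunk_layout, decode_sequence, _RC
from .simulate import ReadPairSet

logger = logging.getLogger(__name__)

_MAX_CANDS = 40  # per read and strand, ordered by (mismatches, position)


def _read_candidates(
    index: GenomeIndex,
    mat: np.ndarray,
    n_chunks: int,
    max_mm: int,
) -> list[list[tuple[int, int, int]]]:
    """Per read: candidate (concat_start, strand, mismatches), best first."""
    n_reads, k = mat.shape
    G = index.length
    layout = chunk_layout(k, n_chunks)
    valid = index.valid_start(k)
    rc_mat = _RC[mat][:, ::-1]
    qi_parts, cand_parts, strand_parts = [], [], []
    for off, L in layout:
        for strand, m in ((0, mat), (1, rc_mat)):
            hq = index.row_hashes(m, off, L)
            qidx, cc = index.find_chunk_candidates(L, hq)
            qi_parts.append(qidx)
            cand_parts.append(cc - off)
            strand_parts.append(np.full(qidx.size, strand, dtype=np.int8))
    qi = np.concatenate(qi_parts)
    cand = np.concatenate(cand_parts)
    strand = np.concatenate(strand_parts)
    ok = (cand >= 0) & (cand <= G - k)
    ok &= valid[np.clip(cand, 0, G - k)]
    qi, cand, strand = qi[ok], cand[ok], strand[ok]
    key = (qi * G + cand) * 2 + strand
    _, first = np.unique(key, return_index=True)
    qi, cand, strand = qi[first], cand[first], strand[first]
    # verify in batches
    mm = np.empty(qi.size, dtype=np.int32)
    BLOCK = 1_000_000
    ar = np.arange(k)
    for lo in range(0, qi.size, BLOCK):
        sl = slice(lo, min(lo + BLOCK, qi.size))
        win = index.codes[cand[sl, None] + ar]
        rows_f = strand[sl] == 0
        q = np.empty_like(win)
        if rows_f.any():
            q[rows_f] = mat[qi[sl][rows_f]]
        if (~rows_f).any():
            q[~rows_f] = rc_mat[qi[sl][~rows_f]]
        mm[sl] = (win != q).sum(axis=1, dtype=np.int32)
    keep = mm <= max_mm
    qi, cand, strand, mm = qi[keep], cand[keep], strand[keep], mm[keep]
    order = np.lexsort((strand, cand, mm, qi))
    out: list[list[tuple[int, int, int]]] = [[] for _ in range(n_reads)]
    for row in order:
        lst = out[qi[row]]
        if len(lst) < _MAX_CANDS:
            lst.append((int(cand[row]), int(strand[row]), int(mm[row])))
    return out


def align_reads_minimal(
    reads: ReadPairSet,
    genome: GenomeBundle,
    seed: int = 0,
    max_mismatches: int = 6,
    n_chunks: int = 3,
    proper_max_outer: float | None = None,
) -> list[AlignmentRecord]:
    """Place read pairs on the genome; returns records sorted by coordinate.

    A pair is flagged proper when its mates align forward/reverse on one
    chromosome with outer distance between the read length and
    ``proper_max_outer`` (default: outer mean + 10 sd).
    """
    k = reads.read_len
    index = genome.kmer_index(k)
    G = index.length
    if proper_max_outer is None:
        proper_max_outer = reads.outer_mean + 10.0 * reads.outer_sd
    c1 = _read_candidates(index, reads.r1, n_chunks, max_mismatches)
    c2 = _read_candidates(index, reads.r2, n_chunks, max_mismatches)
    chrom_id = index.chrom_id
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))

    placements: list[tuple[int, int, int, bool]] = []  # (pos, strand, mate_row, proper)
    pair_of: list[tuple[int | None, int | None]] = []
    n_unmapped = 0
    for i in range(reads.n_pairs):
        a, b = c1[i], c2[i]
        combos = []
        best = None
        for p1, s1, m1 in a:
            for p2, s2, m2 in b:
                if s1 == s2 or chrom_id[p1] != chrom_id[p2]:
                    continue
                left, right = (p1, p2) if s1 == 0 else (p2, p1)
                if right < left:
                    continue
                outer = right + k - left
                if outer > proper_max_outer:
                    continue
                score = m1 + m2
                if best is None or score < best:
                    best = score
                    combos = [(p1, s1, m1, p2, s2, m2)]
                elif score == best:
                    combos.append((p1, s1, m1, p2, s2, m2))
        if combos:
            pick = combos[rng.integers(len(combos))] if len(combos) > 1 else combos[0]
            p1, s1, m1, p2, s2, m2 = pick
            r1_row = len(placements)
            placements.append((p1, s1, 2 * i, True))
            placements.append((p2, s2, 2 * i + 1, True))
            pair_of.append((r1_row, r1_row + 1))
        else:
            rows: list[int | None] = [None, None]
            for mate, cands in enumerate((a, b)):
                if not cands:
                    n_unmapped += 1
                    continue
                best_mm = cands[0][2]
                ties = [c for c in cands if c[2] == best_mm]
                p, s, m = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
                rows[mate] = len(placements)
                placements.append((p, s, 2 * i + mate, False))
            pair_of.append((rows[0], rows[1]))
    if n_unmapped:
        logger.info("%d reads could not be placed and are excluded", n_unmapped)

    if not placements:
        return []
    pos = np.array([p for p, _, _, _ in placements], dtype=np.int64)
    strand = np.array([s for _, s, _, _ in placements], dtype=np.int8)
    mate_row = np.array([r for _, _, r, _ in placements], dtype=np.int64)
    proper = np.array([pr for _, _, _, pr in placements], dtype=bool)
    # aligned-orientation read codes and per-base match matrix
    ar = np.arange(k)
    pair_idx = mate_row // 2
    is_r2 = (mate_row % 2).astype(bool)
    aligned = np.where(
        is_r2[:, None], reads.r2[pair_idx], reads.r1[pair_idx]
    ).astype(np.uint8)
    flip = strand == 1
    aligned[flip] = _RC[aligned[flip]][:, ::-1]
    match = index.codes[pos[:, None] + ar] == aligned
    nm = (~match).sum(axis=1)

    cid, local = index.to_local(pos)
    names = reads.names()
    mate_local = np.full(pos.size, -1, dtype=np.int64)
    mate_rev = np.zeros(pos.size, dtype=bool)
    mate_chrom_idx = np.full(pos.size, -1, dtype=np.int64)
    for r1_row, r2_row in pair_of:
        if r1_row is not None and r2_row is not None:
            for this, other in ((r1_row, r2_row), (r2_row, r1_row)):
                mate_local[this] = local[other]
                mate_rev[this] = strand[other] == 1
                mate_chrom_idx[this] = cid[other]

    records: list[AlignmentRecord] = []
    for row in range(pos.size):
        prof = match[row]
        if strand[row] == 1:
            prof = prof[::-1]  # report in read orientation
        tlen = 0
        if mate_local[row] >= 0 and mate_chrom_idx[row] == cid[row]:
            left = min(local[row], mate_local[row])
            right = max(local[row], mate_local[row]) + k
            tlen = right - left if local[row] <= mate_local[row] else left - right
        records.append(
            AlignmentRecord(
                read_id=names[pair_idx[row]],
                chrom=index.names[cid[row]],
                start=int(local[row]),
                is_proper_pair=bool(proper[row]),
                match_profile=prof.copy(),
                is_reverse=bool(strand[row]),
                nm=int(nm[row]),
                seq=decode_sequence(aligned[row]),
                is_first=not bool(is_r2[row]),
                mate_chrom=index.names[mate_chrom_idx[row]]
                if mate_chrom_idx[row] >= 0
                else None,
                mate_start=int(mate_local[row]),
                mate_is_reverse=bool(mate_rev[row]),
                tlen=int(tlen),
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.read_id, not r.is_first))
    return records
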