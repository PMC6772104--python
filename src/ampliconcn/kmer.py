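"""Exact k-mer matching within a substitution budget.

This is the computational core of the site-selection (build) stage and of the
bundled minimal aligner.  The problem it solves: for every k-mer of a target
chromosome, find *all* locations in the genome (both strands) whose k-mer lies
within a given Hamming distance.  Mappability and informative-site selection
are both thin filters over this primitive.

The algorithm is a pigeonhole filter: a k-mer is split into ``max_mm + 1``
contiguous chunks, so any match with at most ``max_mm`` substitutions shares
at least one chunk *exactly*.  Exact chunk matches are found with a rolling
polynomial hash over the concatenated genome (equal substrings are guaranteed
equal hashes; the rare hash collision only produces an extra candidate, which
the full Hamming verification then discards).  Everything is vectorised with
numpy; the scan is exact, with no heuristic seeding.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np

BASES = "ACGTN"
N_CODE = 4

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# complement map on codes; N stays N
_RC = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_HASH_BASE = 1099511628211  # odd, hence invertible modulo 2**64
_HASH_BASE_INV = pow(_HASH_BASE, -1, 2**64)

_VERIFY_BLOCK = 2_000_000  # candidate pairs verified per vectorised batch


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N (case-insensitive) to uint8 codes 0..4."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENC[raw]
    if (codes == 255).any():
        bad = chr(int(raw[int(np.argmax(codes == 255))]))
        raise ValueError(f"invalid nucleotide character {bad!r}; expected one of {BASES}")
    return codes


_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)


def decode_sequence(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC[codes[::-1]]


def chunk_layout(k: int, n_chunks: int) -> list[tuple[int, int]]:
    """Split k into n_chunks contiguous pieces; returns (offset, length) pairs.

    Lengths differ by at most one (e.g. k=101, n=3 -> 34/34/33)."""
    if n_chunks < 1:
        raise ValueError("need at least one chunk")
    base, rem = divmod(k, n_chunks)
    if base < 1:
        raise ValueError(f"k={k} too short to split into {n_chunks} chunks")
    lens = [base + 1] * rem + [base] * (n_chunks - rem)
    layout = []
    off = 0
    for length in lens:
        layout.append((off, length))
        off += length
    return layout


def _prefix_powers(n: int) -> tuple[np.ndarray, np.ndarray]:
    """B**i and B**-i (mod 2**64) for i in 0..n-1."""
    pw = np.empty(n, dtype=np.uint64)
    ipw = np.empty(n, dtype=np.uint64)
    pw[0] = ipw[0] = 1
    np.multiply.accumulate(np.full(n, _HASH_BASE, dtype=np.uint64)[: n - 1], out=pw[1:])
    np.multiply.accumulate(np.full(n, _HASH_BASE_INV, dtype=np.uint64)[: n - 1], out=ipw[1:])
    return pw, ipw


class GenomeIndex:
    """Concatenated, encoded genome with rolling-hash substring indexes.

    Chromosomes are joined with runs of N at least ``gap`` long, so no window
    of length <= gap+1 can span two chromosomes without containing an N, and
    candidate alignment starts are additionally filtered against per-position
    chromosome ids.
    """

    def __init__(self, sequences: Mapping[str, str | np.ndarray], gap: int = 160):
        self.names = list(sequences)
        self.gap = gap
        parts: list[np.ndarray] = []
        sep = np.full(gap, N_CODE, dtype=np.uint8)
        offsets: dict[str, int] = {}
        chrom_id_parts: list[np.ndarray] = []
        pos = 0
        for i, (name, seq) in enumerate(sequences.items()):
            if i > 0:
                parts.append(sep)
                chrom_id_parts.append(np.full(gap, -1, dtype=np.int32))
                pos += gap
            codes = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
            offsets[name] = pos
            parts.append(codes)
            chrom_id_parts.append(np.full(codes.size, i, dtype=np.int32))
            pos += codes.size
        self.codes = np.concatenate(parts) if parts else np.zeros(0, np.uint8)
        self.chrom_id = (
            np.concatenate(chrom_id_parts) if chrom_id_parts else np.zeros(0, np.int32)
        )
        self.offsets = offsets
        self.lengths = {
            n: (len(s) if not isinstance(s, np.ndarray) else s.size)
            for n, s in sequences.items()
        }
        self.length = self.codes.size
        self.rc_codes = revcomp_codes(self.codes)
        G = self.length
        self._pw, self._ipw = _prefix_powers(G + 1)
        self._prefix = self._make_prefix(self.codes)
        self._prefix_rc = self._make_prefix(self.rc_codes)
        self._n_cum = np.concatenate(
            ([0], np.cumsum(self.codes == N_CODE, dtype=np.int64))
        )
        self._hash_cache: dict[tuple[int, bool], np.ndarray] = {}
        self._sorted_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._valid_cache: dict[int, np.ndarray] = {}

    def _make_prefix(self, codes: np.ndarray) -> np.ndarray:
        G = codes.size
        weighted = codes.astype(np.uint64) * self._pw[:G]
        pref = np.empty(G + 1, dtype=np.uint64)
        pref[0] = 0
        np.cumsum(weighted, dtype=np.uint64, out=pref[1:])
        return pref

    # -- coordinates -------------------------------------------------------
    def to_concat(self, chrom: str, pos) :
        return self.offsets[chrom] + pos

    def to_local(self, concat_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated positions to (chrom index, local position)."""
        cid = self.chrom_id[concat_pos]
        starts = np.array([self.offsets[n] for n in self.names], dtype=np.int64)
        local = concat_pos - starts[np.maximum(cid, 0)]
        return cid, local

    # -- hashes ------------------------------------------------------------
    def substring_hashes(self, L: int, rc: bool = False) -> np.ndarray:
        """hash(codes[p:p+L]) for every p in 0..G-L (position-normalised)."""
        key = (L, rc)
        if key not in self._hash_cache:
            pref = self._prefix_rc if rc else self._prefix
            G = self.length
            h = (pref[L:] - pref[:-L]) * self._ipw[: G - L + 1]
            self._hash_cache[key] = h
            if not rc and L not in self._sorted_cache:
                order = np.argsort(h, kind="stable").astype(np.int64)
                self._sorted_cache[L] = (h[order], order)
        return self._hash_cache[key]

    def sorted_index(self, L: int) -> tuple[np.ndarray, np.ndarray]:
        if L not in self._sorted_cache:
            self.substring_hashes(L)
        return self._sorted_cache[L]

    @staticmethod
    def hash_rows(mat: np.ndarray, offset: int, L: int, pw: np.ndarray) -> np.ndarray:
        """Hash of mat[:, offset:offset+L] rows, comparable to substring_hashes."""
        return (mat[:, offset : offset + L].astype(np.uint64) * pw[:L]).sum(
            axis=1, dtype=np.uint64
        )

    def row_hashes(self, mat: np.ndarray, offset: int, L: int) -> np.ndarray:
        return self.hash_rows(mat, offset, L, self._pw)

    # -- masks -------------------------------------------------------------
    def valid_start(self, k: int) -> np.ndarray:
        """True where a k-window lies entirely inside one chromosome."""
        if k not in self._valid_cache:
            G = self.length
            v = np.zeros(G, dtype=bool)
            if G >= k:
                cid = self.chrom_id
                ok = (cid[: G - k + 1] >= 0) & (cid[: G - k + 1] == cid[k - 1 :])
                v[: G - k + 1] = ok
            self._valid_cache[k] = v
        return self._valid_cache[k]

    def window_n_free(self, k: int) -> np.ndarray:
        """True (over starts 0..G-k) where the k-window contains no N."""
        G = self.length
        if G < k:
            return np.zeros(0, dtype=bool)
        return (self._n_cum[k:] - self._n_cum[:-k]) == 0

    def query_positions(self, chrom: str, k: int) -> np.ndarray:
        """All concat positions on `chrom` with a valid, N-free k-window."""
        start = self.offsets[chrom]
        L = self.lengths[chrom]
        if L < k:
            return np.zeros(0, dtype=np.int64)
        p = np.arange(start, start + L - k + 1, dtype=np.int64)
        ok = self.valid_start(k)[p] & self.window_n_free(k)[p]
        return p[ok]

    def find_chunk_candidates(self, L: int, qh: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All genome positions whose length-L substring hash equals qh[i].

        Returns (query row indices, genome chunk positions)."""
        sh, order = self.sorted_index(L)
        left = np.searchsorted(sh, qh, side="left")
        right = np.searchsorted(sh, qh, side="right")
        counts = right - left
        total = int(counts.sum())
        qidx = np.repeat(np.arange(qh.size, dtype=np.int64), counts)
        cum = np.cumsum(counts) - counts
        within = np.arange(total, dtype=np.int64) - np.repeat(cum, counts)
        cand = order[np.repeat(left, counts) + within]
        return qidx, cand


def _verify_pairs(
    index: GenomeIndex,
    qpos: np.ndarray,
    cand: np.ndarray,
    strand: np.ndarray,
    k: int,
    max_mm: int,
) -> np.ndarray:
    """Hamming distance between genome window at cand and the (oriented) query."""
    G = index.length
    ar = np.arange(k, dtype=np.int64)
    mm = np.empty(qpos.size, dtype=np.int32)
    for lo in range(0, qpos.size, _VERIFY_BLOCK):
        sl = slice(lo, min(lo + _VERIFY_BLOCK, qpos.size))
        cwin = index.codes[cand[sl, None] + ar]
        fwd = strand[sl] == 0
        qwin = np.empty_like(cwin)
        if fwd.any():
            qwin[fwd] = index.codes[qpos[sl][fwd, None] + ar]
        rev = ~fwd
        if rev.any():
            rstart = G - k - qpos[sl][rev]
            qwin[rev] = index.rc_codes[rstart[:, None] + ar]
        mm[sl] = (cwin != qwin).sum(axis=1, dtype=np.int32)
    return mm


def scan_hits(
    index: GenomeIndex,
    k: int,
    max_mm: int,
    queries: np.ndarray,
    collect_mask: np.ndarray | None = None,
    block_size: int = 200_000,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """For each query position, find all genome loci matching within max_mm.

    queries are concatenated coordinates with valid, N-free k-windows.
    Returns (counts, pairs) where counts[i] is the number of distinct matching
    loci for queries[i] (self included), and pairs = (query_index, locus,
    mismatches) sorted by (query_index, locus), restricted to queries where
    ``collect_mask`` is True (all queries if None).  A locus matching on both
    strands is counted once, with the smaller mismatch count.
    """
    G = index.length
    layout = chunk_layout(k, max_mm + 1)
    valid = index.valid_start(k)
    counts = np.zeros(queries.size, dtype=np.int64)
    out_q: list[np.ndarray] = []
    out_c: list[np.ndarray] = []
    out_m: list[np.ndarray] = []
    for lo in range(0, queries.size, block_size):
        q = queries[lo : lo + block_size]
        qi_parts, cand_parts, strand_parts = [], [], []
        for off, L in layout:
            h = index.substring_hashes(L)
            qidx, cc = index.find_chunk_candidates(L, h[q + off])
            qi_parts.append(qidx)
            cand_parts.append(cc - off)
            strand_parts.append(np.zeros(qidx.size, dtype=np.int8))
            hr = index.substring_hashes(L, rc=True)
            qidx, cc = index.find_chunk_candidates(L, hr[G - q - k + off])
            qi_parts.append(qidx)
            cand_parts.append(cc - off)
            strand_parts.append(np.ones(qidx.size, dtype=np.int8))
        qi = np.concatenate(qi_parts)
        cand = np.concatenate(cand_parts)
        strand = np.concatenate(strand_parts)
        ok = (cand >= 0) & (cand <= G - k)
        ok &= valid[np.clip(cand, 0, G - k)]
        qi, cand, strand = qi[ok], cand[ok], strand[ok]
        # dedupe (query, locus, strand) found through several chunks
        key = (qi * G + cand) * 2 + strand
        _, first = np.unique(key, return_index=True)
        qi, cand, strand = qi[first], cand[first], strand[first]
        mm = _verify_pairs(index, q[qi], cand, strand, k, max_mm)
        keep = mm <= max_mm
        qi, cand, mm = qi[keep], cand[keep], mm[keep]
        # collapse strands: one hit per locus, minimum mismatch count
        key = qi * G + cand
        order = np.lexsort((mm, key))
        key, qi, cand, mm = key[order], qi[order], cand[order], mm[order]
        _, first = np.unique(key, return_index=True)
        qi, cand, mm = qi[first], cand[first], mm[first]
        counts[lo : lo + block_size] = np.bincount(qi, minlength=q.size)
        if collect_mask is not None:
            sel = collect_mask[lo : lo + block_size][qi]
            qi, cand, mm = qi[sel], cand[sel], mm[sel]
        out_q.append(qi + lo)
        out_c.append(cand)
        out_m.append(mm)
    pq = np.concatenate(out_q) if out_q else np.zeros(0, np.int64)
    pc = np.concatenate(out_c) if out_c else np.zeros(0, np.int64)
    pm = np.concatenate(out_m) if out_m else np.zeros(0, np.int32)
    return counts, (pq, pc, pm)
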