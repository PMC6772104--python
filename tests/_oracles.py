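"""Independent brute-force oracles for k-mer matching on toy genomes.

Deliberately naive: a full all-positions Hamming scan over both strands with
numpy sliding windows, O(genome^2 * k).  Kept separate from the package so
it shares no code path with the implementation it checks.
"""
from __future__ import annotations

import numpy as np

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC[b] for b in seq.upper()], dtype=np.int16)


def _revcomp(win: np.ndarray) -> np.ndarray:
    return np.array([_COMP[int(b)] for b in win[::-1]], dtype=np.int16)


def brute_force_hits(
    sequences: dict[str, str], chrom: str, k: int, max_mm: int
) -> dict[int, dict[tuple[str, int], int]]:
    """For each N-free k-mer start on `chrom`: {(chrom2, pos2): mismatches}.

    A locus matching on both strands is reported once with the smaller
    mismatch count.  N never matches anything (including N).
    """
    enc = {c: _encode(s) for c, s in sequences.items()}
    windows = {}
    for c, arr in enc.items():
        if arr.size >= k:
            windows[c] = np.lib.stride_tricks.sliding_window_view(arr, k)
    q = enc[chrom]
    out: dict[int, dict[tuple[str, int], int]] = {}
    for p in range(q.size - k + 1):
        win = q[p : p + k]
        if (win == 4).any():
            continue
        rc = _revcomp(win)
        hits: dict[tuple[str, int], int] = {}
        for c2, sw in windows.items():
            # N (4) mismatches everything because the query is N-free
            d_f = (sw != win).sum(axis=1)
            d_r = (sw != rc).sum(axis=1)
            d = np.minimum(d_f, d_r)
            for pos2 in np.nonzero(d <= max_mm)[0]:
                hits[(c2, int(pos2))] = int(d[pos2])
        out[p] = hits
    return out


def brute_force_unique(
    sequences: dict[str, str], chrom: str, k: int, max_edits: int
) -> np.ndarray:
    """Boolean uniqueness track over `chrom` (False where window has N)."""
    L = len(sequences[chrom])
    unique = np.zeros(L, dtype=bool)
    for p, hits in brute_force_hits(sequences, chrom, k, max_edits).items():
        unique[p] = len(hits) == 1
    return unique
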