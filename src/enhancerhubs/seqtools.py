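"""Nucleotide encoding, k-mer hashing, and exact-match tag mapping.

Sequences are held as numpy ``uint8`` arrays with the 2-bit alphabet
A=0, C=1, G=2, T=3 (255 marks anything else, e.g. padding).  A k-mer of
length <= 32 packs into one ``uint64``, which makes exact genome-wide
string search a sort plus a binary search -- the stand-in for an aligner
on synthetic genomes where every hit is either exact or absent.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (non-ACGT -> 255)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; only valid for codes in 0..3."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every overlapping k-mer of a code array into uint64 (k <= 32)."""
    if k > 32:
        raise ValueError("k-mer length must be <= 32 to fit 2 bits/base in uint64")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    a = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        out <<= np.uint64(2)
        out |= a[i : i + n]
    return out


def kmer_code(seq: str) -> int:
    """Pack one sequence into a single uint64 code."""
    codes = encode(seq)
    if (codes > 3).any():
        raise ValueError(f"non-ACGT base in {seq!r}")
    return int(kmer_codes(codes, len(seq))[0])


class GenomeIndex:
    """Sorted index of all forward-strand k-mers of a genome.

    Supports exact mapping of fixed-length tags: a tag maps if its
    sequence (or its reverse complement) occurs exactly once in the
    genome, counting both orientations together.  Mirrors the
    unique-hits-only contract of an aligner run at zero mismatches.
    """

    def __init__(self, genome: Mapping[str, np.ndarray], k: int = 20):
        self.k = int(k)
        if not (1 <= self.k <= 31):
            raise ValueError("k must be in 1..31")
        self.chroms = list(genome)
        self._shift = np.uint64(64 - 2 * self.k)
        self._pos_mask = np.uint64((1 << int(self._shift)) - 1)
        # each chromosome's k-mers packed as (code << shift) | position,
        # then plain-sorted: range queries on the code prefix give both
        # the hit count and the hit position without an argsort
        self._packed: list[np.ndarray] = []
        for chrom in self.chroms:
            arr = genome[chrom]
            if arr.dtype != np.uint8:
                arr = encode(arr) if isinstance(arr, (str, bytes)) else arr.astype(np.uint8)
            codes = kmer_codes(arr, self.k)
            if codes.size > int(self._pos_mask):
                raise ValueError(
                    f"chromosome longer than {int(self._pos_mask)} bp not "
                    f"supported at k={self.k}"
                )
            packed = (codes << self._shift) | np.arange(codes.size, dtype=np.uint64)
            packed.sort()
            self._packed.append(packed)

    def _locate(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Total hit count, chrom index and position of the first hit."""
        n = query.size
        counts = np.zeros(n, dtype=np.int64)
        chrom_idx = np.full(n, -1, dtype=np.int64)
        pos = np.full(n, -1, dtype=np.int64)
        key_lo = query << self._shift
        key_hi = key_lo | self._pos_mask
        for ci, packed in enumerate(self._packed):
            lo = np.searchsorted(packed, key_lo, side="left")
            hi = np.searchsorted(packed, key_hi, side="right")
            c = hi - lo
            first = (counts == 0) & (c > 0)
            if first.any():
                chrom_idx[first] = ci
                pos[first] = (packed[lo[first]] & self._pos_mask).astype(np.int64)
            counts += c
        return counts, chrom_idx, pos

    def map_tags(self, seqs: Sequence[str]) -> pd.DataFrame:
        """Map tag sequences; unique forward hit -> '+', unique RC hit -> '-'.

        Returns a frame aligned with ``seqs`` with columns
        ``mapped, chrom, start, end, strand``; ambiguous (total hits != 1
        across both orientations) and invalid tags are left unmapped.
        """
        n = len(seqs)
        k = self.k
        valid = np.fromiter((len(s) == k for s in seqs), dtype=bool, count=n)
        # pack all fixed-length tags at once; invalid-length rows become all-A
        joined = "".join(s if len(s) == k else "A" * k for s in seqs)
        mat = _ENCODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)].reshape(n, k)
        valid &= ~(mat > 3).any(axis=1)
        mat = np.where(mat > 3, 0, mat).astype(np.uint64)
        rc = (np.uint64(3) - mat)[:, ::-1]
        fwd = np.zeros(n, dtype=np.uint64)
        rev = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            fwd = (fwd << np.uint64(2)) | mat[:, j]
            rev = (rev << np.uint64(2)) | rc[:, j]
        cnt_f, chrom_f, pos_f = self._locate(fwd)
        cnt_r, chrom_r, pos_r = self._locate(rev)
        total = np.where(valid, cnt_f + cnt_r, 0)
        mapped = total == 1
        use_fwd = mapped & (cnt_f == 1)
        use_rev = mapped & ~use_fwd
        start = np.full(n, -1, dtype=np.int64)
        start[use_fwd] = pos_f[use_fwd]
        start[use_rev] = pos_r[use_rev]
        chrom_idx = np.full(n, len(self.chroms), dtype=np.int64)
        chrom_idx[use_fwd] = chrom_f[use_fwd]
        chrom_idx[use_rev] = chrom_r[use_rev]
        strand = np.where(use_fwd, "+", "-")
        chrom_names = np.array(self.chroms + ["*"], dtype=object)
        return pd.DataFrame(
            {
                "mapped": mapped,
                "chrom": chrom_names[chrom_idx],
                "start": start,
                "end": np.where(mapped, start + self.k, -1),
                "strand": strand,
            }
        )


def find_motif(codes: np.ndarray, motif: str) -> np.ndarray:
    """0-based start positions of every occurrence of `motif` (forward strand)."""
    m = encode(motif)
    if codes.size < m.size:
        return np.empty(0, dtype=np.int64)
    hit = codes[: codes.size - m.size + 1] == m[0]
    for i in range(1, m.size):
        hit &= codes[i : codes.size - m.size + 1 + i] == m[i]
    return np.flatnonzero(hit).astype(np.int64)
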