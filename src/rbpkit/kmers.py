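"""Shared nucleotide k-mer machinery.

Sequences are handled internally as uint8 code arrays with A=0, C=1, G=2,
U/T=3.  Any other character maps to a sentinel code that poisons every
window overlapping it, so ambiguous bases are skipped rather than counted.
All RNA-side analysis uses the {A,C,G,U} alphabet; T is accepted on input
and treated as U.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"
SENTINEL = 4

_CODES = np.full(256, SENTINEL, dtype=np.uint8)
for _i, _b in enumerate(RNA_BASES):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i
_CODES[ord("T")] = 3
_CODES[ord("t")] = 3

_RNA_LETTERS = np.frombuffer(b"ACGU", dtype=np.uint8)
_DNA_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (T and U both map to 3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


def decode(codes: np.ndarray, rna: bool = True) -> str:
    """Decode a code array back to a string (RNA letters by default)."""
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.size and codes.max() >= SENTINEL:
        raise ValueError("cannot decode sentinel (non-ACGU) codes")
    letters = _RNA_LETTERS if rna else _DNA_LETTERS
    return letters[codes].tobytes().decode("ascii")


def kmer_to_code(kmer: str) -> int:
    """Integer code of a k-mer under the base-4 encoding (A<C<G<U).

    Because the encoding is order-preserving, sorting by code equals
    sorting k-mer strings lexicographically.
    """
    codes = encode(kmer)
    if codes.size == 0 or (codes >= SENTINEL).any():
        raise ValueError(f"non-ACGU/T character in k-mer {kmer!r}")
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return code


def code_to_kmer(code: int, k: int, rna: bool = True) -> str:
    out = [(code >> shift) & 3 for shift in range(2 * (k - 1), -2, -2)]
    return decode(np.array(out, dtype=np.uint8), rna=rna)


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of every length-k window plus a validity mask.

    Windows touching a sentinel (non-ACGU) position are flagged invalid;
    their code values are meaningless and must be masked by the caller.
    """
    codes = np.asarray(codes)
    if codes.size < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (win < SENTINEL).all(axis=1)
    return win.astype(np.int64) @ powers, valid


def count_kmers(seqs: Iterable[str | np.ndarray], k: int) -> np.ndarray:
    """Overlapping k-mer counts across sequences (length-4^k vector).

    Windows never span sequence boundaries; windows containing ambiguous
    bases are skipped.
    """
    total = np.zeros(4**k, dtype=np.int64)
    for s in seqs:
        codes = encode(s) if isinstance(s, str) else s
        w, valid = window_codes(codes, k)
        if w.size:
            total += np.bincount(w[valid], minlength=4**k)
    return total


def pooled_window_index(
    code_arrays: Sequence[np.ndarray], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Window codes across many sequences with their sequence index.

    Returns ``(wcodes, wseq)`` where ``wcodes[i]`` is the code of the i-th
    valid window and ``wseq[i]`` the index of the sequence it came from,
    in sequence order then position order.  Implemented by concatenating
    all sequences with sentinel separators so a single vectorized pass
    covers the whole pool.
    """
    n = len(code_arrays)
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32)
    lens = np.fromiter((len(c) for c in code_arrays), count=n, dtype=np.int64)
    sep = np.full(1, SENTINEL, dtype=np.uint8)
    parts: list[np.ndarray] = []
    for c in code_arrays:
        parts.append(np.asarray(c, dtype=np.uint8))
        parts.append(sep)
    cat = np.concatenate(parts)
    w, valid = window_codes(cat, k)
    # start position -> owning sequence (each sequence owns its bases plus
    # the following separator; separator-touching windows are invalid)
    seq_of_start = np.repeat(np.arange(n, dtype=np.int32), lens + 1)[: w.size]
    return w[valid], seq_of_start[valid]


DEFAULT_EXCLUDED_7MERS = ("GCUCUUC", "CGAGAAG")


@dataclass(frozen=True)
class KmerUniverse:
    """The set of k-mers that are scored.

    By default for k=7 the two 7-mers corresponding to the SapI/BspQI
    restriction site used during template generation (GCUCUUC and CGAGAAG
    on the RNA side) are excluded from scoring, leaving 16,382 members.
    Exclusion is from the *scored* set only: probes may still contain
    these subsequences.
    """

    k: int
    excluded: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for w in self.excluded:
            if len(w) != self.k:
                raise ValueError(f"excluded k-mer {w!r} has length != {self.k}")

    @cached_property
    def excluded_codes(self) -> np.ndarray:
        return np.array(sorted(kmer_to_code(w) for w in self.excluded), dtype=np.int64)

    @cached_property
    def member_mask(self) -> np.ndarray:
        mask = np.ones(4**self.k, dtype=bool)
        mask[self.excluded_codes] = False
        return mask

    @cached_property
    def member_codes(self) -> np.ndarray:
        return np.flatnonzero(self.member_mask).astype(np.int64)

    @property
    def n_members(self) -> int:
        return 4**self.k - len(self.excluded)

    def members(self) -> list[str]:
        return [code_to_kmer(c, self.k) for c in self.member_codes]


def default_universe(k: int = 7) -> KmerUniverse:
    """The standard scoring universe: all 7-mers minus the SapI-site pair."""
    excluded = frozenset(DEFAULT_EXCLUDED_7MERS) if k == 7 else frozenset()
    return KmerUniverse(k=k, excluded=excluded)
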