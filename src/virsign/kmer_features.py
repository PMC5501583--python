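"""Canonical k-mer spaces and normalized word-frequency signatures.

A sequence is summarized by the frequencies of its length-k words after
collapsing every word with its reverse complement into a single canonical
representative (the lexicographic minimum of the pair).  Collapsing makes
the signature identical for a sequence and its reverse complement, so the
classifier built on top is strand-independent.  For k = 4 there are 136
canonical words; in general (4^k + 4^(k/2)) / 2 for even k (palindromes
are their own partner) and 4^k / 2 for odd k.

Counting slides a width-k window one base at a time; windows containing
any non-ACGT character are skipped.  Frequencies are counts normalized to
sum to one over the canonical space.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, TextIO

import numpy as np

__all__ = [
    "KmerSpace",
    "CountVector",
    "FeatureVector",
    "enumerate_canonical_kmers",
    "count_kmers",
    "normalize_counts",
    "featurize",
    "feature_matrix",
    "write_feature_table",
    "revcomp",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit base code, 4 marks N/invalid
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed 2-bit k-mer codes."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << 2) | ((tmp & 3) ^ 3)
        tmp >>= 2
    return out


def _decode(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


@dataclasses.dataclass(frozen=True)
class KmerSpace:
    """The ordered set of canonical k-mers with O(1) raw-word lookup.

    ``codes`` holds the packed 2-bit encodings of the canonical words in
    lexicographic order; ``lookup`` maps any raw k-mer code to its
    position in that order.
    """

    k: int
    codes: np.ndarray  # sorted canonical codes, shape (size,)
    lookup: np.ndarray  # raw code -> canonical index, shape (4**k,)
    _words: list[str] | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def size(self) -> int:
        return len(self.codes)

    @property
    def words(self) -> list[str]:
        if self._words is None:
            object.__setattr__(
                self, "_words", [_decode(int(c), self.k) for c in self.codes]
            )
        return self._words

    def index_of(self, word: str) -> int:
        """Position of a raw k-mer (or its reverse complement) in the space."""
        if len(word) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {word!r}")
        code = 0
        for ch in word.upper():
            b = _CODE[ord(ch)]
            if b == 4:
                raise ValueError(f"word contains non-ACGT character: {word!r}")
            code = (code << 2) | int(b)
        return int(self.lookup[code])


@dataclasses.dataclass(frozen=True)
class CountVector:
    """Canonical k-mer occurrence counts for one sequence."""

    space: KmerSpace
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Normalized word frequencies; the classifier's input signature."""

    space: KmerSpace
    freqs: np.ndarray


def enumerate_canonical_kmers(k: int) -> KmerSpace:
    """Build the canonical k-mer space for word length *k*.

    Every length-k word over {A,C,G,T} maps, directly or via its reverse
    complement, to exactly one canonical word: the lexicographic minimum
    of the pair.
    """
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    if k > 12:
        raise ValueError(f"k > 12 is not supported (lookup table too large), got {k}")
    raw = np.arange(4**k, dtype=np.int64)
    canon = np.minimum(raw, _revcomp_codes(raw, k))
    codes = np.unique(canon)  # sorted => lexicographic order of words
    lookup = np.searchsorted(codes, canon).astype(np.int64)
    return KmerSpace(k=k, codes=codes, lookup=lookup)


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Packed codes of all valid (N-free) k-windows of *seq*."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | np.where(arr[i : n - k + 1 + i] == 4, 0, arr[i : n - k + 1 + i])
    bad = np.cumsum(np.concatenate(([0], (arr == 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes[valid]


def count_kmers(seq: str, space: KmerSpace) -> CountVector:
    """Count canonical k-mer occurrences in *seq*.

    A word and its reverse complement pool into one count; a palindromic
    window increments its (self-canonical) word once.  Windows containing
    N are skipped.  A sequence shorter than k yields all-zero counts.
    """
    codes = _window_codes(seq, space.k)
    counts = np.bincount(space.lookup[codes], minlength=space.size)
    return CountVector(space=space, counts=counts.astype(np.int64))


def normalize_counts(cv: CountVector) -> FeatureVector:
    """Convert counts N(w) to frequencies V(w) = N(w) / sum N(w)."""
    total = cv.total
    if total == 0:
        raise ValueError(
            "cannot normalize an all-zero count vector (sequence shorter "
            "than k or entirely N)"
        )
    return FeatureVector(space=cv.space, freqs=cv.counts / total)


def featurize(seq: str, space: KmerSpace) -> FeatureVector:
    """Signature of one sequence: count then normalize."""
    return normalize_counts(count_kmers(seq, space))


def feature_matrix(seqs: Sequence[str], space: KmerSpace) -> np.ndarray:
    """Stack signatures of many sequences into an (n, space.size) matrix."""
    X = np.empty((len(seqs), space.size), dtype=np.float64)
    for i, s in enumerate(seqs):
        X[i] = featurize(s, space).freqs
    return X


def write_feature_table(
    ids: Sequence[str], X: np.ndarray, space: KmerSpace, handle: TextIO
) -> None:
    """Write a feature matrix as tab-separated text with a word header."""
    handle.write("id\t" + "\t".join(space.words) + "\n")
    for name, row in zip(ids, X):
        handle.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
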