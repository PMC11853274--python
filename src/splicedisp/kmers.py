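"""Hexamer vocabulary and dinucleotide-containment subsets.

The 4096 hexamers over {A, C, G, T} are split, for each of the 16
dinucleotides XY, into an *XY1* subset (hexamers containing XY as a
contiguous substring, overlaps allowed) and the complementary *XY0*
subset.  For k = 6 the split is 1185/2911 when X != Y and 991/3105 when
X == Y.  ``avoidance_count`` gives the same XY0 sizes by a linear
recurrence and serves as an independent combinatorial oracle for the
enumeration.

Vocabulary order is lexicographic with A < C < G < T throughout the
package; matrices index k-mers by this rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

BASES = "ACGT"
#: the 16 dinucleotides in lexicographic order: AA, AC, ..., TT
PATTERNS: Tuple[str, ...] = tuple(x + y for x in BASES for y in BASES)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_MAX_K = 12


def enumerate_kmers(k: int) -> list[str]:
    """Return all k-mers over ACGT in lexicographic order (length 4**k)."""
    if not 1 <= int(k) <= _MAX_K:
        raise ValueError(f"k must be in [1, {_MAX_K}], got {k!r}")
    return ["".join(p) for p in itertools.product(BASES, repeat=int(k))]


def kmer_rank(kmer: str) -> int:
    """Lexicographic rank of a k-mer: 'AAAAAA' -> 0, 'TTTTTT' -> 4**6 - 1."""
    rank = 0
    for c in kmer:
        try:
            rank = rank * 4 + _BASE_INDEX[c]
        except KeyError:
            raise ValueError(f"invalid base {c!r} in k-mer {kmer!r}") from None
    return rank


def rank_to_kmer(rank: int, k: int) -> str:
    if not 0 <= rank < 4**k:
        raise ValueError(f"rank {rank} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(BASES[rank % 4])
        rank //= 4
    return "".join(reversed(out))


def _validate_pattern(pattern: str) -> None:
    if len(pattern) != 2 or any(c not in _BASE_INDEX for c in pattern):
        raise ValueError(f"pattern must be a dinucleotide over ACGT, got {pattern!r}")


def contains_pattern(kmer: str, pattern: str) -> bool:
    """True iff the dinucleotide occurs as a contiguous substring of the k-mer.

    Containment is orientation-specific: "AG" means A immediately followed
    by G on the given strand; reverse complements are not pooled.
    """
    _validate_pattern(pattern)
    if any(c not in _BASE_INDEX for c in kmer):
        raise ValueError(f"invalid sequence {kmer!r}")
    return pattern in kmer


def _digit_matrix(k: int) -> np.ndarray:
    """Base-4 digits of ranks 0..4**k-1, shape (4**k, k), most significant first."""
    ranks = np.arange(4**k)
    return (ranks[:, None] // 4 ** np.arange(k - 1, -1, -1)) % 4


def pattern_membership(k: int, pattern: str) -> np.ndarray:
    """Boolean vector over the rank-ordered vocabulary: contains XY or not."""
    _validate_pattern(pattern)
    if k < 2:
        raise ValueError("pattern cannot fit in a k-mer with k < 2")
    d = _digit_matrix(k)
    x, y = _BASE_INDEX[pattern[0]], _BASE_INDEX[pattern[1]]
    hit = (d[:, :-1] == x) & (d[:, 1:] == y)
    return hit.any(axis=1)


def partition_by_pattern(k: int, pattern: str) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of the XY1 and XY0 subsets: a disjoint cover of the vocabulary."""
    member = pattern_membership(k, pattern)
    ranks = np.arange(4**k)
    return ranks[member], ranks[~member]


def avoidance_count(k: int, self_overlapping: bool) -> int:
    """Number of k-mers avoiding a fixed dinucleotide, by linear recurrence.

    ``self_overlapping`` distinguishes the X == Y case (the pattern can
    overlap itself) from X != Y.  With a_0 = 1, a_1 = 4:

    * X != Y:  a_n = 4 a_{n-1} - a_{n-2}
    * X == Y:  a_n = 3 a_{n-1} + 3 a_{n-2}
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    a_prev, a = 1, 4
    if k == 0:
        return 1
    for _ in range(k - 1):
        if self_overlapping:
            a_prev, a = a, 3 * a + 3 * a_prev
        else:
            a_prev, a = a, 4 * a - a_prev
    return a


@dataclass(frozen=True)
class SubsetPartition:
    """Membership of every k-mer in the 16 XY1/XY0 subset pairs.

    ``membership[pattern]`` is a boolean vector over the rank-ordered
    vocabulary; True marks XY1 members.
    """

    k: int
    membership: Dict[str, np.ndarray] = field(repr=False)

    @classmethod
    def build(cls, k: int = 6) -> "SubsetPartition":
        if k < 2:
            raise ValueError("pattern cannot fit in a k-mer with k < 2")
        d = _digit_matrix(k)
        membership = {}
        for pat in PATTERNS:
            x, y = _BASE_INDEX[pat[0]], _BASE_INDEX[pat[1]]
            membership[pat] = ((d[:, :-1] == x) & (d[:, 1:] == y)).any(axis=1)
        return cls(k=k, membership=membership)

    def xy1(self, pattern: str) -> np.ndarray:
        """Ranks of k-mers containing the dinucleotide."""
        return np.flatnonzero(self.membership[pattern])

    def xy0(self, pattern: str) -> np.ndarray:
        """Ranks of k-mers not containing the dinucleotide."""
        return np.flatnonzero(~self.membership[pattern])

    def sizes(self, pattern: str) -> tuple[int, int]:
        m = self.membership[pattern]
        n1 = int(m.sum())
        return n1, m.size - n1

    def to_frame(self) -> pd.DataFrame:
        """Long membership table: kmer, rank, then 16 columns AA1..TT1 of 0/1."""
        kmers = enumerate_kmers(self.k)
        data = {"kmer": kmers, "rank": np.arange(4**self.k)}
        for pat in PATTERNS:
            data[f"{pat}1"] = self.membership[pat].astype(int)
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
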