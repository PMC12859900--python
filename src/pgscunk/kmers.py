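"""Canonical k-mer counting and the set algebra the SCUnK score is built on.

Every k-length window of a sequence is collapsed to its *canonical* form —
the lexicographically smaller of the window and its reverse complement —
so counting is strand-free: a node stored in reverse orientation yields the
same tally as its forward twin. Windows containing any non-ACGT symbol
(N, IUPAC ambiguity codes) carry no exact-match information and are skipped
entirely, and windows never span two records of a sequence collection.

The module exposes a small multiset/set algebra: :func:`count_kmers` builds a
:class:`KmerCountTable`, :func:`single_copy` reduces it to the k-mers seen
exactly once, and :func:`intersect_all` intersects such sets across
assemblies — the composition that defines single-copy universal k-mers.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "revcomp",
    "canonical",
    "count_kmers",
    "single_copy",
    "intersect_all",
    "lookup",
    "KmerCountTable",
    "KmerSet",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_RUN = re.compile(r"[ACGT]+")
_ACGT_ONLY = re.compile(r"[ACGT]+\Z")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Return the canonical form of ``kmer``: min(kmer, revcomp(kmer)).

    Idempotent. Raises ``ValueError`` on characters outside {A,C,G,T}.
    """
    if not _ACGT_ONLY.match(kmer):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerCountTable:
    """Multiset of canonical k-mers with occurrence counts.

    Keys are canonical ACGT strings of length ``k``; values are >= 1.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        """Total window mass: the number of counted (ACGT-only) windows."""
        return sum(self.counts.values())

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(kmer, default)


@dataclass(frozen=True)
class KmerSet:
    """Set of canonical k-mers sharing one k."""

    k: int
    members: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.members


def iter_canonical(seq: str, k: int) -> Iterator[str]:
    """Yield canonical k-mers of every ACGT-only window of ``seq``.

    The reverse complement of each maximal ACGT run is materialised once,
    so each window costs two slices and a comparison.
    """
    for m in _ACGT_RUN.finditer(seq):
        run = m.group()
        n = len(run)
        if n < k:
            continue
        rc = run.translate(_COMPLEMENT)[::-1]
        for i in range(n - k + 1):
            f = run[i : i + k]
            r = rc[n - i - k : n - i]
            yield f if f <= r else r


def count_kmers(sequences: Iterable[str], k: int) -> KmerCountTable:
    """Tally canonical k-mers over a collection of sequences.

    Windows slide over each sequence independently (never across record
    boundaries); windows containing a non-ACGT character are skipped;
    sequences shorter than k contribute nothing.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    tally: Counter[str] = Counter()
    for seq in sequences:
        tally.update(iter_canonical(seq, k))
    return KmerCountTable(k=k, counts=dict(tally))


def single_copy(table: KmerCountTable) -> KmerSet:
    """K-mers occurring exactly once in the table."""
    return KmerSet(
        k=table.k,
        members=frozenset(km for km, c in table.counts.items() if c == 1),
    )


def intersect_all(sets: Iterable[KmerSet]) -> KmerSet:
    """Intersection of k-mer sets; all must share the same k."""
    sets = list(sets)
    if not sets:
        raise ValueError("cannot intersect an empty collection of k-mer sets")
    ks = {s.k for s in sets}
    if len(ks) > 1:
        raise ValueError(f"mixed k-mer sizes in intersection: {sorted(ks)}")
    members = frozenset.intersection(*(s.members for s in sets))
    return KmerSet(k=sets[0].k, members=members)


def lookup(table: KmerCountTable, kmer: str) -> int:
    """Occurrence count of a canonical k-mer; 0 when absent.

    The query must be canonical and of the table's k.
    """
    if len(kmer) != table.k:
        raise ValueError(
            f"query length {len(kmer)} does not match table k={table.k}"
        )
    if canonical(kmer) != kmer:
        raise ValueError(f"query k-mer is not canonical: {kmer!r}")
    return table.counts.get(kmer, 0)


def write_kmer_list(kmers: Iterable[str], path) -> None:
    """Write one canonical k-mer per line (interoperability export)."""
    with open(path, "w") as fh:
        for km in sorted(kmers):
            fh.write(km + "\n")
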