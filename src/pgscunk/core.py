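"""The SCUnK score proper.

A k-mer that occurs exactly once in every source assembly (single-copy and
universal, a *SCUnK*) is presumed orthologous, so a graph that faithfully
represents its assemblies should carry it exactly once, in full, within its
node sequences. Each SCUnK is therefore classified against the multiset of
canonical k-mers of the graph's nodes:

* ``unique``     — node count exactly 1 (represented once, in full);
* ``duplicated`` — node count >= 2 (redundantly collapsed / repeated);
* ``split``      — node count 0 (no node carries the full window, i.e. the
  k-mer is fragmented across a node boundary).

The three class percentages sum to 100 and form the ternary score. The
graph is scored as-is: no preprocessing, no path-aware filtering — the
method is intended for the raw graph straight out of construction, before
any simplification that could disturb exact k-mer matches.

``inflation_score`` is the companion structural metric: graph total
nucleotide length over the length of a single reference assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

from .io import Assembly, PangenomeGraph
from .kmers import KmerSet, count_kmers, intersect_all, single_copy

__all__ = [
    "ScunkClassification",
    "ScunkStats",
    "PgScunkResult",
    "find_scunks",
    "classify_scunks",
    "run_pgscunk",
    "inflation_score",
]

DEFAULT_K = 100

LABELS = ("unique", "duplicated", "split")


@dataclass(eq=False)
class ScunkClassification:
    """Per-SCUnK labels plus the aggregate ternary point.

    ``labels`` maps each canonical SCUnK to one of ``unique``,
    ``duplicated``, ``split``. Percentages are exact rationals scaled to
    floats; they always sum to 100 (up to float rounding).
    """

    k: int
    labels: dict[str, str]

    @cached_property
    def _tally(self) -> dict[str, int]:
        t = {lab: 0 for lab in LABELS}
        for lab in self.labels.values():
            t[lab] += 1
        return t

    @property
    def n_scunks(self) -> int:
        return len(self.labels)

    @property
    def n_unique(self) -> int:
        return self._tally["unique"]

    @property
    def n_duplicated(self) -> int:
        return self._tally["duplicated"]

    @property
    def n_split(self) -> int:
        return self._tally["split"]

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_scunks

    @property
    def pct_unique(self) -> float:
        return self._pct(self.n_unique)

    @property
    def pct_duplicated(self) -> float:
        return self._pct(self.n_duplicated)

    @property
    def pct_split(self) -> float:
        return self._pct(self.n_split)

    @property
    def ternary(self) -> tuple[float, float, float]:
        """(pct_unique, pct_duplicated, pct_split) — the ternary-plot point."""
        return (self.pct_unique, self.pct_duplicated, self.pct_split)

    def kmers_with_label(self, label: str) -> list[str]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return sorted(km for km, lab in self.labels.items() if lab == label)

    def summary(self) -> str:
        u, d, s = self.ternary
        return (
            f"SCUnK classification (k={self.k}, n={self.n_scunks}): "
            f"unique {u:.2f}% | duplicated {d:.2f}% | split {s:.2f}%"
        )


@dataclass
class ScunkStats:
    """Bookkeeping around SCUnK discovery.

    ``scunk_fraction`` relates the SCUnK count to the number of distinct
    canonical k-mers in a designated reference assembly (the first listed,
    by default); it quantifies how much of the genome the score actually
    interrogates, and collapses as k grows.
    """

    k: int
    per_assembly_single_copy: dict[str, int]
    n_scunks: int
    reference_assembly: str
    reference_distinct_kmers: int

    @property
    def scunk_fraction(self) -> float:
        if self.reference_distinct_kmers == 0:
            return 0.0
        return self.n_scunks / self.reference_distinct_kmers


@dataclass
class PgScunkResult:
    """End-to-end result: the classification plus discovery stats."""

    classification: ScunkClassification
    stats: ScunkStats

    def summary(self) -> str:
        lines = [self.classification.summary()]
        for name, n in self.stats.per_assembly_single_copy.items():
            lines.append(f"  single-copy k-mers in {name}: {n}")
        lines.append(
            f"  SCUnK fraction of {self.stats.reference_assembly}: "
            f"{self.stats.scunk_fraction:.4f}"
        )
        return "\n".join(lines)


def find_scunks(
    assemblies: Sequence[Assembly], k: int
) -> tuple[KmerSet, ScunkStats]:
    """Derive the SCUnK set: k-mers single-copy in *every* assembly.

    Each assembly is counted over all its contigs jointly, reduced to its
    single-copy canonical k-mers, and the per-assembly sets are intersected.
    Tables are discarded assembly-by-assembly, so memory tracks distinct
    k-mers, not genome size.
    """
    assemblies = list(assemblies)
    if not assemblies:
        raise ValueError("need at least one assembly")
    if len(assemblies) == 1:
        warnings.warn(
            "only one assembly supplied; universality is trivial and the "
            "SCUnK set reduces to its single-copy k-mers",
            stacklevel=2,
        )
    per_assembly: dict[str, int] = {}
    sets: list[KmerSet] = []
    reference_distinct = 0
    for i, asm in enumerate(assemblies):
        table = count_kmers(asm.sequences(), k)
        if i == 0:
            reference_distinct = table.n_distinct
        sc = single_copy(table)
        per_assembly[asm.name] = len(sc)
        sets.append(sc)
    scunks = intersect_all(sets)
    stats = ScunkStats(
        k=k,
        per_assembly_single_copy=per_assembly,
        n_scunks=len(scunks),
        reference_assembly=assemblies[0].name,
        reference_distinct_kmers=reference_distinct,
    )
    return scunks, stats


def classify_scunks(
    scunks: KmerSet, graph: PangenomeGraph, k: int
) -> ScunkClassification:
    """Label every SCUnK by its occurrence count in the graph's nodes."""
    if scunks.k != k:
        raise ValueError(f"SCUnK set has k={scunks.k}, expected {k}")
    if len(scunks) == 0:
        raise ValueError(
            "no SCUnKs at this k; decrease k or check assemblies"
        )
    node_table = count_kmers(graph.sequences(), k)
    labels: dict[str, str] = {}
    for km in scunks:
        c = node_table.get(km)
        if c == 1:
            labels[km] = "unique"
        elif c >= 2:
            labels[km] = "duplicated"
        else:
            labels[km] = "split"
    return ScunkClassification(k=k, labels=labels)


def run_pgscunk(
    graph: PangenomeGraph,
    assemblies: Sequence[Assembly],
    k: int = DEFAULT_K,
) -> PgScunkResult:
    """Full workflow: find SCUnKs in the assemblies, classify against the graph."""
    scunks, stats = find_scunks(assemblies, k)
    classification = classify_scunks(scunks, graph, k)
    return PgScunkResult(classification=classification, stats=stats)


def inflation_score(graph: PangenomeGraph, reference: Assembly) -> float:
    """Graph total nucleotide length over the reference assembly's length."""
    ref_len = reference.total_length
    if ref_len == 0:
        raise ValueError(f"reference assembly {reference.name!r} has zero length")
    return graph.total_length / ref_len
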