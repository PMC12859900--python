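"""Map labeled SCUnKs back onto an assembly's coordinates.

Because a SCUnK is single-copy in every source assembly, each labeled
k-mer has exactly one occurrence (forward or reverse strand) in any of
those assemblies; :func:`locate_scunks` finds it and emits a BED-style
record, and :func:`merge_regions` collapses nearby records per class into
intervals carrying a member count. Finding zero or multiple occurrences
means the supplied assembly is not a source of the scored graph, which is
reported as an error naming the offending k-mer.

Matching is exact over both strands via canonical comparison; windows
containing IUPAC-ambiguous bases can never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ScunkClassification
from .io import Assembly, RegionRecord
from .kmers import _ACGT_RUN, _COMPLEMENT

__all__ = ["locate_scunks", "merge_regions", "MergedRegion"]


@dataclass(frozen=True)
class MergedRegion:
    """A run of nearby same-label SCUnK hits on one contig."""

    contig: str
    start: int
    end: int
    label: str
    n_kmers: int


def locate_scunks(
    assembly: Assembly, classification: ScunkClassification, k: int
) -> list[RegionRecord]:
    """Find the single occurrence of every labeled SCUnK in ``assembly``.

    Returns one record per SCUnK with 0-based half-open coordinates; a
    forward-strand match is a window equal to the canonical k-mer, a
    reverse-strand match is a window whose reverse complement equals it.
    """
    labels = classification.labels
    hits: dict[str, list[RegionRecord]] = {km: [] for km in labels}
    for contig_id, seq in assembly.contigs:
        for m in _ACGT_RUN.finditer(seq):
            run = m.group()
            n = len(run)
            if n < k:
                continue
            off = m.start()
            rc = run.translate(_COMPLEMENT)[::-1]
            for i in range(n - k + 1):
                fwd = run[i : i + k]
                rev = rc[n - i - k : n - i]
                canon = fwd if fwd <= rev else rev
                if canon in hits:
                    hits[canon].append(
                        RegionRecord(
                            contig=contig_id,
                            start=off + i,
                            end=off + i + k,
                            label=labels[canon],
                            strand="+" if fwd == canon else "-",
                            kmer=canon,
                        )
                    )
    records: list[RegionRecord] = []
    for km, occ in hits.items():
        if len(occ) != 1:
            raise ValueError(
                f"SCUnK {km} occurs {len(occ)} times in assembly "
                f"{assembly.name!r}; expected exactly one occurrence — is "
                "this a source assembly of the scored graph?"
            )
        records.append(occ[0])
    records.sort(key=lambda r: (r.contig, r.start))
    return records


def merge_regions(
    records: Iterable[RegionRecord], max_gap: int = 0
) -> list[MergedRegion]:
    """Merge same-contig, same-label records separated by <= ``max_gap`` bases.

    ``max_gap`` 0 merges overlapping or book-ended intervals only. Each
    merged interval carries the count of member SCUnKs, so total SCUnK mass
    is conserved.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    groups: dict[tuple[str, str], list[RegionRecord]] = {}
    for r in records:
        groups.setdefault((r.contig, r.label), []).append(r)
    merged: list[MergedRegion] = []
    for (contig, label), recs in groups.items():
        recs.sort(key=lambda r: r.start)
        cur_start, cur_end, cur_n = recs[0].start, recs[0].end, 1
        for r in recs[1:]:
            if r.start - cur_end <= max_gap:
                cur_end = max(cur_end, r.end)
                cur_n += 1
            else:
                merged.append(MergedRegion(contig, cur_start, cur_end, label, cur_n))
                cur_start, cur_end, cur_n = r.start, r.end, 1
        merged.append(MergedRegion(contig, cur_start, cur_end, label, cur_n))
    merged.sort(key=lambda m: (m.contig, m.start, m.label))
    return merged


def write_merged_bed(merged: Sequence[MergedRegion], path) -> None:
    """Write merged regions as BED: contig, start, end, label, member count."""
    with open(path, "w") as fh:
        for m in merged:
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\t{m.label}\t{m.n_kmers}\t.\n")
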