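"""Readers and writers for the formats the tool touches.

GFA1 graphs are read segment-by-segment: only ``S`` records matter to the
score (the method consults node sequences exclusively), so links, paths,
walks, headers, comments and unknown record types are skipped without
error. Assemblies are read from FASTA via Biopython. Outputs are a BED6
file of per-k-mer regions and a one-row TSV report of the ternary score.

Coordinates are 0-based half-open everywhere, matching BED. Soft-masked
(lowercase) bases are uppercased on load: masking is annotation, not
sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "GraphNode",
    "PangenomeGraph",
    "Assembly",
    "RegionRecord",
    "GfaParseError",
    "read_gfa",
    "read_fasta",
    "write_node_fasta",
    "write_regions_bed",
    "write_report",
]


class GfaParseError(ValueError):
    """Raised for malformed or sequence-less GFA input."""


@dataclass(frozen=True)
class GraphNode:
    """A sequence-bearing graph segment (GFA ``S`` record)."""

    id: str
    sequence: str


@dataclass
class PangenomeGraph:
    """Ordered collection of named, sequence-bearing nodes.

    Edges and paths play no role in the score: a k-mer fragmented across
    nodes is by definition invisible to per-node window counting, which is
    precisely the mechanism that defines the "split" class.
    """

    nodes: list[GraphNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate segment id in graph: {dup!r}")

    @property
    def total_length(self) -> int:
        return sum(len(n.sequence) for n in self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> GraphNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node with id {node_id!r}")

    def sequences(self) -> list[str]:
        return [n.sequence for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Assembly:
    """A haplotype assembly: named, ordered contigs."""

    name: str
    contigs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"assembly {self.name!r} has no contigs")
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(
                f"duplicate contig id {dup!r} in assembly {self.name!r}"
            )

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequences(self) -> list[str]:
        return [s for _, s in self.contigs]

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(f"no contig {contig_id!r} in assembly {self.name!r}")


@dataclass(frozen=True)
class RegionRecord:
    """Location of one labeled SCUnK in an assembly (0-based half-open)."""

    contig: str
    start: int
    end: int
    label: str
    strand: str
    kmer: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.label not in ("unique", "duplicated", "split"):
            raise ValueError(f"bad label {self.label!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != len(self.kmer):
            raise ValueError("interval length does not match k-mer length")


def read_gfa(path) -> PangenomeGraph:
    """Read a GFA1 graph, keeping only segment records with inline sequences.

    Raises :class:`GfaParseError` for an ``S`` line with fewer than three
    fields (naming the line number), for a ``*`` placeholder sequence, and
    for duplicate segment ids.
    """
    nodes: list[GraphNode] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or not line.startswith("S\t"):
                continue  # L, P, W, H, #, unknown: not consulted
            fields = line.split("\t")
            if len(fields) < 3:
                raise GfaParseError(
                    f"{path}: malformed S line at line {lineno}: "
                    f"expected >= 3 tab-separated fields, got {len(fields)}"
                )
            seg_id, seq = fields[1], fields[2]
            if seq == "*":
                raise GfaParseError(
                    f"{path}: segment {seg_id!r} at line {lineno} has no "
                    "sequence; graph must carry inline node sequences"
                )
            if seg_id in seen:
                raise GfaParseError(
                    f"{path}: duplicate segment id {seg_id!r} at line {lineno}"
                )
            seen.add(seg_id)
            nodes.append(GraphNode(id=seg_id, sequence=seq.upper()))
    return PangenomeGraph(nodes=nodes)


def read_fasta(path, name: str | None = None) -> Assembly:
    """Read a (possibly line-wrapped, possibly soft-masked) FASTA assembly.

    ``name`` defaults to the file stem. Empty files, empty-sequence contigs
    and duplicate contig ids are errors.
    """
    if name is None:
        name = Path(path).stem
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: contig {rec.id!r} has empty sequence")
        contigs.append((rec.id, seq))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return Assembly(name=name, contigs=contigs)


def write_node_fasta(graph: PangenomeGraph, path) -> None:
    """Write graph node sequences as FASTA (one record per node)."""
    with open(path, "w") as fh:
        for node in graph.nodes:
            fh.write(f">{node.id}\n{node.sequence}\n")


def write_regions_bed(records: Iterable[RegionRecord], path) -> None:
    """Write BED6: contig, start, end, label:kmer, 0, strand; coordinate-sorted."""
    recs = sorted(records, key=lambda r: (r.contig, r.start, r.end))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.label}:{r.kmer}\t0\t{r.strand}\n"
            )


_REPORT_COLUMNS = (
    "n_scunks",
    "n_unique",
    "n_duplicated",
    "n_split",
    "pct_unique",
    "pct_duplicated",
    "pct_split",
)


def write_report(classification, path) -> None:
    """Write the one-row TSV score report.

    Counts are always emitted so exact values are recoverable from the file;
    percentages are rounded to 2 decimals. With zero SCUnKs the percentage
    fields are "NA" and a warning is issued.
    """
    n = classification.n_scunks
    row = [
        str(n),
        str(classification.n_unique),
        str(classification.n_duplicated),
        str(classification.n_split),
    ]
    if n == 0:
        warnings.warn(
            "zero SCUnKs: percentages are undefined, writing NA", stacklevel=2
        )
        row += ["NA", "NA", "NA"]
    else:
        row += [
            f"{classification.pct_unique:.2f}",
            f"{classification.pct_duplicated:.2f}",
            f"{classification.pct_split:.2f}",
        ]
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        fh.write("\t".join(row) + "\n")
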