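"""Seeded simulator of haplotypes, truth bubble graphs, and graph pathologies.

The generator emulates the inputs the score is designed for: a set of
haplotype assemblies descended from a common ancestor by SNPs and small
indels, and a bubble-structured graph that represents them losslessly —
maximal conserved stretches become shared nodes, each variant site becomes
a bubble with one node per distinct non-empty allele, and every haplotype
is a path through those nodes.

Two properties make the fixtures analytically tractable:

* variant sites are kept at least ``min_spacing`` bases apart (set it to k
  for the clean profile), so no k-window overlaps two sites; and
* every site is polymorphic among the simulated haplotypes (at least one
  carrier and one non-carrier), and indel alleles are drawn junction-distinct
  (an insertion's first/last bases differ from the flanking ancestor bases;
  deletions are only placed where the deleted run is not a local tandem
  repeat), so any window overlapping a site differs between haplotypes and
  cannot be universal.

Together these force every single-copy universal k-mer to lie wholly
inside a shared node, hence an unperturbed truth graph scores 100% unique.
Two perturbation operators inject the pathologies the score detects:
node duplication (unique -> duplicated) and node fragmentation
(unique -> split for windows spanning the cut).

:func:`expected_classification` is an independent oracle: naive substring
tallies with explicit loops, sharing no code with the counting engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ScunkClassification
from .io import Assembly, GraphNode, PangenomeGraph

__all__ = [
    "SimConfig",
    "Variant",
    "SimTruth",
    "simulate_haplotypes",
    "build_truth_graph",
    "perturb_duplicate_node",
    "perturb_split_node",
    "expected_classification",
    "naive_count_kmers",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation.

    Rates are per-ancestor-base probabilities of a variant *site* (each
    site is then polymorphic among the haplotypes). ``min_spacing`` is the
    minimum distance in bases between variant sites; set it to the k you
    intend to score with to get fixtures whose expected classification is
    exactly computable.
    """

    ancestor_length: int
    n_haplotypes: int = 2
    snp_rate: float = 0.001
    indel_rate: float = 0.0
    max_indel: int = 5
    seed: int = 0
    min_spacing: int = 1
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be positive")
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")
        for rate, name in ((self.snp_rate, "snp_rate"), (self.indel_rate, "indel_rate")):
            if not 0.0 <= rate <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1], got {rate}")
        if self.indel_rate > 0 and self.max_indel < 1:
            raise ValueError("max_indel must be >= 1 when indel_rate > 0")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class Variant:
    """One polymorphic site on the ancestor.

    ``pos`` is the 0-based ancestor coordinate of the site; ``ref`` is the
    ancestral allele spelled on the ancestor ("" for an insertion);
    ``alleles`` holds the sequence each haplotype carries at the site
    ("" where a haplotype carries a deletion).
    """

    pos: int
    vtype: str  # "snp" | "ins" | "del"
    ref: str
    alleles: tuple[str, ...]

    @property
    def ref_span(self) -> int:
        return len(self.ref)


@dataclass
class SimTruth:
    """A simulation with full ground truth.

    After :func:`build_truth_graph` the (unperturbed) graph and the
    per-haplotype node paths are attached; ``perturbations`` records graph
    edits applied through the recording helpers, each with its analytically
    expected (d_unique, d_duplicated, d_split) count shift.
    """

    config: SimConfig
    ancestor: str
    haplotypes: list[Assembly]
    variants: list[Variant]
    graph: PangenomeGraph | None = None
    paths: dict[str, list[str]] = field(default_factory=dict)
    perturbations: list[tuple[str, dict]] = field(default_factory=list)
    expected_shift: list[tuple[int, int, int]] = field(default_factory=list)


def _replay(ancestor: str, variants: Sequence[Variant], hap_index: int) -> str:
    """Rebuild one haplotype from the ancestor plus recorded variants."""
    parts: list[str] = []
    cur = 0
    for v in sorted(variants, key=lambda v: v.pos):
        parts.append(ancestor[cur : v.pos])
        parts.append(v.alleles[hap_index])
        cur = v.pos + v.ref_span
    parts.append(ancestor[cur:])
    return "".join(parts)


def _base_not(rng: np.random.Generator, excluded: str) -> str:
    allowed = [b for b in _BASES if b not in excluded]
    return allowed[int(rng.integers(0, len(allowed)))]


def _draw_indel(
    rng: np.random.Generator,
    ancestor: str,
    pos: int,
    max_indel: int,
    carriers,
) -> Variant:
    """Draw a junction-distinct insertion or deletion at ``pos``.

    A window crossing an indel junction must differ between carriers and
    non-carriers, otherwise a universal k-mer would straddle a bubble
    boundary and the truth graph would not be lossless. Insertions get
    first/last bases distinct from the flanking ancestor bases; a deletion
    is only accepted when the deleted run's endpoints differ from their
    shift-by-size counterparts (i.e. it is not a local tandem repeat), and
    falls back to an insertion otherwise.
    """
    if rng.integers(0, 2):  # try a deletion
        sizes = rng.permutation(np.arange(1, max_indel + 1))
        for size in sizes:
            size = int(size)
            if pos + size >= len(ancestor):
                continue
            if (
                ancestor[pos] != ancestor[pos + size]
                and ancestor[pos - 1] != ancestor[pos + size - 1]
            ):
                ref = ancestor[pos : pos + size]
                alleles = tuple("" if c else ref for c in carriers)
                return Variant(pos, "del", ref, alleles)
    # insertion between pos-1 and pos
    size = int(rng.integers(1, max_indel + 1))
    if size == 1:
        ins = _base_not(rng, ancestor[pos - 1] + ancestor[pos])
    else:
        first = _base_not(rng, ancestor[pos])
        last = _base_not(rng, ancestor[pos - 1])
        middle = "".join(
            np.array(list(_BASES))[rng.integers(0, 4, size=size - 2)]
        )
        ins = first + middle + last
    alleles = tuple(ins if c else "" for c in carriers)
    return Variant(pos, "ins", "", alleles)


def simulate_haplotypes(config: SimConfig) -> SimTruth:
    """Draw an ancestor and derive haplotypes by SNPs and small indels.

    Fully deterministic for a given config. Variant sites are spaced at
    least ``min_spacing + max_indel`` bases apart so their reference spans
    can never abut or overlap, and each site gets a polymorphic carrier
    pattern over the haplotypes.
    """
    rng = np.random.default_rng(config.seed)
    L = config.ancestor_length
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ancestor = "".join(
        np.array(list(_BASES))[rng.choice(4, size=L, p=probs)]
    )

    n_snp = int(rng.binomial(L, config.snp_rate))
    n_indel = int(rng.binomial(L, config.indel_rate)) if config.indel_rate else 0
    gap = config.min_spacing + config.max_indel
    lo, hi = 1, L - 1 - config.max_indel
    variants: list[Variant] = []
    if n_snp + n_indel > 0 and hi > lo:
        candidates = rng.permutation(np.arange(lo, hi))
        accepted: list[int] = []
        for pos in candidates:
            if len(accepted) == n_snp + n_indel:
                break
            if all(abs(pos - a) > gap for a in accepted):
                accepted.append(int(pos))
        types = ["snp"] * min(n_snp, len(accepted))
        types += ["indel"] * (len(accepted) - len(types))
        for pos, vtype in zip(sorted(accepted), rng.permutation(types)):
            # carrier pattern: redraw until polymorphic
            while True:
                carriers = rng.integers(0, 2, size=config.n_haplotypes)
                if 0 < carriers.sum() < config.n_haplotypes:
                    break
            if vtype == "snp":
                ref = ancestor[pos]
                alt = _BASES.replace(ref, "")[rng.integers(0, 3)]
                alleles = tuple(alt if c else ref for c in carriers)
                variants.append(Variant(pos, "snp", ref, alleles))
            else:
                variants.append(
                    _draw_indel(rng, ancestor, pos, config.max_indel, carriers)
                )
    variants.sort(key=lambda v: v.pos)

    haplotypes = [
        Assembly(name=f"hap{h + 1}", contigs=[("chr1", _replay(ancestor, variants, h))])
        for h in range(config.n_haplotypes)
    ]
    return SimTruth(config=config, ancestor=ancestor, haplotypes=haplotypes, variants=variants)


def build_truth_graph(truth: SimTruth) -> PangenomeGraph:
    """Construct the lossless bubble graph implied by the recorded variants.

    Maximal conserved ancestor segments become shared nodes; each variant
    site contributes one node per distinct non-empty allele (a deletion's
    empty allele is an edge, not a node). Node paths per haplotype are
    attached to ``truth.paths``; concatenating a path's node sequences
    reproduces that haplotype exactly.
    """
    for v1, v2 in zip(truth.variants, truth.variants[1:]):
        if v2.pos < v1.pos + v1.ref_span + 1:
            raise ValueError(
                f"variants at {v1.pos} and {v2.pos} overlap or abut; "
                "the graph cannot be segmented"
            )
    nodes: list[GraphNode] = []
    paths: dict[str, list[str]] = {a.name: [] for a in truth.haplotypes}
    counter = 0

    def new_node(seq: str) -> str:
        nonlocal counter
        counter += 1
        nid = f"s{counter}"
        nodes.append(GraphNode(id=nid, sequence=seq))
        return nid

    def shared(seq: str) -> None:
        if not seq:
            return
        nid = new_node(seq)
        for p in paths.values():
            p.append(nid)

    cur = 0
    for v in truth.variants:
        shared(truth.ancestor[cur : v.pos])
        allele_ids: dict[str, str] = {}
        order: list[str] = []
        if v.ref and v.ref not in order:
            order.append(v.ref)
        for a in v.alleles:
            if a and a not in order:
                order.append(a)
        for allele in order:
            allele_ids[allele] = new_node(allele)
        for asm, a in zip(truth.haplotypes, v.alleles):
            if a:
                paths[asm.name].append(allele_ids[a])
        cur = v.pos + v.ref_span
    shared(truth.ancestor[cur:])

    graph = PangenomeGraph(nodes=nodes)
    # sanity: every haplotype is reconstructible as its node path
    seq_of = {n.id: n.sequence for n in nodes}
    for asm in truth.haplotypes:
        rebuilt = "".join(seq_of[nid] for nid in paths[asm.name])
        if rebuilt != asm.contigs[0][1]:
            raise AssertionError(f"path for {asm.name} does not spell the haplotype")
    truth.graph = graph
    truth.paths = paths
    return graph


def perturb_duplicate_node(graph: PangenomeGraph, node_id: str) -> PangenomeGraph:
    """Append an exact copy of a node's sequence under a fresh id."""
    node = graph.node(node_id)  # KeyError for unknown id
    existing = set(graph.node_ids)
    i = 1
    while f"{node_id}_dup{i}" in existing:
        i += 1
    return PangenomeGraph(
        nodes=list(graph.nodes) + [GraphNode(id=f"{node_id}_dup{i}", sequence=node.sequence)]
    )


def perturb_split_node(
    graph: PangenomeGraph, node_id: str, offset: int
) -> PangenomeGraph:
    """Replace a node by its two halves, cut at an internal offset.

    Windows spanning the cut lose their in-node occurrence — the mechanism
    behind the "split" class.
    """
    node = graph.node(node_id)
    if not 1 <= offset < len(node.sequence):
        raise ValueError(
            f"offset {offset} not internal to node {node_id!r} "
            f"(length {len(node.sequence)})"
        )
    nodes: list[GraphNode] = []
    for n in graph.nodes:
        if n.id == node_id:
            nodes.append(GraphNode(id=f"{node_id}_a", sequence=n.sequence[:offset]))
            nodes.append(GraphNode(id=f"{node_id}_b", sequence=n.sequence[offset:]))
        else:
            nodes.append(n)
    return PangenomeGraph(nodes=nodes)


# ---------------------------------------------------------------------------
# Independent brute-force oracle (no shared code with pgscunk.kmers)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _naive_revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def naive_count_kmers(sequences: Sequence[str], k: int) -> dict[str, int]:
    """Plain substring tally of canonical k-mers, one window at a time."""
    tally: dict[str, int] = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            sub = seq[i : i + k]
            valid = True
            for ch in sub:
                if ch not in _COMP:
                    valid = False
                    break
            if not valid:
                continue
            rc = _naive_revcomp(sub)
            key = sub if sub <= rc else rc
            tally[key] = tally.get(key, 0) + 1
    return tally


def expected_classification(
    truth: SimTruth, k: int, graph: PangenomeGraph | None = None
) -> ScunkClassification:
    """Brute-force classification of the truth's haplotypes against a graph.

    Defaults to ``truth.graph`` (possibly perturbed graphs may be passed
    explicitly). Entirely independent of the counting engine.
    """
    if graph is None:
        graph = truth.graph
    if graph is None:
        raise ValueError("no graph attached to truth; call build_truth_graph first")
    per_hap: list[set[str]] = []
    for asm in truth.haplotypes:
        tally = naive_count_kmers([seq for _, seq in asm.contigs], k)
        per_hap.append({km for km, c in tally.items() if c == 1})
    scunks = set.intersection(*per_hap)
    node_tally = naive_count_kmers([n.sequence for n in graph.nodes], k)
    labels: dict[str, str] = {}
    for km in scunks:
        c = node_tally.get(km, 0)
        labels[km] = "unique" if c == 1 else ("duplicated" if c >= 2 else "split")
    return ScunkClassification(k=k, labels=labels)


def record_perturbation(
    truth: SimTruth, kind: str, k: int, **kwargs
) -> PangenomeGraph:
    """Apply a perturbation to ``truth.graph``, recording its expected shift.

    The shift (d_unique, d_duplicated, d_split) is computed with the
    brute-force oracle before and after the edit.
    """
    before = expected_classification(truth, k)
    if kind == "duplicate":
        graph = perturb_duplicate_node(truth.graph, kwargs["node_id"])
    elif kind == "split":
        graph = perturb_split_node(truth.graph, kwargs["node_id"], kwargs["offset"])
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    after = expected_classification(truth, k, graph)
    truth.graph = graph
    truth.perturbations.append((kind, dict(kwargs)))
    truth.expected_shift.append(
        (
            after.n_unique - before.n_unique,
            after.n_duplicated - before.n_duplicated,
            after.n_split - before.n_split,
        )
    )
    return graph


# ---------------------------------------------------------------------------
# Text output for the `simulate` CLI subcommand


def write_truth_gfa(truth: SimTruth, path) -> None:
    """Write the truth graph as GFA1 with S, L and P lines."""
    if truth.graph is None:
        raise ValueError("no graph attached; call build_truth_graph first")
    links: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for p in truth.paths.values():
        for a, b in zip(p, p[1:]):
            if (a, b) not in seen:
                seen.add((a, b))
                links.append((a, b))
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for n in truth.graph.nodes:
            fh.write(f"S\t{n.id}\t{n.sequence}\n")
        for a, b in links:
            fh.write(f"L\t{a}\t+\t{b}\t+\t0M\n")
        for name, p in truth.paths.items():
            fh.write(f"P\t{name}\t{','.join(nid + '+' for nid in p)}\t*\n")


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Write the recorded variants as TSV: pos, type, ref, per-hap alleles."""
    names = [a.name for a in truth.haplotypes]
    with open(path, "w") as fh:
        fh.write("pos\ttype\tref\t" + "\t".join(names) + "\n")
        for v in truth.variants:
            alleles = "\t".join(a if a else "-" for a in v.alleles)
            fh.write(f"{v.pos}\t{v.vtype}\t{v.ref if v.ref else '-'}\t{alleles}\n")


def write_haplotype_fastas(truth: SimTruth, outdir) -> list[str]:
    """Write one FASTA per haplotype into ``outdir``; return the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for asm in truth.haplotypes:
        p = outdir / f"{asm.name}.fa"
        with open(p, "w") as fh:
            for cid, seq in asm.contigs:
                fh.write(f">{cid}\n{seq}\n")
        written.append(str(p))
    return written
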