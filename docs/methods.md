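# Methods

## The score

For k-mer size `k` (default 100) and source assemblies `A_1 … A_n`, let
`S_i` be the set of canonical k-mers occurring exactly once across all
contigs of `A_i` (contigs are counted jointly; windows never cross contig
boundaries). The SCUnK set is `S = ∩_i S_i`: k-mers single-copy in *every*
assembly. Requiring single-copy in each assembly — not merely presence —
is what licenses the orthology assumption: each SCUnK marks one homologous
locus per haplotype.

Each SCUnK is then looked up in the multiset of canonical k-mers of the
graph's node sequences: count 1 → `unique`, ≥ 2 → `duplicated`
(no upper cap), 0 → `split`. Counts and the three percentages (which sum
to 100 exactly in rational arithmetic) are the result; per-k-mer labels
are retained for region mapping and export.

Assumptions and consequences:

* **Canonical counting.** Every window is collapsed to
  `min(w, revcomp(w))`. Graph paths may traverse nodes in either
  orientation, so a strand-specific count would misclassify
  reverse-oriented nodes. A reverse-complement palindrome (possible at
  even k) counts once per genomic occurrence; even k is allowed.
* **Edges and paths are ignored.** Only node sequences are consulted. A
  k-mer whose occurrence straddles a node boundary is invisible to
  in-node counting — that invisibility *is* the definition of `split`.
  The graph should be scored raw, before smoothing/simplification that
  could perturb exact matches.
* **Non-ACGT windows are skipped** (soft-masked lowercase is uppercased
  first — masking is annotation, not sequence). Ambiguity codes carry no
  exact-match information.
* **No node deduplication.** Two identical nodes produce counts of 2;
  that is the duplication signal, not an artifact.

`ScunkStats.scunk_fraction` reports |S| over the number of distinct
canonical k-mers of a designated reference assembly (the first listed, by
convention). It quantifies how much of the genome the score interrogates
and collapses as k grows; the reference choice is a documented convention,
configurable by reordering the inputs.

Total inflation is `graph.total_length / reference.total_length`, a
structural redundancy indicator reported to 4 decimals by the CLI.

## Parameters

| parameter | unit | default | notes |
|---|---|---|---|
| `k` | bases | 100 | supported at least up to 211; SCUnK yield collapses as k grows (fewer windows escape polymorphism), while the ternary score itself is comparatively insensitive |
| `max_gap` (region merging) | bases | 0 | merge only overlapping/book-ended same-class hits; no windowing scheme is assumed |

Counting streams one window at a time; memory scales with the number of
distinct k-mers retained, and per-assembly tables are discarded after
reduction to single-copy sets. Disk-partitioned counting is out of scope.

## Region mapping

Because a SCUnK is single-copy in every source assembly, it has exactly
one occurrence (forward or reverse strand) there; `locate_scunks` scans
all windows once and emits a BED6 record per SCUnK (0-based half-open,
`name = label:kmer`, strand from the matching orientation; a palindromic
match reports `+`). Zero or multiple occurrences of a labeled k-mer mean
the supplied assembly is not a source of the scored graph and raise an
error naming the k-mer. `merge_regions` collapses same-contig, same-label
hits separated by ≤ `max_gap` bases into intervals carrying the member
count, so SCUnK mass is conserved.

## The simulator

`simulate_haplotypes` draws a uniform-ACGT ancestor (a GC-content knob
exists, default 0.5) and derives `n ≥ 2` haplotypes by placing SNP and
indel *sites* at per-base rates (≤ 0.1), each site carrying a polymorphic
allele pattern over the haplotypes. `build_truth_graph` converts the
recorded variants into the lossless bubble graph: maximal conserved
segments become shared nodes, each variant site one node per distinct
non-empty allele (a deletion's empty allele is an edge, not a node), and
each haplotype is reconstructible as a node path (checked at build time).
Everything is deterministic given the config, including the seed.

Three constraints make the fixtures analytically solvable:

1. **Site spacing.** Sites are kept at least `min_spacing + max_indel`
   bases apart; with `min_spacing = k` no k-window overlaps two sites.
2. **Polymorphism.** Every site has at least one carrier and one
   non-carrier haplotype, so any window overlapping a site differs
   between haplotypes and cannot be universal.
3. **Junction-distinct indels.** An insertion's first/last bases are
   drawn to differ from the flanking ancestor bases, and a deletion is
   only placed where the deleted run is not a local tandem repeat
   (endpoint bases differ from their shift-by-size counterparts).
   Without this, an indel junction window can be identical in carriers
   and non-carriers — a genuine universal k-mer straddling a bubble
   boundary — and a lossless graph would legitimately score split > 0.

Under these constraints every SCUnK lies wholly inside a shared node, so
an unperturbed truth graph scores exactly (100, 0, 0); the test suite
asserts this across seeds, k ∈ {31, 51, 100}, 2–5 haplotypes and SNP/indel
rates up to 0.01/0.002. A "dense" profile (`min_spacing = 1`) drops the
spacing guarantee for stress tests where only the brute-force oracle
defines truth.

Two perturbation operators inject known pathologies: `perturb_duplicate_node`
(every formerly-unique SCUnK fully inside the node becomes duplicated)
and `perturb_split_node` (exactly the formerly-unique SCUnKs whose sole
full occurrence spans the cut become split). `expected_classification`
recomputes labels by naive substring tallying — explicit per-window loops
and a dictionary, sharing no code with the counting engine — and serves
as the independent oracle for all recovery tests.

What the simulator does **not** emulate: transition/transversion bias,
structural-variant spectra, repeat families, GC heterogeneity along the
genome, sequencing or assembly error. Passing tests therefore demonstrate
algorithmic correctness of the classification machinery on graphs with
known truth, not robustness to the repeat-rich, partially assembled
genomes real pangenomes integrate — on real data the single-copy filter
itself is what screens out repeats.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere (BED convention).
* Report percentages are rounded to 2 decimals; raw counts are always
  emitted so exact values are recoverable. Zero SCUnKs → percentage
  fields `NA` plus a warning (the "no SCUnKs at this k" error from the
  classifier advises decreasing k).
* GFA1 `S` records must carry inline sequences (`*` is an error naming
  the record); rGFA tags are tolerated and ignored; `L/P/W/H`, comments
  and unknown record types are skipped. GFA2 and binary graph formats are
  out of scope.
* Ties: a `while` loop redraws carrier patterns until polymorphic; node
  ids in truth graphs are `s1, s2, …` in left-to-right order; duplicate
  copies get `<id>_dupN`, split halves `<id>_a` / `<id>_b`.
* Problem sizes in the test suite and acceptance script (ancestors of
  ~10·k to 100 kb, 2–5 haplotypes, 20–100 seeded replicates) were chosen
  as the smallest sizes at which every property is non-degenerate
  (thousands of SCUnKs per case) while the whole suite runs in seconds.

## Known limitations

* In-memory counting: fine to tens of megabases per assembly; the
  gigabase-scale graphs the method targets in production need a
  disk-partitioned counter behind the same interface.
* The score cannot distinguish a k-mer lost from the graph entirely from
  one fragmented across nodes; both count as `split` (the definition
  follows from in-node counting).
* Exact matching only: a single base error in a node sequence converts
  its windows to `split`, which is intended sensitivity but makes the
  score inappropriate for polished/simplified graphs.
* `locate_scunks` requires the target assembly to be a source assembly;
  mapping onto an arbitrary related genome is deliberately refused rather
  than approximated.
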