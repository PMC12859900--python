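# pgscunk

**How well does a pangenome graph represent the assemblies it was built
from?** Structural summaries (node/edge counts, total length) say little
about whether homologous sequence is integrated once, redundantly, or not
at all. `pgscunk` answers the question with single-copy universal k-mers.

## The method

A k-mer that occurs **exactly once in every source assembly** of a graph —
a *single-copy universal k-mer*, or **SCUnK** — is presumed orthologous,
so a faithful graph should carry it exactly once, in full, inside one of
its nodes. Writing `c(x)` for the number of full-length occurrences of
canonical k-mer `x` in the graph's node sequences, each SCUnK is classed

| class | condition | meaning |
|---|---|---|
| unique | `c(x) = 1` | represented once, in full |
| duplicated | `c(x) ≥ 2` | redundantly collapsed or repeated |
| split | `c(x) = 0` | fragmented across a node boundary |

The three percentages sum to 100 and form a ternary score; an ideal graph
sits at (100, 0, 0). High duplication predicts ambiguous (secondary)
read alignments; high split predicts reduced mapping rates. All counting
is canonical (a k-mer and its reverse complement are the same object), so
the score is invariant to node orientation, node order and naming, and
assembly orientation. Windows containing non-ACGT symbols are skipped;
windows never span two records. Default `k = 100`.

The companion metrics are **region mapping** (locate each labeled SCUnK at
its single position in a source assembly, emit BED6 per class, merge into
regions) and **total inflation** (graph nucleotide length divided by one
reference assembly's length; 1.0 for a perfectly deduplicated graph).

A seeded simulator generates ground-truth test cases: haplotypes derived
from a common ancestor by SNPs and small indels, the lossless bubble graph
that represents them (conserved segments are shared nodes, variant sites
are bubbles), and controlled pathologies (node duplication, node
fragmentation) whose effect on the score is known exactly.

## Worked example

Simulate four haplotypes of a 20 kb ancestor with their lossless truth
graph, then score it at k = 100:

```sh
pg-scunk simulate --length 20000 --haps 4 --snp-rate 0.002 \
    --indel-rate 0.0005 --spacing 100 --seed 42 -o demo
pg-scunk run -g demo/graph.gfa -a demo/hap1.fa -a demo/hap2.fa \
    -a demo/hap3.fa -a demo/hap4.fa -k 100 -o demo/out
```

```
SCUnK classification (k=100, n=14973): unique 100.00% | duplicated 0.00% | split 0.00%
ternary	100.00	0.00	0.00
```

14 973 100-mers are single-copy in all four haplotypes, and every one of
them occurs exactly once in the graph's nodes — the graph is lossless, so
the ternary point is (100, 0, 0). The log (stderr) reports per-assembly
single-copy counts (~19 900 each) and the SCUnK fraction (0.75 of hap1's
distinct 100-mers), which shrinks as k grows.

Damaging the same graph — appending a copy of its largest node and cutting
the second-largest in two — moves the score off the corner:

```
n_scunks  n_unique  n_duplicated  n_split  pct_unique  pct_duplicated  pct_split
14973     13700     1174          99       91.50       7.84            0.66
```

The 1 174 SCUnKs contained in the duplicated node are now seen twice
(duplicated); the 99 whose only full occurrence spanned the cut are seen
nowhere (split). Total inflation rises accordingly:

```sh
pg-scunk inflation -g demo/broken.gfa -r demo/hap1.fa   # -> 1.0662
```

`pg-scunk regions` maps each labeled SCUnK back to an assembly as BED6
(`contig  start  end  label:kmer  0  strand`) plus a merged-region BED, to
inspect *where* duplicated or split sequence lives.

## Library use

```python
import pgscunk as pg

graph = pg.read_gfa("graph.gfa")
asms = [pg.read_fasta(p) for p in ("hap1.fa", "hap2.fa")]
result = pg.run_pgscunk(graph, asms, k=100)
print(result.classification.ternary)   # (pct_unique, pct_duplicated, pct_split)
print(pg.inflation_score(graph, asms[0]))
```

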