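"""Simulator determinism, truth-graph structure, and perturbation semantics."""

import numpy as np
import pytest

from pgscunk.core import classify_scunks, find_scunks, run_pgscunk
from pgscunk.synthetic import (
    SimConfig,
    build_truth_graph,
    expected_classification,
    naive_count_kmers,
    perturb_duplicate_node,
    perturb_split_node,
    record_perturbation,
    simulate_haplotypes,
    write_truth_gfa,
)
from pgscunk.io import read_gfa


def sim(**kw):
    defaults = dict(ancestor_length=2000, n_haplotypes=2, snp_rate=0.005,
                    indel_rate=0.001, max_indel=5, seed=1, min_spacing=31)
    defaults.update(kw)
    return simulate_haplotypes(SimConfig(**defaults))


class TestSimulateHaplotypes:
    def test_zero_rates_give_identical_haplotypes(self):
        truth = sim(snp_rate=0.0, indel_rate=0.0, seed=7)
        for asm in truth.haplotypes:
            assert asm.contigs[0][1] == truth.ancestor
        assert truth.variants == []

    def test_different_seeds_give_different_ancestors(self):
        assert sim(seed=1).ancestor != sim(seed=2).ancestor

    def test_determinism_is_byte_identical(self):
        a, b = sim(seed=5), sim(seed=5)
        assert a.ancestor == b.ancestor
        assert a.variants == b.variants
        assert [x.contigs for x in a.haplotypes] == [x.contigs for x in b.haplotypes]
        ga, gb = build_truth_graph(a), build_truth_graph(b)
        assert [(n.id, n.sequence) for n in ga.nodes] == [(n.id, n.sequence) for n in gb.nodes]

    def test_variants_replay_to_haplotypes(self):
        """Applying the recorded variants to the ancestor reproduces each haplotype."""
        truth = sim(n_haplotypes=3, seed=9)
        assert truth.variants  # non-degenerate fixture
        for h, asm in enumerate(truth.haplotypes):
            parts, cur = [], 0
            for v in truth.variants:
                parts.append(truth.ancestor[cur : v.pos])
                parts.append(v.alleles[h])
                cur = v.pos + len(v.ref)
            parts.append(truth.ancestor[cur:])
            assert "".join(parts) == asm.contigs[0][1]

    def test_every_site_is_polymorphic(self):
        truth = sim(n_haplotypes=4, seed=3)
        for v in truth.variants:
            assert len(set(v.alleles)) >= 2

    def test_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(ancestor_length=100, snp_rate=0.5)
        with pytest.raises(ValueError):
            SimConfig(ancestor_length=100, n_haplotypes=1)


class TestBuildTruthGraph:
    def test_no_variants_single_node(self):
        truth = sim(snp_rate=0.0, indel_rate=0.0)
        g = build_truth_graph(truth)
        assert len(g) == 1 and g.nodes[0].sequence == truth.ancestor
        res = run_pgscunk(g, truth.haplotypes, 31)
        assert res.classification.pct_unique == 100.0

    def test_one_snp_makes_four_nodes(self):
        truth = sim(snp_rate=0.0, indel_rate=0.0)
        from pgscunk.synthetic import Variant

        p = 900
        ref = truth.ancestor[p]
        alt = "ACGT".replace(ref, "")[0]
        truth.variants = [Variant(p, "snp", ref, (ref, alt))]
        truth.haplotypes[1].contigs[0] = (
            "chr1",
            truth.ancestor[:p] + alt + truth.ancestor[p + 1 :],
        )
        g = build_truth_graph(truth)
        assert len(g) == 4  # prefix, two 1-bp alleles, suffix
        assert sorted(len(n.sequence) for n in g.nodes) == [1, 1, p, len(truth.ancestor) - p - 1]

    def test_deletion_makes_three_nodes(self):
        truth = sim(snp_rate=0.0, indel_rate=0.0)
        from pgscunk.synthetic import Variant

        p, d = 900, 3
        ref = truth.ancestor[p : p + d]
        truth.variants = [Variant(p, "del", ref, (ref, ""))]
        truth.haplotypes[1].contigs[0] = (
            "chr1",
            truth.ancestor[:p] + truth.ancestor[p + d :],
        )
        g = build_truth_graph(truth)
        assert len(g) == 3  # prefix, deleted allele, suffix

    def test_paths_spell_haplotypes_and_gfa_round_trips(self, tmp_path):
        truth = sim(n_haplotypes=3, seed=13)
        g = build_truth_graph(truth)
        seq_of = {n.id: n.sequence for n in g.nodes}
        for asm in truth.haplotypes:
            assert "".join(seq_of[i] for i in truth.paths[asm.name]) == asm.contigs[0][1]
        p = tmp_path / "truth.gfa"
        write_truth_gfa(truth, p)
        g2 = read_gfa(p)
        assert [(n.id, n.sequence) for n in g2.nodes] == [(n.id, n.sequence) for n in g.nodes]


class TestPerturbations:
    def test_duplicate_flips_single_node_graph_to_all_duplicated(self):
        truth = sim(snp_rate=0.0, indel_rate=0.0)
        g = build_truth_graph(truth)
        g2 = perturb_duplicate_node(g, g.nodes[0].id)
        res = run_pgscunk(g2, truth.haplotypes, 31)
        assert res.classification.pct_duplicated == 100.0

    def test_duplicate_unknown_id_rejected(self):
        g = build_truth_graph(sim())
        with pytest.raises(KeyError):
            perturb_duplicate_node(g, "nope")

    def test_reduplicating_keeps_counts_at_duplicated(self):
        truth = sim(snp_rate=0.0, indel_rate=0.0)
        g = build_truth_graph(truth)
        nid = g.nodes[0].id
        g2 = perturb_duplicate_node(g, nid)
        g3 = perturb_duplicate_node(g2, nid)
        scunks, _ = find_scunks(truth.haplotypes, 31)
        c2, c3 = classify_scunks(scunks, g2, 31), classify_scunks(scunks, g3, 31)
        assert c2.n_duplicated == c3.n_duplicated  # counts 2 -> 3 stay "duplicated"

    def test_duplicating_scunk_free_node_changes_nothing(self):
        truth = sim(seed=21)
        g = build_truth_graph(truth)
        # 1-bp allele nodes hold no full k-window at k=31
        small = next(n.id for n in g.nodes if len(n.sequence) < 31)
        g2 = perturb_duplicate_node(g, small)
        scunks, _ = find_scunks(truth.haplotypes, 31)
        assert classify_scunks(scunks, g, 31).labels == classify_scunks(scunks, g2, 31).labels

    def test_split_offset_bounds(self):
        g = build_truth_graph(sim(snp_rate=0.0, indel_rate=0.0))
        nid = g.nodes[0].id
        n = len(g.nodes[0].sequence)
        with pytest.raises(ValueError):
            perturb_split_node(g, nid, 0)
        with pytest.raises(ValueError):
            perturb_split_node(g, nid, n)

    def test_split_loses_exactly_cut_spanning_windows(self):
        k = 31
        truth = sim(snp_rate=0.0, indel_rate=0.0, seed=4, ancestor_length=400)
        g = build_truth_graph(truth)
        nid, seq = g.nodes[0].id, g.nodes[0].sequence
        scunks, _ = find_scunks(truth.haplotypes, k)
        whole = naive_count_kmers([seq], k)
        for offset in (1, k - 1, k, 200, len(seq) - 1):
            g2 = perturb_split_node(g, nid, offset)
            c = classify_scunks(scunks, g2, k)
            halves = naive_count_kmers([seq[:offset], seq[offset:]], k)
            spanning = {
                km for km in scunks
                if whole.get(km, 0) == 1 and halves.get(km, 0) == 0
            }
            assert {km for km, lab in c.labels.items() if lab == "split"} == spanning

    def test_record_perturbation_tracks_expected_shift(self):
        truth = sim(seed=8)
        build_truth_graph(truth)
        before = expected_classification(truth, 31)
        big = max(truth.graph.nodes, key=lambda n: len(n.sequence)).id
        record_perturbation(truth, "duplicate", 31, node_id=big)
        after = expected_classification(truth, 31)
        du, dd, ds = truth.expected_shift[0]
        assert (after.n_unique - before.n_unique,
                after.n_duplicated - before.n_duplicated,
                after.n_split - before.n_split) == (du, dd, ds)
        assert dd > 0 and du == -dd and ds == 0


def test_oracle_matches_engine_on_dense_profile():
    """With unspaced variants only the oracle defines truth; the engine must agree."""
    truth = simulate_haplotypes(
        SimConfig(ancestor_length=1500, n_haplotypes=3, snp_rate=0.01,
                  indel_rate=0.002, max_indel=4, seed=17, min_spacing=1)
    )
    g = build_truth_graph(truth)
    res = run_pgscunk(g, truth.haplotypes, 21)
    assert res.classification.labels == expected_classification(truth, 21).labels
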