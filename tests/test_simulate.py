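"""Simulator contracts: structure round-trip, truth replay, concerted IR
evolution, determinism, caller/truth agreement, parameter recovery."""

import numpy as np
import pytest

from plastocmp.alignment import align_pair
from plastocmp.errors import SimulationError
from plastocmp.simulate import (
    RegionGenes,
    SimulationParams,
    apply_variants,
    evolve,
    generate_ancestor,
    lift_features,
    recover_parameters,
)
from plastocmp.structure import (
    composition_summary,
    detect_quadripartite,
    revcomp,
)
from plastocmp.variants import call_variants

from conftest import small_sim_params


class TestGenerateAncestor:
    def test_total_length_and_structure_round_trip(self, small_params, small_ancestor):
        rec, feats = small_ancestor
        assert rec.length == small_params.total_len
        q = detect_quadripartite(rec, min_ir_length=800)
        assert len(q.lsc) == small_params.lsc_len
        assert q.ir_length == small_params.ir_len
        assert len(q.ssc) == small_params.ssc_len

    def test_zero_genes_empty_annotation(self):
        p = small_sim_params(
            lsc_genes=RegionGenes(), ssc_genes=RegionGenes(), ir_genes=RegionGenes()
        )
        rec, feats = generate_ancestor(p, seed=0)
        assert feats == []
        c = composition_summary(rec, feats)
        assert c.coding_percent == 0.0

    def test_infeasible_layout_rejected(self):
        p = small_sim_params(
            lsc_genes=RegionGenes(n_protein=40, protein_mean_len=400)
        )
        with pytest.raises(SimulationError, match="layout"):
            generate_ancestor(
                small_sim_params(
                    lsc_len=2000,
                    lsc_genes=RegionGenes(n_protein=40, protein_mean_len=400),
                ),
                seed=0,
            )

    def test_ir_genes_duplicated_and_mirrored(self, small_ancestor):
        rec, feats = small_ancestor
        dups = [f for f in feats if f.copy == "ir_duplicated"]
        assert len(dups) % 2 == 0 and dups
        by_name = {}
        for f in dups:
            by_name.setdefault(f.name, []).append(f)
        for name, pair in by_name.items():
            assert len(pair) == 2
            a, b = sorted(pair, key=lambda f: f.span.start)
            assert a.strand != b.strand
            # mirrored copies carry identical exon lengths
            assert sorted(len(iv) for iv in a.exons) == sorted(
                len(iv) for iv in b.exons
            )


class TestEvolve:
    def test_zero_rates_identity(self, small_ancestor):
        rec, feats = small_ancestor
        p = small_sim_params(
            tree_newick="(A:0.0,B:0.0,C:0.0);", mnv_rate=0.0, indel_rate=0.0
        )
        leaves, truth = evolve(rec, feats, p, seed=5)
        for leaf in leaves:
            assert leaf.sequence == rec.sequence
        assert all(not ev for ev in truth.branch_events.values())

    def test_same_seed_byte_identical(self, small_params, small_ancestor):
        rec, feats = small_ancestor
        l1, _ = evolve(rec, feats, small_params, seed=9)
        l2, _ = evolve(rec, feats, small_params, seed=9)
        assert [(a.id, a.sequence) for a in l1] == [(b.id, b.sequence) for b in l2]
        l3, _ = evolve(rec, feats, small_params, seed=10)
        assert any(a.sequence != b.sequence for a, b in zip(l1, l3))

    def test_truth_replay_reproduces_every_node(self, small_family):
        rec, feats, leaves, truth = small_family
        import dendropy

        tree = dendropy.Tree.get(
            data=truth.newick_labelled, schema="newick", preserve_underscores=True
        )
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            label = node.taxon.label if node.taxon else node.label
            parent = node.parent_node
            plabel = (
                "root"
                if parent.parent_node is None
                else (parent.taxon.label if parent.taxon else parent.label)
            )
            replayed = apply_variants(
                truth.node_reduced[plabel], truth.branch_events[label]
            )
            assert replayed == truth.node_reduced[label], label

    def test_leaf_irs_remain_exact_reverse_complements(self, small_family):
        rec, feats, leaves, truth = small_family
        for leaf in leaves:
            ir0, ir1 = truth.leaf_ir_bounds[leaf.id]
            reduced = truth.node_reduced[leaf.id]
            assert leaf.sequence == reduced + revcomp(reduced[ir0:ir1])
            q = detect_quadripartite(leaf, min_ir_length=800)
            assert revcomp(q.ir_a.slice(leaf.sequence)) == q.ir_b.slice(leaf.sequence)

    def test_root_to_leaf_map_consistent(self, small_family):
        rec, feats, leaves, truth = small_family
        root = truth.node_reduced["root"]
        for leaf in leaves:
            m = truth.root_to_leaf[leaf.id]
            reduced = truth.node_reduced[leaf.id]
            surv = m >= 0
            # unmutated surviving bases keep their nucleotide (SNP/MNV sites
            # may differ; test a conserved window around position 0)
            idx = np.flatnonzero(surv)[:50]
            same = sum(root[i] == reduced[m[i]] for i in idx)
            assert same >= 45  # few early positions may be substituted

    def test_lifted_features_translate_intact_where_unmutated(self, small_family):
        rec, feats, leaves, truth = small_family
        p = small_sim_params()
        leaf = leaves[0]
        lifted = lift_features(
            feats,
            truth.root_to_leaf[leaf.id],
            p.reduced_len,
            truth.leaf_ir_bounds[leaf.id],
            leaf.length,
        )
        assert lifted
        names_root = {f.name for f in feats}
        assert {f.name for f in lifted} <= names_root


class TestCallerVsTruth:
    def test_snp_only_single_branch_recall_precision_1(self, small_ancestor):
        """Well-separated SNP events on one branch are recovered exactly."""
        rec, feats = small_ancestor
        p = small_sim_params(
            tree_newick="(L1:0.004,L2:0.0,L3:0.0);", mnv_rate=0.0, indel_rate=0.0
        )
        leaves, truth = evolve(rec, feats, p, seed=31)
        leaf = next(l for l in leaves if l.id == "L1")
        red_len = p.reduced_len
        ref = truth.node_reduced["root"]
        qry = truth.node_reduced["L1"]
        from plastocmp.structure import PlastomeRecord

        pair = align_pair(
            PlastomeRecord(id="root", sequence=ref),
            PlastomeRecord(id="L1", sequence=qry),
            method="anchored",
        )
        called = {
            (v.type, v.ref_position, v.ref_allele, v.alt_allele)
            for v in call_variants(pair)
        }
        true = {
            (v.type, v.ref_position, v.ref_allele, v.alt_allele)
            for v in truth.branch_events["L1"]
        }
        assert len(true) > 20
        assert called == true

    def test_mixed_events_recovered(self, small_ancestor):
        rec, feats = small_ancestor
        p = small_sim_params(
            tree_newick="(L1:0.003,L2:0.0,L3:0.0);", min_event_spacing=8
        )
        leaves, truth = evolve(rec, feats, p, seed=37)
        ref = truth.node_reduced["root"]
        qry = truth.node_reduced["L1"]
        from plastocmp.structure import PlastomeRecord

        pair = align_pair(
            PlastomeRecord(id="root", sequence=ref),
            PlastomeRecord(id="L1", sequence=qry),
            method="anchored",
        )
        called = call_variants(pair)
        true = truth.branch_events["L1"]
        # count by type: alignment-normalized indel positions may shift
        # within homopolymer runs, so compare event multiset by type/length
        def sig(vs):
            return sorted((v.type, len(v.ref_allele), len(v.alt_allele)) for v in vs)

        assert sig(called) == sig(true)


class TestRecoverParameters:
    def test_kappa_recovery(self):
        p = SimulationParams(
            lsc_len=30000, ir_len=2000, ssc_len=2000,
            lsc_genes=RegionGenes(), ssc_genes=RegionGenes(), ir_genes=RegionGenes(),
            tree_newick="(X:0.0,Y:0.06);",
            kappa=2.0, mnv_rate=0.0, indel_rate=0.0,
        )
        rec, feats = generate_ancestor(p, seed=2)
        leaves, truth = evolve(rec, feats, p, seed=3)
        calls = truth.branch_events["Y"]
        est = recover_parameters(calls)
        assert est["n_variants"] >= 1500
        assert est["kappa_flag"] is None
        assert abs(est["kappa_hat"] - 2.0) / 2.0 < 0.15

    def test_no_snps_flagged(self):
        est = recover_parameters([])
        assert est["kappa_hat"] is None and est["kappa_flag"]

    def test_intergenic_enrichment_detected(self, small_ancestor):
        rec, feats = small_ancestor
        p = small_sim_params(
            tree_newick="(L1:0.01,L2:0.0,L3:0.0);",
            mnv_rate=0.0, indel_rate=0.0,
            mult_coding=1.0, mult_intron=1.0, mult_intergenic=3.0,
        )
        leaves, truth = evolve(rec, feats, p, seed=41)
        calls = truth.branch_events["L1"]
        red_feats = [f for f in feats if f.span.end <= p.reduced_len]
        est = recover_parameters(calls, red_feats, p.reduced_len)
        enr = est["region_enrichment"]
        assert enr["intergenic"] > 1.5 * enr["coding"]

    def test_uniform_multipliers_match_length_shares(self, small_ancestor):
        rec, feats = small_ancestor
        p = small_sim_params(
            tree_newick="(L1:0.02,L2:0.0,L3:0.0);",
            mnv_rate=0.0, indel_rate=0.0,
            mult_coding=1.0, mult_intron=1.0, mult_intergenic=1.0,
        )
        leaves, truth = evolve(rec, feats, p, seed=43)
        calls = truth.branch_events["L1"]
        red_feats = [f for f in feats if f.span.end <= p.reduced_len]
        est = recover_parameters(calls, red_feats, p.reduced_len)
        for region, prop in est["region_proportions"].items():
            share = est["region_length_shares"][region]
            # binomial tolerance at n ~ L * t
            n = est["n_variants"]
            se = np.sqrt(share * (1 - share) / n)
            assert abs(prop - share) < 5 * se + 0.02, region
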