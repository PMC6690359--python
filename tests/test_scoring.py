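"""Relevance, penalty and final scores, and cross-experiment combination."""

import math

import networkx as nx
import pytest

from gvtsig.errors import ConfigError, UsageError
from gvtsig.io_formats import GeneSet, ProteinQuantRecord, RatioTable
from gvtsig.network import SubNetwork, build_subnetwork
from gvtsig.quantfilter import CandidateSet, filter_by_ratio
from gvtsig.scoring import (CandidateScore, combine_experiments,
                            connectivity_weights, final_scores,
                            penalty_factors, relevance_scores)


def _graph(edges):
    g = nx.Graph()
    for a, b, c in edges:
        g.add_edge(a, b, confidence=c)
    return g


def _candidates(ratios, experiment_id="e1"):
    order = tuple(sorted(ratios, key=lambda g: (-ratios[g], g)))
    return CandidateSet(experiment_id=experiment_id, genes=order,
                        ratio_of=dict(ratios),
                        provenance={g: frozenset({"swissprot"}) for g in ratios})


def _score(gene, exp, final):
    return CandidateScore(gene, exp, final, 0.0, final, 0, 1.0, final)


class TestConnectivity:
    def test_symmetric_triangle_all_one(self):
        g = _graph([("A", "B", 0.8), ("B", "C", 0.8), ("A", "C", 0.8)])
        w = connectivity_weights(build_subnetwork(g, {"A", "B", "C"}, 0.5))
        assert w == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_all_isolated_all_zero(self):
        g = _graph([("A", "B", 0.2)])
        w = connectivity_weights(build_subnetwork(g, {"A", "B"}, 0.7))
        assert w == {"A": 0.0, "B": 0.0}

    def test_hand_summed_toy_graph(self):
        # raw sums: A = .9 + .8 = 1.7, B = .9 + .6 = 1.5, C = .8, D = .6
        g = _graph([("A", "B", 0.9), ("A", "C", 0.8), ("B", "D", 0.6)])
        w = connectivity_weights(build_subnetwork(g, {"A", "B", "C", "D"}, 0.5))
        assert w["A"] == pytest.approx(1.0)
        assert w["B"] == pytest.approx(1.5 / 1.7)
        assert w["C"] == pytest.approx(0.8 / 1.7)
        assert w["D"] == pytest.approx(0.6 / 1.7)

    def test_outer_genes_support_core_but_get_no_weight(self):
        from gvtsig.network import extend_outer
        g = _graph([("A", "OUT", 0.9)])
        sub = extend_outer(g, build_subnetwork(g, {"A"}, 0.7))
        w = connectivity_weights(sub)
        assert w == {"A": 1.0}  # outer edge counted for A, OUT unscored

    def test_empty_core_rejected(self):
        sub = SubNetwork(nx.Graph(), frozenset(), frozenset(), 0.7)
        with pytest.raises(UsageError):
            connectivity_weights(sub)


class TestRelevance:
    def test_formula(self):
        rel = relevance_scores(_candidates({"A": 1.5}), {"A": 1.0}, alpha=1.0)
        assert rel["A"] == pytest.approx(3.0)

    def test_alpha_zero_reduces_to_ratio(self):
        rel = relevance_scores(_candidates({"A": 1.5, "B": 2.0}),
                               {"A": 1.0, "B": 0.3}, alpha=0.0)
        assert rel == {"A": 1.5, "B": 2.0}

    def test_missing_weight_means_zero(self):
        rel = relevance_scores(_candidates({"A": 1.5}), {}, alpha=1.0)
        assert rel["A"] == 1.5

    def test_negative_alpha_rejected(self):
        with pytest.raises(ConfigError):
            relevance_scores(_candidates({"A": 1.5}), {}, alpha=-0.1)

    def test_network_support_ranks_module_above_equal_ratio_isolates(self, bundle42):
        """Planted-module genes outrank equal-ratio isolated genes."""
        from gvtsig.quantfilter import exclude_genesets
        cand = exclude_genesets(filter_by_ratio(bundle42.training, 1.2),
                                bundle42.exclusion_sets)
        sub = build_subnetwork(bundle42.network, cand, 0.7)
        weights = connectivity_weights(sub)
        rel = relevance_scores(cand, weights, alpha=1.0)
        sig = bundle42.truth.genes_of("signature")
        # an isolated background gene never outranks a signature gene whose
        # ratio is at least as large
        isolated = [g for g in cand.genes
                    if g not in sig and weights.get(g, 0.0) == 0.0]
        assert isolated
        for g in isolated:
            for s in sig & set(cand.genes):
                if cand.ratio_of[s] >= cand.ratio_of[g]:
                    assert rel[s] >= rel[g]
        sig_rel = sorted(rel[g] for g in cand.genes if g in sig)
        bkg_rel = sorted(rel[g] for g in cand.genes if g not in sig)
        # aggregate: median planted relevance well above median background
        assert sig_rel[len(sig_rel) // 2] > bkg_rel[len(bkg_rel) // 2]


class TestPenalty:
    LIB = [GeneSet("D1", "d", frozenset({"A", "B"})),
           GeneSet("D2", "d", frozenset({"A"}))]

    def test_unlisted_gene_factor_one(self):
        assert penalty_factors(["X"], self.LIB, beta=0.5)["X"] == (0, 1.0)

    def test_two_hits_halve_the_score(self):
        # a gene hit twice at beta 0.5 is modified more than two-fold
        k, factor = penalty_factors(["A"], self.LIB, beta=0.5)["A"]
        assert (k, factor) == (2, 0.5)

    def test_beta_zero_disables_all_penalties(self):
        out = penalty_factors(["A", "B", "X"], self.LIB, beta=0.0)
        assert all(f == 1.0 for _, f in out.values())

    def test_negative_beta_rejected(self):
        with pytest.raises(ConfigError):
            penalty_factors(["A"], self.LIB, beta=-1)


class TestFinalScores:
    def test_chain_example(self):
        cand = _candidates({"A": 1.5})
        pen = {"A": (2, 0.5)}
        (s,) = final_scores(cand, {"A": 1.0}, pen, alpha=1.0)
        assert s.relevance == pytest.approx(3.0)
        assert s.final_score == pytest.approx(1.5)

    def test_sub_one_scores_retained(self):
        cand = _candidates({"A": 1.3})
        (s,) = final_scores(cand, {}, {"A": (4, 1 / 3)}, alpha=1.0)
        assert s.final_score < 1
        assert s.gene == "A"  # still present in the output

    def test_sorted_by_final_then_alphabetical(self):
        cand = _candidates({"B": 2.0, "A": 2.0, "C": 3.0})
        out = final_scores(cand, {}, {}, alpha=1.0)
        assert [s.gene for s in out] == ["C", "A", "B"]

    def test_bound_chain_on_synthetic_run(self, bundle42):
        from gvtsig.cli import PipelineConfig, score_experiment
        cfg = PipelineConfig()
        scores, _, _ = score_experiment(bundle42.training, bundle42.network,
                                        bundle42.exclusion_sets,
                                        bundle42.penalty_library, cfg)
        for s in scores:
            assert s.final_score <= s.relevance + 1e-12
            assert s.relevance <= s.ratio * (1 + cfg.alpha) + 1e-12

    def test_zero_alpha_beta_degenerates_to_ratio_ranking(self, bundle42):
        from gvtsig.quantfilter import exclude_genesets
        cand = exclude_genesets(filter_by_ratio(bundle42.training, 1.2),
                                bundle42.exclusion_sets)
        sub = build_subnetwork(bundle42.network, cand, 0.7)
        w = connectivity_weights(sub)
        pen = penalty_factors(cand.genes, bundle42.penalty_library, beta=0.0)
        out = final_scores(cand, w, pen, alpha=0.0)
        assert [s.gene for s in out] == list(cand.genes)  # ratio order

    def test_penalty_changes_scores_never_membership(self, bundle42):
        from gvtsig.quantfilter import exclude_genesets
        cand = exclude_genesets(filter_by_ratio(bundle42.training, 1.2),
                                bundle42.exclusion_sets)
        sub = build_subnetwork(bundle42.network, cand, 0.7)
        w = connectivity_weights(sub)
        on = final_scores(cand, w,
                          penalty_factors(cand.genes,
                                          bundle42.penalty_library, 0.5))
        off = final_scores(cand, w,
                           penalty_factors(cand.genes,
                                           bundle42.penalty_library, 0.0))
        assert {s.gene for s in on} == {s.gene for s in off}
        assert any(a.final_score != b.final_score
                   for a, b in zip(sorted(on, key=lambda s: s.gene),
                                   sorted(off, key=lambda s: s.gene)))


class TestCombine:
    def test_geometric_mean_for_shared_genes(self):
        sig = combine_experiments([_score("A", "t", 2.0)],
                                  [_score("A", "v", 0.5)])
        entry = sig.entries["A"]
        assert entry.combined_score == pytest.approx(1.0)
        assert entry.provenance == "both"

    def test_singleton_carries_own_score(self):
        sig = combine_experiments([_score("A", "t", 1.4)],
                                  [_score("B", "v", 0.9)])
        assert sig.entries["A"].combined_score == pytest.approx(1.4)
        assert sig.entries["A"].provenance == "training_only"
        assert sig.entries["B"].provenance == "validation_only"

    def test_union_size_by_inclusion_exclusion(self):
        shared = [f"S{i}" for i in range(15)]
        a = [_score(g, "t", 1.5) for g in shared + [f"A{i}" for i in range(31)]]
        b = [_score(g, "v", 1.5) for g in shared + [f"B{i}" for i in range(15)]]
        sig = combine_experiments(a, b)
        assert (len(a), len(b)) == (46, 30)
        assert len(sig) == 61

    def test_strata_counts_partition_signature(self):
        a = [_score("A", "t", 2.0), _score("B", "t", 0.5),
             _score("C", "t", 1.0)]
        b = [_score("D", "v", 3.0)]
        sig = combine_experiments(a, b)
        counts = sig.strata_counts()
        assert counts == {"above_1": 2, "below_1": 1, "equal_1": 1}
        assert sum(counts.values()) == len(sig)

    def test_arithmetic_mean_option(self):
        sig = combine_experiments([_score("A", "t", 2.0)],
                                  [_score("A", "v", 0.5)], method="arithmetic")
        assert sig.entries["A"].combined_score == pytest.approx(1.25)

    def test_same_experiment_id_rejected(self):
        with pytest.raises(UsageError):
            combine_experiments([_score("A", "t", 1.0)],
                                [_score("B", "t", 1.0)])
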