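"""Signed-community construction, Q-/Qs/frustration/CSB/PPC and hubs."""

import math
from itertools import combinations

import pytest

from signedcomm import (
    GeneratorParams,
    Partition,
    UndefinedMetricError,
    UndirectedSignedNetwork,
    build_signed_communities,
    classify_stability,
    classify_triad,
    csb,
    frustration,
    generate,
    metrics_report,
    negative_hubs,
    ppc,
    q_negative,
    q_positive,
    q_signed,
    reciprocal_projection,
)

from conftest import random_undirected
from _oracles import (
    community_triads,
    frustration_count,
    pairwise_q_signed,
    set_partitions,
)


def toy_two_blocks() -> tuple[UndirectedSignedNetwork, Partition]:
    net = UndirectedSignedNetwork(
        ["a", "b", "c", "d"],
        {("a", "b"): 1, ("c", "d"): 1, ("a", "c"): -1},
    )
    return net, Partition({"a": 0, "b": 0, "c": 1, "d": 1})


class TestSignedCommunitySet:
    def test_direct_counts_on_toy(self):
        net, p = toy_two_blocks()
        scs = build_signed_communities(net, p)
        assert scs.mc_pos == {0: 1, 1: 1} and scs.mc_neg == {0: 0, 1: 0}
        assert scs.inter_neg == 1 and scs.inter_pos == 0
        assert scs.sizes == {0: 2, 1: 2}

    def test_single_community_absorbs_all_links(self):
        net, _ = toy_two_blocks()
        scs = build_signed_communities(net, Partition({v: 0 for v in net.node_ids}))
        assert scs.total_mc_pos == net.m_pos and scs.total_mc_neg == net.m_neg
        assert scs.inter_pos == scs.inter_neg == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_identity_on_random_networks(self, seed):
        net = random_undirected(seed)
        labels = {v: k % 3 for k, v in enumerate(net.node_ids)}
        scs = build_signed_communities(net, Partition(labels))
        assert scs.total_mc_pos + scs.inter_pos == net.m_pos
        assert scs.total_mc_neg + scs.inter_neg == net.m_neg
        assert sum(scs.sizes.values()) == net.n_nodes


class TestQNegative:
    def test_zero_without_negative_links(self):
        net = UndirectedSignedNetwork(["a", "b"], {("a", "b"): 1})
        assert q_negative(net, Partition({"a": 0, "b": 0})) == 0.0

    def test_negatives_inside_communities_match_hand_formula(self):
        # negative subgraph: edges {a,b} and {c,d}, both intra. m=2, per
        # community: intra=1, degree sum=2, so Q- = 2*(1/2 - (2/4)^2) = 1/2.
        net = UndirectedSignedNetwork(
            ["a", "b", "c", "d"], {("a", "b"): -1, ("c", "d"): -1, ("a", "c"): 1}
        )
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        assert math.isclose(q_negative(net, p), 0.5, rel_tol=1e-12)

    def test_negatives_exclusively_between_communities_score_negative(self):
        net, p = toy_two_blocks()
        assert q_negative(net, p) < 0


class TestQSigned:
    def test_equals_q_positive_without_negative_links(self, two_cliques):
        p = Partition({v: 0 if v.startswith("a") else 1 for v in two_cliques.node_ids})
        assert math.isclose(
            q_signed(two_cliques, p), q_positive(two_cliques, p), rel_tol=1e-12
        )

    def test_balanced_counts_give_half_difference(self):
        net = UndirectedSignedNetwork(
            ["a", "b", "c", "d"], {("a", "b"): 1, ("c", "d"): -1}
        )
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        expected = (q_positive(net, p) - q_negative(net, p)) / 2
        assert math.isclose(q_signed(net, p), expected, rel_tol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_pairwise_summation(self, seed):
        net = random_undirected(seed, n=10)
        if net.m_pos == 0 or net.m_neg == 0:
            pytest.skip("needs both signs")
        p = Partition({v: k % 2 for k, v in enumerate(net.node_ids)})
        assert math.isclose(
            q_signed(net, p), pairwise_q_signed(net, p.assignment), rel_tol=1e-10
        )


class TestFrustration:
    def test_perfect_signed_partition_scores_zero(self):
        net, p = toy_two_blocks()
        assert frustration(net, p) == 0.0

    def test_single_community_counts_all_negatives(self):
        net, _ = toy_two_blocks()
        p = Partition({v: 0 for v in net.node_ids})
        assert frustration(net, p, normalized=False) == net.m_neg

    def test_minimum_over_partitions_matches_exhaustive_search(self):
        net = random_undirected(123, n=7)
        ours = min(
            frustration(
                net,
                Partition(
                    {v: k for k, blk in enumerate(blocks) for v in blk}
                ),
                normalized=False,
            )
            for blocks in set_partitions(net.node_ids)
        )
        oracle = min(
            frustration_count(net, {v: k for k, blk in enumerate(blocks) for v in blk})
            for blocks in set_partitions(net.node_ids)
        )
        assert ours == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_normalized_form_equals_count_identity(self, seed):
        net = random_undirected(seed)
        p = Partition({v: k % 3 for k, v in enumerate(net.node_ids)})
        scs = build_signed_communities(net, p)
        expected = (scs.inter_pos + scs.total_mc_neg) / net.m_total
        assert math.isclose(frustration(net, p), expected, rel_tol=1e-12)


class TestTriadsAndCSB:
    @pytest.mark.parametrize(
        "signs, expected",
        [
            ((1, 1, 1), "balanced"),
            ((1, -1, -1), "balanced"),
            ((1, 1, -1), "unbalanced"),
            ((-1, -1, -1), "unbalanced"),  # strong-balance convention
        ],
    )
    def test_triad_classification(self, signs, expected):
        assert classify_triad(*signs) == expected

    def test_positive_clique_community_is_fully_balanced(self):
        nodes = ["a", "b", "c", "d"]
        edges = {(x, y): 1 for x, y in combinations(nodes, 2)}
        net = UndirectedSignedNetwork(nodes, edges)
        value, census = csb(net, Partition({v: 0 for v in nodes}))
        assert value == 1.0
        assert census.total_in_communities == 4

    def test_one_negative_edge_in_triangle_breaks_balance(self):
        net = UndirectedSignedNetwork(
            ["a", "b", "c"], {("a", "b"): 1, ("b", "c"): 1, ("a", "c"): -1}
        )
        value, _ = csb(net, Partition({v: 0 for v in net.node_ids}))
        assert value == 0.0

    def test_no_triads_is_flagged_undefined(self):
        net, p = toy_two_blocks()
        value, census = csb(net, p)
        assert value is None and census.total_in_communities == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_census_matches_cubic_enumeration(self, seed):
        net = random_undirected(seed, n=12)
        p = Partition({v: k % 2 for k, v in enumerate(net.node_ids)})
        value, census = csb(net, p)
        bal, tot = community_triads(net, p.assignment)
        assert (census.balanced_in_communities, census.total_in_communities) == (bal, tot)

    def test_csb_is_one_when_communities_have_no_negatives(self):
        params = GeneratorParams(
            n_nodes=30, community_sizes=[10] * 3, p_pos_in=0.8, p_neg_out=0.3, seed=0
        )
        net, truth = generate(params)
        recip, _ = reciprocal_projection(net)
        value, census = csb(recip, truth.partition)
        assert census.total_in_communities > 0
        assert value == 1.0


class TestPPCAndStability:
    def test_no_negative_links_means_zero_ppc(self, two_cliques):
        p = Partition({v: 0 if v.startswith("a") else 1 for v in two_cliques.node_ids})
        assert ppc(q_positive(two_cliques, p), q_signed(two_cliques, p)) == 0.0

    def test_direct_arithmetic(self):
        assert math.isclose(ppc(0.8, 0.6), 25.0, rel_tol=1e-12)

    def test_undefined_for_nonpositive_q(self):
        with pytest.raises(UndefinedMetricError):
            ppc(0.0, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_algebraic_identity_with_signed_modularity_expansion(self, seed):
        """PPC via definition equals 100 * (2w-/(2w+ + 2w-)) * (Q+ + Q-)/Q+."""
        net = random_undirected(seed, n=14)
        if net.m_pos == 0 or net.m_neg == 0:
            pytest.skip("needs both signs")
        p = Partition({v: k % 3 for k, v in enumerate(net.node_ids)})
        qp, qn, qs = q_positive(net, p), q_negative(net, p), q_signed(net, p)
        if qp <= 0:
            pytest.skip("Q+ not positive for this draw")
        lhs = ppc(qp, qs)
        w_neg_frac = net.m_neg / (net.m_pos + net.m_neg)
        rhs = 100.0 * w_neg_frac * (qp + qn) / qp
        assert math.isclose(lhs, rhs, abs_tol=1e-12)

    @pytest.mark.parametrize(
        "value, expected",
        [(0.0, "stable"), (9.999, "stable"), (10.0, "semi-stable"),
         (24.999, "semi-stable"), (25.0, "unstable"), (80.0, "unstable")],
    )
    def test_stability_boundaries_are_half_open(self, value, expected):
        assert classify_stability(value) == expected

    def test_high_perturbation_regime_classified_unstable(self):
        """Many within-community enmities push PPC past the unstable threshold
        in nearly every draw."""
        hits = 0
        for seed in range(40):
            params = GeneratorParams(
                n_nodes=60,
                community_sizes=[15] * 4,
                p_pos_in=0.6,
                p_neg_in=0.25,
                p_neg_out=0.1,
                seed=seed,
            )
            net, truth = generate(params)
            recip, _ = reciprocal_projection(net)
            rep = metrics_report(recip, truth.partition)
            if rep.stability_class == "unstable":
                hits += 1
        assert hits >= 38


class TestNegativeHubs:
    def test_planted_hub_is_always_flagged(self):
        params = GeneratorParams(
            n_nodes=40,
            community_sizes=[20] * 2,
            p_pos_in=0.5,
            p_neg_out=0.05,
            n_hubs=1,
            hub_neg_degree=5,
            seed=3,
        )
        net, truth = generate(params)
        recip, _ = reciprocal_projection(net)
        scs = build_signed_communities(recip, truth.partition)
        report = negative_hubs(scs, min_intra_neg=5)
        assert set(truth.hub_nodes) <= set(report.flagged)

    def test_all_positive_communities_have_no_hubs(self, two_cliques):
        p = Partition({v: 0 if v.startswith("a") else 1 for v in two_cliques.node_ids})
        scs = build_signed_communities(two_cliques, p)
        assert negative_hubs(scs, 1).flagged == []
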