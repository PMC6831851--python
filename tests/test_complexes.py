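"""Complex discovery: MCL, cohesiveness growth, core-attachment, matching."""

import networkx as nx
import numpy as np
import pytest

from cofracnet.complexes import (
    PredictedComplex,
    cohesiveness,
    cohesiveness_grow,
    core_attach,
    interaction_profile_correlation,
    match_and_select,
    mcl_cluster,
    omega,
    within_between_test,
)
from cofracnet.io import ReferenceComplexCatalog


def clique_graph(*cliques, weight=1.0):
    g = nx.Graph()
    for nodes in cliques:
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                g.add_edge(a, b, weight=weight)
    return g


class TestOmega:
    def test_identical_sets_score_one(self):
        assert omega({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert omega({"a"}, {"b", "c"}) == 0.0

    def test_partial_overlap(self):
        assert omega({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(4 / 9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            omega(set(), {"a"})

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        universe = list("abcdefghij")
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 8), replace=False))
            assert omega(a, b) == omega(b, a)


class TestMcl:
    def test_two_disjoint_triangles(self):
        g = clique_graph(list("abc"), list("xyz"))
        clusters = mcl_cluster(g)
        assert sorted(sorted(c.members) for c in clusters) == [list("abc"), list("xyz")]

    def test_single_edge_yields_heterodimer(self):
        g = clique_graph(["a", "b"])
        (cluster,) = mcl_cluster(g)
        assert cluster.members == frozenset("ab")

    def test_weak_bridge_barbell_splits(self):
        g = clique_graph(list("abcd"), list("wxyz"), weight=1.0)
        g.add_edge("d", "w", weight=0.1)
        clusters = mcl_cluster(g, inflation=2.0)
        assert sorted(sorted(c.members) for c in clusters) == [list("abcd"), list("wxyz")]

    def test_disjoint_cliques_match_connected_components(self):
        g = clique_graph(list("abc"), list("defg"), ["h", "i"], list("jklmn"))
        clusters = {frozenset(c.members) for c in mcl_cluster(g)}
        components = {frozenset(c) for c in nx.connected_components(g)}
        assert clusters == components

    def test_deterministic(self):
        g = clique_graph(list("abcd"), list("cdef"))
        a = [sorted(c.members) for c in mcl_cluster(g)]
        b = [sorted(c.members) for c in mcl_cluster(g)]
        assert a == b


class TestCohesiveness:
    def test_isolated_clique_with_zero_penalty(self):
        g = clique_graph(list("abcd"))
        assert cohesiveness(g, set("abcd"), penalty=0.0) == 1.0

    def test_pendant_node_changes_score_by_known_amount(self):
        # triangle a-b-c (weight 1 each) with pendant d attached to c (weight 1)
        g = clique_graph(list("abc"))
        g.add_edge("c", "d", weight=1.0)
        p = 2.0
        f_core = cohesiveness(g, set("abc"), p)  # w_in 3, w_bound 1
        f_ext = cohesiveness(g, set("abcd"), p)  # w_in 4, w_bound 0
        assert f_core == pytest.approx(3 / (3 + 1 + p))
        assert f_ext == pytest.approx(4 / (4 + 0 + p))

    def test_negative_penalty_rejected(self):
        g = clique_graph(["a", "b"])
        with pytest.raises(ValueError):
            cohesiveness_grow(g, penalty=-1.0)

    def test_grows_planted_cliques(self):
        g = clique_graph(list("abcd"), list("wxyz"), weight=5.0)
        clusters = cohesiveness_grow(g, penalty=2.0)
        assert {frozenset(c.members) for c in clusters} == {
            frozenset("abcd"),
            frozenset("wxyz"),
        }

    def test_heavily_overlapping_sets_merge(self):
        # two 10-cliques sharing 9 members: omega = 81/100 >= 0.8 -> one set
        left = [f"n{i}" for i in range(10)]
        right = [f"n{i}" for i in range(1, 11)]
        g = clique_graph(left, right, weight=3.0)
        clusters = cohesiveness_grow(g, penalty=2.0, overlap_merge=0.8)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset(left) | frozenset(right)

    def test_scale_invariance_with_zero_penalty(self):
        g = clique_graph(list("abcd"))
        g.add_edge("d", "e", weight=1.0)
        f1 = cohesiveness(g, set("abc"), penalty=0.0)
        g10 = clique_graph(list("abcd"), weight=10.0)
        g10.add_edge("d", "e", weight=10.0)
        assert cohesiveness(g10, set("abc"), penalty=0.0) == pytest.approx(f1)


class TestCoreAttach:
    def test_full_clique_is_a_core(self):
        g = clique_graph(list("abcd"))
        clusters = core_attach(g, core_density=1.0, attach_ratio=1.0)
        assert frozenset("abcd") in {c.members for c in clusters}

    def test_half_connected_neighbor_attaches_at_ratio_half(self):
        g = clique_graph(list("abcd"), weight=5.0)
        g.add_edge("e", "a", weight=0.5)
        g.add_edge("e", "b", weight=0.5)
        clusters = core_attach(g, core_density=1.0, attach_ratio=0.5)
        assert frozenset("abcde") in {c.members for c in clusters}

    def test_strict_ratio_keeps_cores_bare(self):
        g = clique_graph(list("abcd"), weight=5.0)
        g.add_edge("e", "a", weight=0.5)
        clusters = core_attach(g, core_density=1.0, attach_ratio=1.0)
        assert all("e" not in c.members or len(c.members) == 2 for c in clusters)

    def test_parameter_range_enforced(self):
        g = clique_graph(["a", "b"])
        with pytest.raises(ValueError):
            core_attach(g, core_density=0.0)
        with pytest.raises(ValueError):
            core_attach(g, attach_ratio=1.5)


class TestMatchAndSelect:
    def _catalog(self):
        return ReferenceComplexCatalog(
            {"c1": frozenset("abcd"), "c2": frozenset("wxyz"), "c3": frozenset("pq")}
        )

    def test_exact_predictions_all_recovered(self):
        cat = self._catalog()
        preds = {
            "mcl": [PredictedComplex(frozenset(m), "mcl") for m in cat.complexes.values()]
        }
        matched, best, pvals = match_and_select(preds, cat)
        assert best == "mcl"
        for p in matched["mcl"]:
            assert p.best_match[1] == 1.0

    def test_omega_boundary_is_inclusive(self):
        # omega = 0.24 misses the cutoff, 0.25 makes it
        cat = ReferenceComplexCatalog({"c": frozenset(f"r{i}" for i in range(15))})
        low = PredictedComplex(
            frozenset(list(f"r{i}" for i in range(6)) + [f"x{i}" for i in range(4)]),
            "a",
        )  # overlap 6, sizes 10 x 15 -> 36/150 = 0.24
        hit = PredictedComplex(frozenset(f"r{i}" for i in range(6)), "b")
        # overlap 6, sizes 6 x 15 -> 36/90 = 0.4
        matched, best, _ = match_and_select({"a": [low], "b": [hit]}, cat)
        assert matched["a"][0].best_match[1] == pytest.approx(0.24)
        assert matched["b"][0].best_match[1] >= 0.25
        assert best == "b"

    def test_deterministic_best_algorithm(self):
        cat = self._catalog()
        preds = {
            "mcl": [PredictedComplex(frozenset("abcd"), "mcl")],
            "core_attach": [PredictedComplex(frozenset("abcd"), "core_attach")],
        }
        results = {match_and_select(dict(preds), cat)[1] for _ in range(3)}
        assert len(results) == 1

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            match_and_select(
                {"mcl": []}, ReferenceComplexCatalog({})
            )


class TestInteractionProfiles:
    def test_identical_neighborhoods_fully_correlated(self):
        g = nx.Graph()
        for v, w in [("x", 1.0), ("y", 2.0), ("z", 3.0)]:
            g.add_edge("a", v, weight=w)
            g.add_edge("b", v, weight=w)
        assert interaction_profile_correlation(g, ("a", "b")) == pytest.approx(1.0)

    def test_partner_only_protein_is_skipped(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("a", "x", weight=1.0)
        g.add_edge("x", "y", weight=1.0)
        assert interaction_profile_correlation(g, ("a", "b")) is None

    def test_missing_protein_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        with pytest.raises(ValueError):
            interaction_profile_correlation(g, ("a", "zz"))


class TestWithinBetween:
    def test_identical_samples_are_indistinguishable(self):
        p = within_between_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert 0.3 < p < 0.7

    def test_fully_separated_samples_match_exact_enumeration(self):
        # all within > all between, 5 vs 5: exact one-sided rank-sum
        # p = 1 / C(10, 5) = 1/252
        p = within_between_test([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert p == pytest.approx(1 / 252)

    def test_swapped_samples_flip_the_tail(self):
        p = within_between_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p > 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            within_between_test([], [0.1])
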