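"""Randomization nulls, margin z-test, relative cost, event ratios."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cophylo as cp
from cophylo.hypotheses import randomize_associations


def make_null(real, costs_vector, mode="target_permutation", seed=0):
    arr = np.asarray(costs_vector, dtype=float)
    return cp.NullDistribution(real_cost=real, randomized_costs=arr,
                               N=len(arr), seed=seed,
                               randomization_mode=mode)


class TestRandomizeAssociations:
    def test_target_permutation_preserves_multiset(self):
        assoc = cp.AssociationTable(
            pairs=(("v1", "A"), ("v2", "A"), ("v3", "B")))
        out = randomize_associations(assoc, "target_permutation", seed=5)
        assert sorted(out.targets) == ["A", "A", "B"]
        assert out.dependents == assoc.dependents

    def test_single_pair_unchanged(self):
        assoc = cp.AssociationTable(pairs=(("v1", "A"),))
        for mode in ("target_permutation", "host_tip_renaming"):
            assert randomize_associations(assoc, mode, seed=3).pairs == \
                assoc.pairs

    def test_seed_determinism_and_divergence(self):
        pairs = tuple((f"v{i}", f"H{i}") for i in range(12))
        assoc = cp.AssociationTable(
            pairs=pairs, independent_labels=tuple(f"H{i}" for i in range(12)))
        for mode in ("target_permutation", "host_tip_renaming"):
            a = randomize_associations(assoc, mode, seed=1)
            b = randomize_associations(assoc, mode, seed=1)
            c = randomize_associations(assoc, mode, seed=2)
            assert a.pairs == b.pairs
            assert a.pairs != c.pairs

    def test_host_tip_renaming_preserves_structure(self):
        # two viruses sharing a host still share one after renaming
        assoc = cp.AssociationTable(
            pairs=(("v1", "A"), ("v2", "A"), ("v3", "B")),
            independent_labels=("A", "B", "C"))
        out = randomize_associations(assoc, "host_tip_renaming", seed=7)
        m = out.mapping
        assert m["v1"] == m["v2"]
        assert m["v3"] != m["v1"]

    def test_unknown_mode(self):
        assoc = cp.AssociationTable(pairs=(("v1", "A"),))
        with pytest.raises(cp.ValidationError):
            randomize_associations(assoc, "bogus", seed=0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=1, max_size=12),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_property(self, targets, seed):
        pairs = tuple((f"v{i}", t) for i, t in enumerate(targets))
        assoc = cp.AssociationTable(pairs=pairs)
        out = randomize_associations(assoc, "target_permutation", seed)
        assert sorted(out.targets) == sorted(targets)


class TestCostNull:
    def test_perfect_congruence_real_zero(self, jane_costs):
        host = cp.simulate_host_tree(10, seed=2)
        assoc = cp.AssociationTable.identity(host.tip_labels, ind_tree=host)
        nd = cp.cost_null(host, host.copy(), assoc, jane_costs, N=100,
                          seed=4)
        assert nd.real_cost == 0
        assert np.all(nd.randomized_costs >= 0)

    def test_cherry_null_has_at_most_two_values(self, ind3, jane_costs):
        # dep cherry on 2 hosts: only two association permutations exist,
        # so the randomized costs take at most 2 distinct values -- and
        # exactly the costs of those two enumerated tables.
        dep = cp.parse_newick("(p1,p2);")
        assoc = cp.AssociationTable.from_pairs(
            [("p1", "A"), ("p2", "C")], dep_tree=dep, ind_tree=ind3)
        flipped = cp.AssociationTable.from_pairs(
            [("p1", "C"), ("p2", "A")], dep_tree=dep, ind_tree=ind3)
        expected = {
            cp.reconcile(ind3, dep, assoc, jane_costs).total_cost,
            cp.reconcile(ind3, dep, flipped, jane_costs).total_cost,
        }
        nd = cp.cost_null(ind3, dep, assoc, jane_costs, N=50, seed=9)
        assert set(nd.randomized_costs) <= expected

    def test_n_one_gives_length_one(self, ind3, jane_costs):
        dep = cp.parse_newick("(p1,p2);")
        assoc = cp.AssociationTable.from_pairs(
            [("p1", "A"), ("p2", "C")], dep_tree=dep, ind_tree=ind3)
        nd = cp.cost_null(ind3, dep, assoc, jane_costs, N=1, seed=0)
        assert len(nd.randomized_costs) == 1

    def test_bit_reproducible(self, jane_costs):
        host = cp.simulate_host_tree(8, seed=5)
        assoc = cp.AssociationTable.identity(host.tip_labels, ind_tree=host)
        a = cp.cost_null(host, host.copy(), assoc, jane_costs, N=30, seed=8)
        b = cp.cost_null(host, host.copy(), assoc, jane_costs, N=30, seed=8)
        assert np.array_equal(a.randomized_costs, b.randomized_costs)


class TestMarginZTest:
    def test_closed_form_z(self):
        # construct a null with sample mean exactly 110 and sd exactly 10;
        # closed form: z = (110 - 1.05*100) / (10 / sqrt(1000)) = 15.811...
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        x = 110.0 + 10.0 * (x - x.mean()) / x.std(ddof=1)
        nd = make_null(100.0, x)
        res = cp.margin_z_test(nd)
        assert res.z_statistic == pytest.approx(
            5.0 / (10.0 / math.sqrt(1000)), rel=1e-9)
        assert res.p_value < 1e-12
        assert res.significant

    def test_degenerate_all_equal_real(self):
        nd = make_null(7.0, [7.0] * 20)
        res = cp.margin_z_test(nd)
        assert res.degenerate
        assert res.p_value == 1.0
        assert not res.significant

    def test_degenerate_all_above_threshold(self):
        nd = make_null(10.0, [20.0] * 20)
        res = cp.margin_z_test(nd)
        assert res.degenerate
        assert res.p_value == 0.0
        assert res.significant

    def test_zero_real_cost_margin_vanishes(self):
        nd = make_null(0.0, [5.0, 6.0, 7.0, 8.0, 9.0] * 40)
        res = cp.margin_z_test(nd)
        assert res.z_statistic > 0
        assert res.significant

    def test_requires_two_randomizations(self):
        with pytest.raises(cp.ValidationError):
            cp.margin_z_test(make_null(1.0, [2.0]))


class TestRelativeCost:
    @pytest.mark.parametrize("real,null,expected", [
        (0.0, [3.0, 4.0, 5.0], 0.0),
        (42.0, [84.0, 84.0, 84.0], 50.0),
        (6.0, [6.0, 6.0, 6.0], 100.0),
    ])
    def test_percent_arithmetic(self, real, null, expected):
        assert cp.relative_cost_percent(make_null(real, null)) == expected

    def test_zero_median_is_an_error_not_zero(self):
        nd = make_null(1.0, [0.0, 0.0, 0.0])
        with pytest.raises(cp.DegenerateStatisticError):
            cp.relative_cost(nd)


class TestEventRatioTest:
    def test_matrix_shape_four_tip_tree(self):
        host = cp.simulate_host_tree(4, seed=1)
        dep = host.unroot()
        assoc = cp.AssociationTable.identity(host.tip_labels, ind_tree=host)
        er = cp.event_ratio_test(host, cp.TreeSet([dep]), assoc,
                                 n_randomizations=10, seed=0)
        assert er.real_cospeciation.shape == (1, 5)
        assert er.randomized_switch.shape == (1, 5, 10)

    def test_perfect_congruence_enriches_cospeciation(self):
        # real associations on a perfectly codiverging 12-tip pair give
        # more cospeciations than host-renamed nulls; switch counts do not
        # exceed the null (the qualitative contrast the method is built on)
        host = cp.simulate_host_tree(12, seed=77)
        assoc = cp.AssociationTable.identity(host.tip_labels, ind_tree=host)
        er = cp.event_ratio_test(host, cp.TreeSet([host.unroot()]), assoc,
                                 n_randomizations=100, seed=13)
        assert er.cospeciation_ratio > 1
        assert er.p_cospeciation <= 0.05
        assert er.p_switch > 0.05

    def test_rooted_dependent_rejected(self):
        host = cp.simulate_host_tree(5, seed=2)
        assoc = cp.AssociationTable.identity(host.tip_labels, ind_tree=host)
        with pytest.raises(cp.ValidationError):
            cp.event_ratio_test(host, cp.TreeSet([host.copy()]), assoc,
                                n_randomizations=5, seed=0)


class TestPairedCostComparison:
    def test_identical_vectors_give_p_one(self):
        assert cp.paired_cost_comparison([1.0] * 10, [1.0] * 10) == 1.0

    def test_constant_shift_is_extreme(self):
        a = np.arange(20, dtype=float)
        p = cp.paired_cost_comparison(a, a + 10)
        assert p < 1e-3

    def test_length_mismatch(self):
        with pytest.raises(cp.ValidationError):
            cp.paired_cost_comparison([1.0] * 6, [1.0] * 7)

    def test_minimum_length(self):
        with pytest.raises(cp.ValidationError):
            cp.paired_cost_comparison([1.0] * 4, [2.0] * 4)
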