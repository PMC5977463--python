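"""Balance/count rules and recursive tree construction."""

import pytest

from rxntrees.kegg_io import Compound, ReactionTerm, parse_equation
from rxntrees.rsf import Internal, LonerTip, PairTip, topology_pattern
from rxntrees.split import (
    CountIndex,
    SplitConfig,
    SplitError,
    SubProblem,
    aggregate_units,
    build_count_index,
    build_tree,
    build_trees,
    ecp_key,
    enumerate_candidates,
    mass_difference,
    select_candidate,
    walk_subproblems,
)


def catalog_of(**weights):
    return {cid: Compound(cid, None, w) for cid, w in weights.items()}


class TestAggregateUnits:
    def test_coefficient_multiplies_weight(self):
        catalog = catalog_of(C00407=131.17)
        (unit,) = aggregate_units([ReactionTerm("C00407", 2)], catalog)
        assert unit.weight == pytest.approx(262.34)

    def test_duplicate_terms_fold(self):
        catalog = catalog_of(X=10.0)
        (unit,) = aggregate_units(
            [ReactionTerm("X", 1), ReactionTerm("X", 2)], catalog)
        assert unit.coefficient == 3 and unit.weight == pytest.approx(30.0)

    def test_missing_weight_names_compound(self):
        with pytest.raises(SplitError, match="C_GONE"):
            aggregate_units([ReactionTerm("C_GONE", 1)], {})


class TestMassDifference:
    @pytest.mark.parametrize("w_a, w_b, expected", [
        (186.06, 168.04, 0.09685),
        (100.0, 100.0, 0.0),
        (507.18, 525.19, 0.03429),
    ])
    def test_values(self, w_a, w_b, expected):
        assert mass_difference(w_a, w_b) == pytest.approx(expected, abs=5e-6)
        assert mass_difference(w_b, w_a) == mass_difference(w_a, w_b)

    def test_requires_positive_weights(self):
        with pytest.raises(ValueError):
            mass_difference(0.0, 1.0)


class TestEnumerateCandidates:
    @pytest.mark.parametrize("n_left, n_right, expected", [
        (1, 2, 2), (2, 2, 8), (1, 1, 0), (3, 2, 20),
    ])
    def test_counts_exclude_whole(self, n_left, n_right, expected):
        left = tuple(
            aggregate_units([ReactionTerm(f"L{i}", 1)],
                            catalog_of(**{f"L{i}": 10.0 + i}))[0]
            for i in range(n_left))
        right = tuple(
            aggregate_units([ReactionTerm(f"R{i}", 1)],
                            catalog_of(**{f"R{i}": 20.0 + i}))[0]
            for i in range(n_right))
        sp = SubProblem(left, right)
        assert len(enumerate_candidates(sp)) == expected
        assert enumerate_candidates(SubProblem(left, ())) == []

    def test_size_guard(self):
        catalog = catalog_of(**{f"X{i}": 10.0 + i for i in range(12)},
                             **{f"Y{i}": 20.0 + i for i in range(12)})
        rxn = parse_equation(
            "RBIG",
            " + ".join(f"X{i}" for i in range(12)) + " <=> "
            + " + ".join(f"Y{i}" for i in range(12)))
        with pytest.raises(SplitError, match="guard"):
            build_tree(rxn, catalog, config=SplitConfig(max_candidates=1000))


class TestCountIndex:
    def test_frequency_counts_reactions_once(self):
        catalog = catalog_of(ATP=507.18, ADP=427.2, A=100.0, B=90.0, C=80.0)
        rxns = [
            parse_equation("R1", "ATP + A <=> ADP + B"),
            parse_equation("R2", "ATP + B <=> ADP + C"),
            parse_equation("R3", "ATP + C <=> ADP + A"),
            parse_equation("R4", "A <=> B + C"),
        ]
        index = build_count_index(rxns, catalog)
        key = (("ADP",), ("ATP",))
        assert index.frequency(key) == 3

    def test_key_is_side_agnostic(self):
        catalog = catalog_of(ATP=507.18, ADP=427.2)
        (atp,) = aggregate_units([ReactionTerm("ATP", 1)], catalog)
        (adp,) = aggregate_units([ReactionTerm("ADP", 1)], catalog)
        assert ecp_key((atp,), (adp,)) == ecp_key((adp,), (atp,))

    def test_empty(self):
        assert build_count_index([], {}).frequencies == {}


class TestSelectCandidate:
    def test_balance_on_unique_minimum(self, bundled):
        catalog, _, _ = bundled
        rxn = parse_equation("R00658", "C00631 <=> C00074 + C00001")
        sp = SubProblem(aggregate_units(rxn.substrates, catalog),
                        aggregate_units(rxn.products, catalog))
        selected, rule = select_candidate(sp)
        assert rule == "balance"
        assert ecp_key(selected.a, selected.b) == (("C00074",), ("C00631",))

    def test_count_on_exact_tie(self, bundled):
        catalog, reactions, _ = bundled
        index = build_count_index(reactions, catalog)
        rxn = next(r for r in reactions if r.id == "R02090")
        sp = SubProblem(aggregate_units(rxn.substrates, catalog),
                        aggregate_units(rxn.products, catalog))
        selected, rule = select_candidate(sp, index)
        assert rule == "count"
        assert ecp_key(selected.a, selected.b) == (("C00002",), ("C00008",))

    def test_unique_minimum_is_balance_even_without_index(self):
        catalog = catalog_of(A=100.0, B=60.0, C=30.0)
        sp = SubProblem(aggregate_units([ReactionTerm("A", 1)], catalog),
                        aggregate_units([ReactionTerm("B", 1),
                                         ReactionTerm("C", 1)], catalog))
        assert len(enumerate_candidates(sp)) == 2
        selected, rule = select_candidate(sp)
        assert rule == "balance"
        assert ecp_key(selected.a, selected.b) == (("A",), ("B",))

    def test_empty_subproblem_is_an_error(self):
        with pytest.raises(SplitError):
            select_candidate(SubProblem((), ()))

    def test_frequency_tie_breaks_lexicographically(self):
        catalog = catalog_of(A=100.0, B=100.0, C=100.0)
        sp = SubProblem(aggregate_units([ReactionTerm("A", 1)], catalog),
                        aggregate_units([ReactionTerm("B", 1),
                                         ReactionTerm("C", 1)], catalog))
        selected, rule = select_candidate(sp, CountIndex())
        assert rule == "count"
        assert ecp_key(selected.a, selected.b) == (("A",), ("B",))


class TestBuildTree:
    def test_atp_hydrolysis_shape(self):
        # ATP + H2O <=> ADP + Pi: remainder water loner, then Pi loner,
        # then the ATP/ADP pair (nested twice).
        catalog = catalog_of(C00002=507.18, C00001=18.02, C00008=427.2,
                             C00009=97.99)
        rxn = parse_equation("RATP", "C00002 + C00001 <=> C00008 + C00009")
        tree = build_tree(rxn, catalog)
        assert topology_pattern(tree) == ">(!(C)(!(C)(C_C)))"
        assert {t.pair for t in tree.pair_tips()} == {
            frozenset({"C00002", "C00008"})}

    def test_one_sided_remainder_peels_lightest_loner(self):
        # ({A,X},{B}) wins the first split, stranding C and D on the
        # product side: the lightest (D) peels first as a left loner.
        catalog = catalog_of(A=100.0, X=110.0, B=210.5, C=30.0, D=20.0)
        rxn = parse_equation("RPEEL", "A + X <=> B + C + D")
        tree = build_tree(rxn, catalog)
        root = tree.root
        assert isinstance(root, Internal) and root.rule == "balance"
        assert root.left == Internal("balance", LonerTip("D", "product"),
                                     LonerTip("C", "product"))

    def test_tip_coverage_on_bundled(self, bundled, bundled_trees):
        catalog, reactions, _ = bundled
        for rxn in reactions:
            tree = bundled_trees[rxn.id]
            tips = set()
            for tip in tree.iter_tips():
                ids = ({tip.substrate_id, tip.product_id}
                       if isinstance(tip, PairTip) else {tip.compound_id})
                assert not (ids & tips), "compound in more than one tip"
                tips |= ids
            assert tips == rxn.compound_ids

    def test_balance_nodes_attain_minimum_d(self, bundled, bundled_trees):
        catalog, reactions, _ = bundled
        for rxn in reactions:
            tree = bundled_trees[rxn.id]
            for node, sp, (sel_l, sel_r) in walk_subproblems(
                    tree, rxn, catalog):
                candidates = enumerate_candidates(sp)
                if not candidates or node.rule != "balance":
                    continue
                d_min = min(c.d for c in candidates)
                selected_key = ecp_key(sel_l, sel_r)
                matching = [c for c in candidates
                            if ecp_key(c.a, c.b) == selected_key]
                if not matching:
                    continue  # one-sided peeling node
                assert matching[0].d == pytest.approx(d_min, abs=1e-12)

    def test_determinism_under_input_permutation(self, bundled):
        catalog, reactions, _ = bundled
        forward = build_trees(reactions, catalog)
        backward = build_trees(list(reversed(reactions)), catalog)
        a = {t.reaction_id: t for t in forward}
        b = {t.reaction_id: t for t in backward}
        assert a == b

    def test_tree_has_at_least_two_tips_for_filtered_reactions(
            self, bundled_trees):
        for tree in bundled_trees.values():
            assert len(list(tree.iter_tips())) >= 2
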