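"""Pair matching, hit-fail categories, beta intervals and crosstabs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxntrees.cluster import ClusterOfTrees, cluster_trees
from rxntrees.kegg_io import RPairRecord
from rxntrees.rsf import Internal, LonerTip, PairTip, TreeStructure
from rxntrees.validate import (
    PairMatch,
    beta_interval,
    categorize_reaction,
    class_crosstab,
    confidence_band,
    cts_precision,
    match_tree_pairs,
    validate_trees,
)


def tree_of(rid, *tips):
    root = tips[0]
    for tip in tips[1:]:
        root = Internal("balance", root, tip)
    return TreeStructure.from_root(rid, root)


class TestMatchTreePairs:
    def test_matching_is_unordered(self):
        tree = tree_of("R00025", PairTip("C01847", "C00061"))
        rec = RPairRecord("R00025", "C00061", "C01847", "RC00126", "cofac")
        (match,) = match_tree_pairs(tree, [rec])
        assert match.matched and match.matched_rclass_id == "RC00126"
        assert match.kotera_class == "cofac"

    def test_loners_never_match(self):
        tree = tree_of("R1", LonerTip("C00001", "product"),
                       PairTip("A", "B"))
        rec = RPairRecord("R1", "C00001", "A", "RC1", "leave")
        matches = match_tree_pairs(tree, [rec])
        assert len(matches) == 1 and not matches[0].matched

    def test_other_reactions_annotations_ignored(self):
        tree = tree_of("R1", PairTip("A", "B"))
        rec = RPairRecord("R2", "A", "B", "RC1", "main")
        (match,) = match_tree_pairs(tree, [rec])
        assert not match.matched


class TestCategorize:
    @pytest.mark.parametrize("flags, category, labels", [
        ((True, True), "EPP", ("EPP", "EPP")),
        ((True, False), "MP", ("MPP", "MFP")),
        ((False, False), "FP", ("FP", "FP")),
    ])
    def test_categories(self, flags, category, labels):
        matches = [PairMatch("R1", frozenset({f"A{i}", f"B{i}"}), flag)
                   for i, flag in enumerate(flags)]
        result = categorize_reaction(matches)
        assert (result.category, result.pair_labels) == (category, labels)

    def test_no_pair_tips_is_an_error(self):
        with pytest.raises(ValueError, match="no pair tips"):
            categorize_reaction([])


class TestBetaInterval:
    @pytest.mark.parametrize("y, n, expected", [
        (11, 12, (0.7151, 0.9977, 0.8564)),
        (926, 1028, (0.8818, 0.9183, 0.9000)),
        (1016, 1059, (0.9467, 0.9704, 0.9586)),
    ])
    def test_table_parameterization(self, y, n, expected):
        est = beta_interval(y, n, "table")
        assert est.q025 == pytest.approx(expected[0], abs=5e-5)
        assert est.q975 == pytest.approx(expected[1], abs=5e-5)
        assert est.interval_average == pytest.approx(expected[2], abs=5e-5)

    def test_uniform_prior_quantiles(self):
        est = beta_interval(0, 0, "methods")
        assert (est.q025, est.q975) == pytest.approx((0.025, 0.975))

    def test_table_falls_back_on_degenerate_counts(self):
        # y = n: table mode would need Beta(n, 0); Beta(n+1, 1) has the
        # closed form q(p) = p^(1/(n+1)).
        est = beta_interval(5, 5, "table")
        assert est.q025 == pytest.approx(0.025 ** (1 / 6), abs=1e-10)
        assert est.q975 == pytest.approx(0.975 ** (1 / 6), abs=1e-10)

    @pytest.mark.parametrize("alpha", [1, 3, 11, 40])
    def test_beta_alpha_one_closed_form(self, alpha):
        est = beta_interval(alpha, alpha + 1, "table")  # Beta(alpha, 1)
        assert est.q025 == pytest.approx(0.025 ** (1 / alpha), abs=1e-10)
        assert est.q975 == pytest.approx(0.975 ** (1 / alpha), abs=1e-10)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_interval_brackets_average(self, y, extra):
        n = y + extra
        for mode in ("table", "methods"):
            est = beta_interval(y, n, mode)
            assert est.q025 < est.interval_average < est.q975
            assert 0.0 < est.posterior_mean < 1.0

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            beta_interval(5, 3)
        with pytest.raises(ValueError):
            beta_interval(-1, 3)


class TestConfidenceBand:
    @pytest.mark.parametrize("value, band", [
        (0.9586, "high"), (0.8, "high"), (0.6748, "medium"), (0.6, "medium"),
        (0.458, "low"),
    ])
    def test_bands(self, value, band):
        assert confidence_band(value) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            confidence_band(1.2)


class TestCtsPrecision:
    def make(self, n_reactions, hits_per, fails_per):
        cluster = ClusterOfTrees(
            "CTS-1", ">(!(C_C)(C_C))",
            tuple(f"R{i}" for i in range(n_reactions)), "Balance")
        matches = {}
        for i in range(n_reactions):
            ms = [PairMatch(f"R{i}", frozenset({f"A{j}", f"B{j}"}), True)
                  for j in range(hits_per)]
            ms += [PairMatch(f"R{i}", frozenset({f"X{j}", f"Y{j}"}), False)
                   for j in range(fails_per)]
            matches[f"R{i}"] = ms
        return cluster, matches

    def test_emits_estimate_above_threshold(self):
        cluster, matches = self.make(12, 1, 0)
        est = cts_precision(cluster, matches, min_reactions=10)
        assert est is not None and (est.y, est.n) == (12, 12)

    def test_skips_small_clusters(self):
        cluster, matches = self.make(5, 1, 0)
        assert cts_precision(cluster, matches, min_reactions=10) is None

    def test_skips_clusters_without_pairs(self):
        cluster, _ = self.make(12, 1, 0)
        assert cts_precision(cluster, {}, min_reactions=10) is None


class TestCrosstabAndPipeline:
    def test_counts_conserved(self):
        matches = {
            "R1": [PairMatch("R1", frozenset({"A", "B"}), True,
                             "RC1", "main")],
            "R2": [PairMatch("R2", frozenset({"C", "D"}), True,
                             "RC2", "cofac"),
                   PairMatch("R2", frozenset({"E", "F"}), False)],
        }
        categories = {rid: categorize_reaction(ms)
                      for rid, ms in matches.items()}
        bands = {"R1": "high", "R2": "medium"}
        rpairs = [RPairRecord("R2", "E", "G", "RC3", "leave")]
        table = class_crosstab(matches, categories, bands, rpairs)
        assert table["count"].sum() == 3
        row = table[(table.kotera_class == "leave")
                    & (table.label == "MFP")]
        assert row["count"].item() == 1  # same-compound class fallback

    def test_empty_input(self):
        table = class_crosstab({}, {}, {})
        assert len(table) == 0

    def test_pipeline_with_corrupted_annotations(self):
        """Degrading annotations produces the EPP/MP/FP mix and the
        general estimate reflects the observed hit fraction."""
        trees = []
        records = []
        for i in range(30):
            rid = f"R{i:03d}"
            trees.append(tree_of(rid, PairTip(f"A{i}", f"B{i}"),
                                 PairTip(f"C{i}", f"D{i}")))
            if i < 10:  # both pairs annotated: EPP
                records.append(RPairRecord(rid, f"A{i}", f"B{i}", "RC", "main"))
                records.append(RPairRecord(rid, f"C{i}", f"D{i}", "RC",
                                           "cofac"))
            elif i < 20:  # one pair annotated: MP
                records.append(RPairRecord(rid, f"A{i}", f"B{i}", "RC", "main"))
        clusters = cluster_trees(trees)
        result = validate_trees(trees, records, clusters)
        tally = {"EPP": 0, "MP": 0, "FP": 0}
        for cat in result.categories.values():
            tally[cat.category] += 1
        assert tally == {"EPP": 10, "MP": 10, "FP": 10}
        assert (result.general.y, result.general.n) == (30, 60)
        assert result.general.q025 < 0.5 < result.general.q975
        assert result.crosstab["count"].sum() == 60
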