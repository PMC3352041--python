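"""Hypergeometric tails, ORA, BH adjustment, Venn overlap, overlap codes
and family enrichment — checked against enumeration oracles and scipy."""

import itertools
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mirlink.enrichment import (
    DEPLETED,
    ENRICHED,
    OraResult,
    bh_adjust,
    derive_gene_sets,
    family_ora,
    hypergeom_tail,
    ora,
    overlap_codes,
    venn_overlap,
)
from mirlink.io_formats import (
    GENE,
    MIRNA,
    CategoryDB,
    DeregulationSet,
    FamilyDB,
    InteractionTable,
)
from mirlink.simulate import ScenarioSpec, build_scenario


def enumeration_tail(population, successes, draws, observed, side):
    """Exact oracle: enumerate every equally likely draw of ``draws`` items."""
    hits = 0
    total = 0
    success_items = set(range(successes))
    for draw in itertools.combinations(range(population), draws):
        total += 1
        k = len(success_items.intersection(draw))
        if (side == "upper" and k >= observed) or (side == "lower" and k <= observed):
            hits += 1
    return Fraction(hits, total)


class TestHypergeomTail:
    def test_matches_enumeration_oracle_on_worked_example(self):
        assert hypergeom_tail(10, 4, 5, 4, "upper") == pytest.approx(6 / 252)
        assert enumeration_tail(10, 4, 5, 4, "upper") == Fraction(6, 252)

    def test_degenerate_tails_are_one(self):
        assert hypergeom_tail(10, 0, 5, 0, "lower") == 1.0
        assert hypergeom_tail(10, 4, 5, 0, "upper") == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(population=5, successes=6, draws=2, observed=1),
            dict(population=5, successes=2, draws=6, observed=1),
            dict(population=10, successes=4, draws=5, observed=5),
            dict(population=10, successes=4, draws=5, observed=-1),
        ],
    )
    def test_parameter_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            hypergeom_tail(side="upper", **kwargs)

    def test_invalid_side_raises(self):
        with pytest.raises(ValueError, match="side"):
            hypergeom_tail(10, 4, 5, 2, "both")

    @given(
        population=st.integers(1, 40),
        data=st.data(),
    )
    def test_upper_plus_lower_below_is_one(self, population, data):
        successes = data.draw(st.integers(0, population))
        draws = data.draw(st.integers(0, population))
        k_max = min(draws, successes)
        observed = data.draw(st.integers(min(1, k_max), k_max) if k_max else st.just(0))
        upper = hypergeom_tail(population, successes, draws, observed, "upper")
        if observed == 0:
            assert upper == pytest.approx(1.0)
        else:
            lower = hypergeom_tail(population, successes, draws, observed - 1, "lower")
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    @given(
        population=st.integers(1, 60),
        data=st.data(),
    )
    def test_agrees_with_scipy_hypergeom(self, population, data):
        successes = data.draw(st.integers(0, population))
        draws = data.draw(st.integers(0, population))
        observed = data.draw(st.integers(0, min(draws, successes)))
        expected_upper = float(sps.hypergeom.sf(observed - 1, population, successes, draws))
        expected_lower = float(sps.hypergeom.cdf(observed, population, successes, draws))
        assert hypergeom_tail(population, successes, draws, observed, "upper") == (
            pytest.approx(expected_upper, abs=1e-12)
        )
        assert hypergeom_tail(population, successes, draws, observed, "lower") == (
            pytest.approx(expected_lower, abs=1e-12)
        )


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_tied_p_values_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.2])

    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0, allow_nan=False), min_size=1,
                 max_size=12),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance_and_dominance(self, ps, rnd):
        adjusted = bh_adjust(ps)
        assert all(a >= p - 1e-12 and a <= 1.0 for a, p in zip(adjusted, ps))
        order = list(range(len(ps)))
        rnd.shuffle(order)
        shuffled = bh_adjust([ps[i] for i in order])
        assert shuffled == pytest.approx([adjusted[i] for i in order])


class TestOra:
    def test_worked_enrichment_example(self):
        reference = {f"G{i}" for i in range(10)}
        categories = CategoryDB(categories={"cat": frozenset({"G0", "G1", "G2", "G3"})})
        test = {"G0", "G1", "G2", "G3", "G9"}
        (result,) = ora(test, reference, categories)
        assert result.direction == ENRICHED
        assert result.p_raw == pytest.approx(12 / 252)
        assert result.expected == pytest.approx(2.0)

    def test_test_set_equal_to_reference_is_degenerate(self):
        reference = {f"G{i}" for i in range(8)}
        categories = CategoryDB(
            categories={"a": frozenset({"G0", "G1"}), "b": frozenset({"G2"})}
        )
        for result in ora(reference, reference, categories):
            assert result.test_hits == result.ref_hits
            assert result.p_raw == pytest.approx(1.0)

    def test_test_set_outside_reference_raises(self):
        with pytest.raises(ValueError, match="not contained"):
            ora({"X"}, {"A", "B"}, CategoryDB(categories={"c": frozenset({"A"})}))

    def test_category_absent_from_reference_skipped(self, caplog):
        reference = {"A", "B"}
        categories = CategoryDB(
            categories={"in": frozenset({"A"}), "out": frozenset({"Z"})}
        )
        results = ora({"A"}, reference, categories)
        assert [r.category for r in results] == ["in"]

    def test_planted_category_ranks_first(self):
        bundle = build_scenario(ScenarioSpec(seed=31))
        sets = derive_gene_sets(bundle.mir_dereg, bundle.gene_dereg, bundle.interactions)
        results = ora(sets.dereg_genes, sets.reference, bundle.categories)
        assert results[0].category == bundle.truth["planted_category"]

    def test_results_sorted_by_adjusted_p(self):
        bundle = build_scenario(ScenarioSpec(seed=32))
        sets = derive_gene_sets(bundle.mir_dereg, bundle.gene_dereg, bundle.interactions)
        results = ora(sets.dereg_genes, sets.reference, bundle.categories)
        assert [r.p_adj for r in results] == sorted(r.p_adj for r in results)

    def test_invariant_enforced_on_result_record(self):
        with pytest.raises(ValueError):
            OraResult(
                category="x", test_hits=5, test_size=4, ref_hits=5, ref_size=10,
                expected=2.0, direction=ENRICHED, p_raw=0.1, p_adj=0.1,
            )


class TestDeriveGeneSets:
    def test_hand_enumeration(self):
        mir = DeregulationSet(entity_class=MIRNA, entries={"hsa-miR-1": +1})
        genes = DeregulationSet(entity_class=GENE, entries={"G1": +1, "G3": -1})
        table = InteractionTable(
            pairs=(("hsa-miR-1", "G1", None), ("hsa-miR-1", "G2", None),
                   ("hsa-miR-2", "G3", None)),
            organism_prefix="hsa",
        )
        sets = derive_gene_sets(mir, genes, table)
        assert sets.targets_of_dereg_mirs == {"G1", "G2"}
        assert sets.dereg_genes == {"G1", "G3"}
        assert sets.dereg_targets_of_dereg_mirs == {"G1"}
        assert sets.reference == {"G1", "G2", "G3"}

    def test_no_deregulated_mirnas_gives_empty_targets(self):
        mir = DeregulationSet(entity_class=MIRNA, entries={})
        genes = DeregulationSet(entity_class=GENE, entries={"G1": +1, "G2": -1})
        table = InteractionTable(pairs=(("hsa-miR-1", "G1", None),), organism_prefix="hsa")
        sets = derive_gene_sets(mir, genes, table)
        assert sets.targets_of_dereg_mirs == frozenset()
        assert sets.dereg_targets_of_dereg_mirs == frozenset()

    @pytest.mark.parametrize("seed", [41, 42, 43])
    def test_subset_structure_on_random_fixtures(self, seed):
        bundle = build_scenario(ScenarioSpec(seed=seed, dependence_strength=0.3))
        sets = derive_gene_sets(bundle.mir_dereg, bundle.gene_dereg, bundle.interactions)
        assert sets.dereg_targets_of_dereg_mirs <= sets.targets_of_dereg_mirs
        assert sets.dereg_targets_of_dereg_mirs <= sets.dereg_genes
        assert sets.targets_of_dereg_mirs | sets.dereg_genes <= sets.reference


class TestVennOverlap:
    def test_worked_example(self):
        universe = {f"G{i}" for i in range(6)}
        result = venn_overlap({"G1", "G2", "G3"}, {"G2", "G3", "G4"}, universe)
        assert (result.left, result.overlap, result.right) == (1, 2, 1)
        assert result.p_value == pytest.approx(0.5)

    def test_disjoint_sets(self):
        universe = {f"G{i}" for i in range(10)}
        result = venn_overlap({"G0"}, {"G1"}, universe)
        assert result.overlap == 0
        assert result.p_value == pytest.approx(1.0)

    def test_identical_sets_in_saturated_universe(self):
        genes = {"A", "B", "C"}
        result = venn_overlap(genes, genes, genes)
        assert result.overlap == 3
        assert result.p_value == pytest.approx(1.0)

    def test_sets_outside_universe_raise(self):
        with pytest.raises(ValueError, match="universe"):
            venn_overlap({"A"}, {"B"}, {"A"})

    @pytest.mark.parametrize("seed", [51, 52])
    def test_partition_identities_on_random_fixtures(self, seed):
        bundle = build_scenario(ScenarioSpec(seed=seed))
        sets = derive_gene_sets(bundle.mir_dereg, bundle.gene_dereg, bundle.interactions)
        result = venn_overlap(
            sets.dereg_genes, sets.targets_of_dereg_mirs, sets.reference
        )
        assert result.left + result.overlap == len(sets.targets_of_dereg_mirs)
        assert result.overlap + result.right == len(sets.dereg_genes)


def _result(category, p_adj):
    return OraResult(
        category=category, test_hits=1, test_size=2, ref_hits=2, ref_size=10,
        expected=0.4, direction=ENRICHED, p_raw=min(p_adj, 1.0), p_adj=p_adj,
    )


def _lists(patterns):
    """patterns: category -> set of analyses in which it is significant."""
    lists = {}
    for label in "ABC":
        lists[label] = [
            _result(cat, 0.01 if label in sig else 0.9)
            for cat, sig in sorted(patterns.items())
        ]
    return lists["A"], lists["B"], lists["C"]


class TestOverlapCodes:
    def test_b_and_c_only_codes_two(self):
        a, b, c = _lists({"dna-replication": {"B", "C"}, "filler": set()})
        table = overlap_codes(a, b, c)
        assert table.rows["dna-replication"] == (("b", "c"), 2)

    def test_all_three_codes_seven(self):
        a, b, c = _lists({"olfactory": {"A", "B", "C"}, "filler": set()})
        table = overlap_codes(a, b, c)
        assert table.rows["olfactory"] == (("a", "b", "c"), 7)

    def test_single_analysis_excluded(self):
        a, b, c = _lists({"lonely": {"A"}})
        assert overlap_codes(a, b, c).rows == {}

    def test_achievable_codes_are_exactly_1_2_4_7(self):
        patterns = {
            "ab": {"A", "B"},
            "bc": {"B", "C"},
            "ac": {"A", "C"},
            "abc": {"A", "B", "C"},
            "none": set(),
            "only-a": {"A"},
        }
        table = overlap_codes(*_lists(patterns))
        codes = {name: code for name, (_, code) in table.rows.items()}
        assert codes == {"ab": 1, "bc": 2, "ac": 4, "abc": 7}

    def test_mismatched_category_universes_raise(self):
        a, b, c = _lists({"x": set(), "y": set()})
        with pytest.raises(ValueError, match="different categories"):
            overlap_codes(a, b[:1], c)

    def test_raw_p_mode(self):
        a, b, c = _lists({"cat": set()})
        a = [_result("cat", 0.9)]
        # raw p significant, adjusted p not: visible only in raw mode
        a[0] = OraResult(
            category="cat", test_hits=1, test_size=2, ref_hits=2, ref_size=10,
            expected=0.4, direction=ENRICHED, p_raw=0.01, p_adj=0.5,
        )
        b = [a[0]]
        c = [_result("cat", 0.9)]
        assert overlap_codes(a, b, c).rows == {}
        assert overlap_codes(a, b, c, use_raw=True).rows["cat"] == (("a", "b"), 1)


class TestFamilyOra:
    def _setup(self):
        mir = DeregulationSet(
            entity_class=MIRNA,
            entries={"hsa-miR-1": +1, "hsa-miR-2": -1, "hsa-miR-3": +1},
        )
        universe = {f"hsa-mir-{i}" for i in range(1, 11)}
        families = FamilyDB(
            families={
                "contained": frozenset({"hsa-miR-1", "hsa-miR-2", "hsa-miR-3"}),
                "disjoint": frozenset({"hsa-mir-7", "hsa-mir-8", "hsa-mir-9"}),
            }
        )
        return mir, families, universe

    def test_wholly_contained_family_has_smallest_p(self):
        mir, families, universe = self._setup()
        results = family_ora(mir, families, universe)
        assert results[0].category == "contained"
        assert results[0].direction == ENRICHED
        assert results[0].test_hits == 3

    def test_disjoint_family_is_depleted(self):
        mir, families, universe = self._setup()
        by_name = {r.category: r for r in family_ora(mir, families, universe)}
        assert by_name["disjoint"].direction == DEPLETED
        assert by_name["disjoint"].test_hits == 0

    def test_planted_family_recovered_as_preselected(self):
        bundle = build_scenario(ScenarioSpec(seed=61))
        results = family_ora(
            bundle.mir_dereg, bundle.families, bundle.interactions.mirna_ids
        )
        assert results[0].category == bundle.truth["planted_family"]
        assert results[0].preselected
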