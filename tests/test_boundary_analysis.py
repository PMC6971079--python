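import numpy as np
import pytest
from hypothesis import given, strategies as st

from mitorder.boundary_analysis import (
    adjacency_set,
    breakpoint_distance,
    build_catalogue,
    classify_vs_ancestor,
    pairwise_shared_derived,
)
from mitorder.errors import (
    ArrangementTooShort,
    DuplicateTaxonId,
    GeneContentMismatch,
)
from mitorder.genome_model import arrangement_from_tokens

from .conftest import make_arrangement, random_arrangement_tokens
from .oracles import (
    naive_adjacency_keys,
    naive_breakpoints,
    naive_catalogue_totals,
    naive_pairwise_shared,
)


class TestAdjacencySet:
    def test_ancestral_fixture_boundary_counts(self, ancestor):
        assert len(adjacency_set(ancestor, "exclude")) == 37
        assert len(adjacency_set(ancestor, "include")) == 38

    def test_linear_arrangement_has_n_minus_1(self):
        a = arrangement_from_tokens("t", ["cox1", "nad1", "nad2", "nad3", "nad4"],
                                    topology="linear")
        assert len(adjacency_set(a, "exclude")) == 4

    def test_cr_exclusion_joins_flanking_genes(self):
        from mitorder.boundary_analysis import boundary_key
        from mitorder.genome_model import SignedGene

        a = arrangement_from_tokens("t", ["cox1", "CR", "nad2", "nad3"])
        keys = adjacency_set(a, "exclude")
        joined = boundary_key(
            SignedGene.from_token("cox1"), SignedGene.from_token("nad2")
        )
        assert joined in keys

    def test_too_short_after_cr_removal(self):
        a = arrangement_from_tokens("t", ["cox1", "CR"])
        with pytest.raises(ArrangementTooShort):
            adjacency_set(a, "exclude")

    def test_reflection_gives_identical_keys(self, ancestor):
        assert adjacency_set(ancestor) == adjacency_set(ancestor.reflected())


class TestClassification:
    def test_ancestor_vs_itself_all_ancestral(self, ancestor):
        tb = classify_vs_ancestor(ancestor, ancestor)
        assert (len(tb.ancestral), len(tb.derived)) == (37, 0)

    def test_partition_invariant_include_mode(self, ancestor, rng):
        tokens = random_arrangement_tokens(rng, 8)
        a = make_arrangement("t", tokens)
        tb = classify_vs_ancestor(a, ancestor, "include")
        assert tb.n_boundaries == len(adjacency_set(a, "include"))

    @given(k=st.integers(0, 37), reflect=st.booleans())
    def test_invariant_under_rotation_reflection(self, ancestor, k, reflect):
        a = ancestor.rotated(k)
        if reflect:
            a = a.reflected()
        tb = classify_vs_ancestor(a, ancestor)
        assert len(tb.derived) == 0 and len(tb.ancestral) == 37

    def test_single_gene_transposition_yields_3_derived(self):
        """Enumerate every clean single-gene move of a 10-gene circle."""
        genes = ["cox1", "nad1", "nad2", "nad3", "nad4", "nad5",
                 "cob", "atp6", "atp8", "rrnS"]
        anc = arrangement_from_tokens("anc", genes)
        n = len(genes)
        for i in range(n):
            for dest in range(1, n - 1):
                rest = genes[i + 1:] + genes[:i]
                moved = rest[:dest] + [genes[i]] + rest[dest:]
                tb = classify_vs_ancestor(make_arrangement("t", moved), anc)
                assert len(tb.derived) == 3, (i, dest)


class TestCatalogue:
    def test_identical_derived_taxa_share_everything(self, ancestor, rng):
        tokens = random_arrangement_tokens(rng, 9)
        a = make_arrangement("t1", tokens)
        b = make_arrangement("t2", tokens)
        cat = build_catalogue([a, b], ancestor)
        assert cat.unique_derived_keys == set()
        assert all(len(t) == 2 for t in cat.derived_taxa.values())

    def test_duplicate_circular_taxon_raises(self, ancestor):
        a = arrangement_from_tokens("t", ["cox1", "nad1", "nad2"])
        with pytest.raises(DuplicateTaxonId):
            build_catalogue([a, a], ancestor)

    def test_multipartite_linear_chromosomes_merge(self, ancestor):
        chr1 = arrangement_from_tokens(
            "sp", ["cox1", "nad1", "nad2", "nad3"], topology="linear")
        chr2 = arrangement_from_tokens(
            "sp", ["cob", "rrnS"], topology="linear")
        cat = build_catalogue([chr1, chr2], ancestor)
        tb = cat.per_taxon["sp"]
        # 3 boundaries from chr1 + 1 from chr2; no cross-chromosome adjacency
        assert tb.n_boundaries == 4

    def test_sharing_partition_is_disjoint(self, ancestor, rng):
        arrs = [
            make_arrangement(f"t{i}", random_arrangement_tokens(rng, 8))
            for i in range(5)
        ]
        cat = build_catalogue(arrs, ancestor)
        shared, unique = cat.shared_derived_keys, cat.unique_derived_keys
        assert shared | unique == set(cat.derived_taxa)
        assert shared & unique == set()


class TestPairwiseAndBreakpoints:
    def test_taxon_vs_ancestor_shares_nothing(self, ancestor, rng):
        a = make_arrangement("t", random_arrangement_tokens(rng, 10))
        assert pairwise_shared_derived(a, ancestor, ancestor) == 0

    def test_identity_and_reflection_distance_zero(self, ancestor):
        assert breakpoint_distance(ancestor, ancestor) == 0
        assert breakpoint_distance(ancestor, ancestor.reflected()) == 0

    def test_content_mismatch_reported(self):
        a = arrangement_from_tokens("a", ["cox1", "nad1", "nad2"])
        b = arrangement_from_tokens("b", ["cox1", "nad1", "cob"])
        with pytest.raises(GeneContentMismatch) as err:
            breakpoint_distance(a, b)
        assert err.value.only_a == {"nad2"} and err.value.only_b == {"cob"}

    def test_restrict_to_shared_removes_asymmetric_genes(self):
        a = arrangement_from_tokens("a", ["cox1", "nad1", "nad2"])
        b = arrangement_from_tokens("b", ["cox1", "nad1", "cob"])
        assert breakpoint_distance(a, b, restrict_to_shared=True) == 0

    def test_symmetry_with_equal_content(self, rng):
        for _ in range(20):
            tokens = random_arrangement_tokens(rng, 8)
            perm = list(tokens)
            rng.shuffle(perm)
            a, b = make_arrangement("a", tokens), make_arrangement("b", perm)
            assert breakpoint_distance(a, b) == breakpoint_distance(b, a)


class TestOracleEquivalence:
    """All counts must match an independent naive implementation exactly."""

    def test_adjacency_and_classification_match_oracle(self, ancestor, rng):
        anc_tokens = ancestor.tokens()
        for _ in range(100):
            tokens = random_arrangement_tokens(rng, with_cr=True)
            a = make_arrangement("t", tokens)
            for strand in (True, False):
                assert adjacency_set(a, "exclude", strand) == naive_adjacency_keys(
                    tokens, True, True, strand
                )
            tb = classify_vs_ancestor(a, ancestor)
            oracle_keys = naive_adjacency_keys(tokens)
            oracle_anc = naive_adjacency_keys(anc_tokens)
            assert tb.ancestral == oracle_keys & oracle_anc
            assert tb.derived == oracle_keys - oracle_anc

    def test_catalogue_totals_match_oracle(self, ancestor, rng):
        for _ in range(20):
            taxa = {
                f"t{i}": random_arrangement_tokens(rng, 10)
                for i in range(5)
            }
            arrs = [make_arrangement(t, toks) for t, toks in taxa.items()]
            cat = build_catalogue(arrs, ancestor)
            oracle = naive_catalogue_totals(taxa, ancestor.tokens())
            assert cat.total_derived_boundaries == oracle["total_derived"]
            assert len(cat.shared_derived_keys) == oracle["distinct_shared"]
            assert len(cat.unique_derived_keys) == oracle["distinct_unique"]

    def test_pairwise_and_breakpoints_match_oracle(self, ancestor, rng):
        for _ in range(40):
            ta = random_arrangement_tokens(rng, 9)
            tb_perm = list(ta)
            rng.shuffle(tb_perm)
            a, b = make_arrangement("a", ta), make_arrangement("b", tb_perm)
            assert pairwise_shared_derived(a, b, ancestor) == naive_pairwise_shared(
                ta, tb_perm, ancestor.tokens()
            )
            assert breakpoint_distance(a, b) == naive_breakpoints(ta, tb_perm)
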