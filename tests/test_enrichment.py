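import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rwrscreen.enrichment import (
    AnnotationCorpus,
    enrichment_vector,
    functional_similarity,
    go_overrepresentation,
    hypergeometric_association,
    max_function_score,
    namespace_counts,
    neighborhood_gene_set,
    _log_hypergeom_tail,
)
from rwrscreen.errors import ValidationError
from rwrscreen.network import WeightedNetwork


def exact_tail(overlap, universe, term, draw) -> Fraction:
    """Rational-arithmetic upper tail P(X >= overlap) for the hypergeometric."""
    total = Fraction(math.comb(universe, draw))
    acc = Fraction(0)
    for k in range(overlap, min(term, draw) + 1):
        acc += Fraction(math.comb(term, k) * math.comb(universe - term, draw - k))
    return acc / total


class TestNeighborhood:
    def test_path_center_includes_both_ends(self, path3):
        assert neighborhood_gene_set(path3, "b") == {"a", "b", "c"}

    def test_isolated_gene_is_its_own_neighborhood(self):
        net = WeightedNetwork([("a", "b", 10)], extra_nodes=["z"])
        assert neighborhood_gene_set(net, "z") == {"z"}

    def test_star_center_neighborhood_size(self, star4):
        assert len(neighborhood_gene_set(star4, "h")) == 4

    def test_absent_gene_is_an_error(self, path3):
        with pytest.raises(ValidationError):
            neighborhood_gene_set(path3, "nope")


class TestHypergeometricAssociation:
    def test_worked_example_universe10_term5_neighborhood4_overlap4(self):
        """P(X >= 4) = C(5,4)C(5,0)/C(10,4) = 5/210; -log10 p = log10(42)."""
        universe = [f"g{i}" for i in range(10)]
        value = hypergeometric_association(universe[:4], universe[:5], universe)
        assert value == pytest.approx(math.log10(42), abs=1e-9)

    def test_zero_overlap_gives_zero(self):
        universe = [f"g{i}" for i in range(10)]
        assert hypergeometric_association(universe[:4], universe[6:9], universe) == 0.0

    def test_term_equal_to_universe_gives_zero(self):
        universe = [f"g{i}" for i in range(8)]
        assert hypergeometric_association(universe[:3], universe, universe) == 0.0

    def test_empty_neighborhood_gives_zero_with_warning(self):
        universe = [f"g{i}" for i in range(5)]
        assert hypergeometric_association([], universe[:2], universe) == 0.0

    def test_log_space_tail_matches_rational_enumeration(self):
        """Exhaustive check of the log-gamma tail against exact fractions, N <= 12."""
        for universe in range(1, 13):
            for term in range(1, universe + 1):
                for draw in range(1, universe + 1):
                    lo = max(0, draw + term - universe)
                    for overlap in range(lo, min(term, draw) + 1):
                        expected = exact_tail(overlap, universe, term, draw)
                        got = math.exp(_log_hypergeom_tail(overlap, universe, term, draw))
                        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_neglog10_p_monotone_in_overlap(self):
        universe, term, draw = 40, 12, 9
        values = [-_log_hypergeom_tail(k, universe, term, draw) for k in range(0, draw + 1)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_subset_violation_is_an_error(self):
        with pytest.raises(ValidationError):
            hypergeometric_association(["x"], ["a"], ["a", "b"])


class TestEnrichmentVector:
    @pytest.fixture
    def corpus(self):
        return AnnotationCorpus(
            {"T1": ["a", "b"], "T2": ["c"], "T3": ["a", "c"]},
            {"T1": "BP", "T2": "CC", "T3": "MF"},
        )

    def test_vector_length_matches_corpus(self, path3, corpus):
        assert enrichment_vector(path3, "b", corpus).shape == (3,)

    def test_identical_neighborhoods_give_identical_vectors(self, corpus):
        # triangle: a and b share the identical neighborhood {a, b, c}
        net = WeightedNetwork([("a", "b", 10), ("a", "c", 10), ("b", "c", 10)])
        va = enrichment_vector(net, "a", corpus)
        vb = enrichment_vector(net, "b", corpus)
        assert (va == vb).all()

    def test_term_disjoint_from_neighborhood_gets_zero_entry(self, corpus):
        net = WeightedNetwork([("a", "b", 10), ("c", "d", 10)])
        v = enrichment_vector(net, "c", corpus)  # neighborhood {c, d}; T1 = {a, b}
        assert v[list(corpus.term_order).index("T1")] == 0.0


class TestFunctionalSimilarity:
    def test_self_similarity_is_one(self):
        v = np.array([1.0, 2.0, 0.5])
        assert functional_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert functional_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_scale_invariance(self):
        assert functional_similarity(np.array([2.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_zero_norm_convention(self):
        assert functional_similarity(np.zeros(3), np.ones(3)) == 0.0

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            functional_similarity(np.ones(2), np.ones(3))

    @given(
        v1=hnp.arrays(float, 5, elements=st.floats(0, 100)),
        v2=hnp.arrays(float, 5, elements=st.floats(0, 100)),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded_on_nonnegative_vectors(self, v1, v2):
        s = functional_similarity(v1, v2)
        assert s == functional_similarity(v2, v1)
        assert 0.0 <= s <= 1.0


class TestMaxFunctionScore:
    def test_takes_maximum_over_validated(self):
        vectors = {"c": np.array([1.0, 0.0]), "v1": np.array([0.5, 1.0]), "v2": np.array([1.0, 0.1])}
        mfs = max_function_score("c", ["v1", "v2"], vectors)
        assert mfs == pytest.approx(functional_similarity(vectors["c"], vectors["v2"]))

    def test_all_zero_candidate_vector_gives_zero(self):
        vectors = {"c": np.zeros(2), "v": np.ones(2)}
        assert max_function_score("c", ["v"], vectors) == 0.0

    def test_identical_vector_gives_one(self):
        vectors = {"c": np.array([0.3, 0.7]), "v": np.array([0.3, 0.7])}
        assert max_function_score("c", ["v"], vectors) == pytest.approx(1.0)

    def test_missing_vector_error_names_the_gene(self):
        with pytest.raises(ValidationError, match="v2"):
            max_function_score("c", ["v2"], {"c": np.ones(2)})


class TestGoOverrepresentation:
    @pytest.fixture
    def toy(self):
        universe = [f"g{i}" for i in range(12)]
        corpus = AnnotationCorpus(
            {
                "T1": universe[:3],
                "T2": universe[3:8],
                "T3": universe[0:6],
                "T4": universe[8:12],
                "T5": universe[2:5],
            },
            {"T1": "BP", "T2": "CC", "T3": "MF", "T4": "BP", "T5": "CC"},
        )
        return universe, corpus

    def test_exact_annotation_set_has_minimum_p(self, toy):
        """Querying T1's own gene set: T1's p is the smallest over the toy corpus."""
        universe, corpus = toy
        genes = corpus.genes_for("T1")
        expected = {
            term: float(exact_tail(len(genes & corpus.genes_for(term)), 12,
                                   len(corpus.genes_for(term)), len(genes)))
            for term in corpus.term_order
        }
        assert min(expected, key=expected.get) == "T1"
        result = go_overrepresentation(genes, corpus, universe, p_cutoff=1.0)
        assert result[0].term == "T1"
        for t in result:
            assert t.p_value == pytest.approx(expected[t.term], rel=1e-10)

    def test_cutoff_one_returns_all_terms_with_p_below_one(self, toy):
        universe, corpus = toy
        result = go_overrepresentation(universe[:4], corpus, universe, p_cutoff=1.0)
        assert {t.term for t in result} <= set(corpus.term_order)
        assert all(t.p_value < 1.0 for t in result)

    def test_disjoint_gene_set_yields_nothing_significant(self, toy):
        universe, corpus = toy
        extended = universe + ["h1", "h2"]
        corpus2 = AnnotationCorpus(
            {t: corpus.genes_for(t) for t in corpus.term_order},
            {t: corpus.namespace(t) for t in corpus.term_order},
        )
        assert go_overrepresentation(["h1", "h2"], corpus2, extended, p_cutoff=0.05) == []

    def test_empty_gene_set_is_an_error(self, toy):
        universe, corpus = toy
        with pytest.raises(ValidationError):
            go_overrepresentation([], corpus, universe)

    def test_namespace_counts_partition(self, toy):
        universe, corpus = toy
        result = go_overrepresentation(universe[:5], corpus, universe, p_cutoff=1.0)
        counts = namespace_counts(result)
        assert sum(counts.values()) == len(result)


class TestGmtRoundTrip:
    def test_corpus_roundtrips_through_gmt(self, tmp_path):
        corpus = AnnotationCorpus(
            {"T1": ["a", "b"], "T2": ["c"]},
            {"T1": "BP", "T2": "KEGG"},
            {"T1": "one", "T2": "two"},
        )
        path = tmp_path / "corpus.gmt"
        corpus.to_gmt(path)
        reloaded = AnnotationCorpus.from_gmt(path)
        assert reloaded.term_order == corpus.term_order
        for t in corpus.term_order:
            assert reloaded.genes_for(t) == corpus.genes_for(t)
            assert reloaded.namespace(t) == corpus.namespace(t)

    def test_bad_namespace_is_an_error(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tnonsense\ta\tb\n")
        with pytest.raises(ValidationError):
            AnnotationCorpus.from_gmt(path)

    def test_term_without_genes_is_an_error(self):
        with pytest.raises(ValidationError):
            AnnotationCorpus({"T1": []}, {"T1": "BP"})
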