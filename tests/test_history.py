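"""Gene-, term- and species-level historical statistics."""

import datetime

import numpy as np
import pytest

from gochron.annotations import AnnotationEdition, AnnotationRecord, propagate_edition
from gochron.errors import InsufficientDataError, TermLookupError
from gochron.history import (
    EditionSeries,
    annotation_rank_stability,
    gene_count_series,
    multifunctionality,
    multifunctionality_ranks,
    semantic_similarity_series,
    species_trends,
    term_gene_count_series,
)

from conftest import gid, make_edition

D = datetime.date


def make_series(per_edition, ontology, species="human"):
    """per_edition: list of {gene: [term, ...]} dicts, one per month."""
    editions = []
    for i, gene_terms in enumerate(per_edition):
        date = D(2005, 1, 1) + datetime.timedelta(days=28 * i)
        records = frozenset(
            AnnotationRecord(g, t, "IEA")
            for g, terms in gene_terms.items()
            for t in terms
        )
        ontology_dated = type(ontology)(date, dict(ontology.terms), ontology.edges)
        editions.append(propagate_edition(
            AnnotationEdition(species, date, records), ontology_dated))
    return EditionSeries(species, tuple(editions))


@pytest.fixture
def chain():
    return make_edition([(gid(3), gid(2)), (gid(2), gid(1))])


class TestGeneCountSeries:
    def test_direct_counts_and_absence(self, chain):
        series = make_series(
            [{"P1": [gid(1)]}, {"P1": [gid(1), gid(2)]}, {"P2": [gid(1)]}], chain
        )
        frame = gene_count_series(series, "P1", mode="direct")
        assert list(frame["count"]) == [1, 2, 0]

    def test_propagated_closure_size(self, chain):
        series = make_series([{"P1": [gid(3)]}] * 2, chain)
        frame = gene_count_series(series, "P1", mode="propagated")
        assert list(frame["count"]) == [3, 3]

    def test_species_mean_over_annotated_genes(self, chain):
        series = make_series([{"P1": [gid(1)], "P2": [gid(1), gid(2), gid(3)]}], chain)
        frame = gene_count_series(series, "P1", mode="direct")
        assert frame["species_mean"].iloc[0] == 2.0


class TestSemanticSimilarity:
    def test_reference_edition_is_one(self, chain):
        series = make_series([{"P1": [gid(1)]}, {"P1": [gid(1), gid(2)]}], chain)
        frame = semantic_similarity_series(series, "P1", series.dates[1])
        assert frame["jaccard"].iloc[1] == 1.0
        assert frame["jaccard"].iloc[0] == pytest.approx(0.5)

    def test_partial_overlap_third(self, chain):
        series = make_series(
            [{"P1": [gid(1), gid(2)]}, {"P1": [gid(2), gid(3)]}], chain
        )
        frame = semantic_similarity_series(series, "P1", series.dates[1])
        assert frame["jaccard"].iloc[0] == pytest.approx(1 / 3)

    def test_both_empty_is_one_disjoint_is_zero(self, chain):
        series = make_series([{"P9": [gid(1)]}, {"P1": [gid(1)]}], chain)
        frame = semantic_similarity_series(series, "P1", series.dates[1])
        assert frame["jaccard"].iloc[1] == 1.0
        series2 = make_series([{"P1": [gid(1)]}, {"P1": [gid(3)]}], chain)
        # direct sets {1} vs {3} are disjoint
        assert semantic_similarity_series(series2, "P1", series2.dates[1])["jaccard"].iloc[0] == 0.0


class TestMultifunctionality:
    def test_hand_computed_value(self):
        # 4 genes; P1 and P2 share one specific term: n_t=2, N=4 -> 1/(2*2)
        ontology = make_edition([(gid(2), gid(1))])
        series = make_series(
            [{"P1": [gid(2)], "P2": [gid(2)], "P3": [gid(1)], "P4": [gid(1)]}], ontology
        )
        edition = series.editions[0]
        # P3 carries only the universal root (n_t = N contributes 0)
        assert multifunctionality(edition, "P3") == 0.0
        assert multifunctionality(edition, "P1") == pytest.approx(1 / (2 * 2))

    def test_identical_term_sets_equal_scores_and_rank_range(self):
        ontology = make_edition([(gid(2), gid(1)), (gid(3), gid(1))])
        series = make_series(
            [{"P1": [gid(2)], "P2": [gid(2)], "P3": [gid(3)], "P4": [gid(1)]}], ontology
        )
        edition = series.editions[0]
        assert multifunctionality(edition, "P1") == multifunctionality(edition, "P2")
        ranks = multifunctionality_ranks(edition)
        assert set(ranks) == {"P1", "P2", "P3", "P4"}
        assert all(0.0 <= v <= 1.0 for v in ranks.values())

    def test_unannotated_gene_raises(self, chain):
        series = make_series([{"P1": [gid(1)]}], chain)
        with pytest.raises(TermLookupError):
            multifunctionality(series.editions[0], "P99")


class TestTermGeneCounts:
    def test_direct_vs_propagated_counts(self, chain):
        series = make_series(
            [{"P1": [gid(2)], "P2": [gid(2)], "P3": [gid(2)], "P4": [gid(3)], "P5": [gid(3)]}],
            chain,
        )
        assert term_gene_count_series(series, gid(2), mode="direct")["total"].iloc[0] == 3
        assert term_gene_count_series(series, gid(2), mode="propagated")["total"].iloc[0] == 5

    def test_evidence_breakdown_all_automatic(self, chain):
        series = make_series([{"P1": [gid(2)], "P2": [gid(2)]}], chain)
        frame = term_gene_count_series(series, gid(2), breakdown="by_evidence_category")
        assert frame["automatic"].iloc[0] == 2 and frame["curated"].iloc[0] == 0

    def test_absent_term_reports_zero(self, chain):
        series = make_series([{"P1": [gid(1)]}], chain)
        assert term_gene_count_series(series, gid(3))["total"].iloc[0] == 0


class TestSpeciesTrends:
    def test_hand_means_on_chain(self, chain):
        series = make_series([{"P1": [gid(1)], "P2": [gid(1), gid(2), gid(3)]}], chain)
        row = species_trends(series).iloc[0]
        assert row["annotated_genes"] == 2
        assert row["mean_direct_per_gene"] == 2.0
        # P1 propagates to {1}, P2 to {1,2,3}: mean inferred = 2.0
        assert row["mean_inferred_per_gene"] == 2.0
        assert row["mean_inferred_per_gene"] >= row["mean_direct_per_gene"]

    def test_empty_edition_row_of_zeros(self, chain):
        series = make_series([{}], chain)
        row = species_trends(series).iloc[0]
        assert row["annotated_genes"] == 0 and row["mean_direct_per_gene"] == 0.0

    def test_annotated_genes_matches_direct_keys(self, stable_history):
        _, _, _, series = stable_history
        frame = species_trends(series)
        for row, edition in zip(frame.itertuples(), series.editions):
            assert row.annotated_genes == len(edition.gene_to_direct)


class TestRankStability:
    def setup_series(self, counts_a, counts_b, chain):
        terms = [gid(1), gid(2), gid(3)]
        def expand(counts):
            return {f"P{i}": terms[:c] for i, c in enumerate(counts)}
        return make_series([expand(counts_a), expand(counts_b)], chain)

    def test_identical_is_one_reversed_is_minus_one(self, chain):
        series = self.setup_series([1, 2, 3], [1, 2, 3], chain)
        assert annotation_rank_stability(series, *series.dates) == pytest.approx(1.0)
        series = self.setup_series([1, 2, 3], [3, 2, 1], chain)
        assert annotation_rank_stability(series, *series.dates) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, chain):
        rng = np.random.default_rng(7)
        # 3 distinct count values over 50 genes: exercises tie handling
        a = rng.integers(1, 4, size=50)
        b = rng.integers(1, 4, size=50)
        series = self.setup_series(list(a), list(b), chain)
        observed = annotation_rank_stability(series, *series.dates)

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x), float)
            i = 0
            sorted_x = np.array(x)[order]
            while i < len(x):
                j = i
                while j < len(x) and sorted_x[j] == sorted_x[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert observed == pytest.approx(expected, abs=1e-12)

    def test_insufficient_shared_genes(self, chain):
        series = make_series([{"P1": [gid(1)]}, {"P1": [gid(1)]}], chain)
        with pytest.raises(InsufficientDataError):
            annotation_rank_stability(series, *series.dates)
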