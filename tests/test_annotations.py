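"""GAF parsing, accession harmonization, edition matching, propagation."""

import datetime
import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gochron.annotations import (
    AccessionMapping,
    AnnotationEdition,
    AnnotationRecord,
    harmonize,
    match_ontology,
    parse_gaf,
    parse_secondary_mapping,
    propagate_edition,
)
from gochron.errors import AmbiguousMappingError, GafParseError, MatchingError
from gochron.ontology import Term

from conftest import gid, make_edition

D = datetime.date
DATE = D(2005, 3, 1)


def gaf_line(acc="P10001", qualifier="", term=gid(3), evidence="IEA", aspect="P", ref="PMID:1"):
    fields = ["UniProtKB", acc, acc, qualifier, term, ref, evidence, "", aspect,
              "", "", "protein", "taxon:9606", "20050301", "UniProt", "", ""]
    return "\t".join(fields)


def parse(lines):
    return parse_gaf(io.StringIO("!gaf-version: 2.2\n" + "\n".join(lines) + "\n"), "human", DATE)


class TestParseGaf:
    def test_columns_transcribed(self):
        edition = parse([gaf_line(evidence="IEA")])
        (record,) = edition.records
        assert (record.accession, record.term_id, record.evidence_code) == ("P10001", gid(3), "IEA")
        assert record.aspect == "biological_process"

    def test_not_qualifier_excluded(self):
        edition = parse([gaf_line(qualifier="NOT|involved_in"), gaf_line(acc="P10002")])
        assert {r.accession for r in edition.records} == {"P10002"}

    def test_duplicate_triples_collapse(self):
        edition = parse([gaf_line(ref="PMID:1"), gaf_line(ref="PMID:2")])
        assert len(edition.records) == 1

    def test_wrong_column_count_reports_line(self):
        with pytest.raises(GafParseError, match="line 2"):
            parse(["a\tb\tc"])

    def test_empty_file_is_empty_edition(self):
        edition = parse_gaf(io.StringIO("!comment only\n"), "human", DATE)
        assert edition.records == frozenset()


class TestSecondaryMapping:
    def test_merge_two_secondaries_one_primary(self):
        mapping = parse_secondary_mapping(io.StringIO("P1 P9\nP2 P9\n"))
        assert mapping.resolve("P1") == "P9" and mapping.resolve("P2") == "P9"

    def test_chain_collapses_to_terminal(self):
        mapping = parse_secondary_mapping(io.StringIO("P1 P2\nP2 P3\n"))
        assert mapping.resolve("P1") == "P3"

    def test_ambiguous_secondary_raises(self):
        with pytest.raises(AmbiguousMappingError, match="P1"):
            parse_secondary_mapping(io.StringIO("P1 P2\nP1 P3\n"))

    def test_header_lines_tolerated(self):
        text = "Secondary AC   Primary AC\n============   ==========\nP1 P9\n"
        assert parse_secondary_mapping(io.StringIO(text)).resolve("P1") == "P9"


class TestHarmonize:
    def mapping(self, **kw):
        return AccessionMapping(secondary_to_primary=dict(**kw))

    def edition(self, *accs):
        return AnnotationEdition(
            "human", DATE,
            frozenset(AnnotationRecord(a, gid(3), "IEA") for a in accs),
        )

    def test_substitution(self):
        out = harmonize(self.edition("P1"), self.mapping(P1="P9"))
        assert {r.accession for r in out.records} == {"P9"}

    def test_merge_collapses_duplicates(self):
        out = harmonize(self.edition("P1", "P9"), self.mapping(P1="P9"))
        assert len(out.records) == 1

    def test_empty_mapping_identity_and_idempotence(self):
        edition = self.edition("P1", "P2")
        assert harmonize(edition, self.mapping()) == edition
        mapping = self.mapping(P1="P9")
        once = harmonize(edition, mapping)
        assert harmonize(once, mapping) == once

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from([f"P{i}" for i in range(12)]), min_size=1, max_size=8),
           st.dictionaries(st.sampled_from([f"P{i}" for i in range(6)]),
                           st.sampled_from([f"Q{i}" for i in range(4)]), max_size=5))
    def test_gene_coverage_never_increases(self, accs, raw_map):
        edition = self.edition(*accs)
        mapping = AccessionMapping(secondary_to_primary=raw_map)
        out = harmonize(edition, mapping)
        assert len({r.accession for r in out.records}) <= len(accs)
        assert harmonize(out, mapping) == out


class TestMatchOntology:
    def test_closest_before(self):
        assert match_ontology(D(2005, 3, 10), [D(2005, 3, 1), D(2005, 4, 1)]) == D(2005, 3, 1)

    def test_equal_date_matches_itself(self):
        assert match_ontology(D(2005, 3, 1), [D(2005, 3, 1), D(2005, 4, 1)]) == D(2005, 3, 1)

    def test_no_earlier_edition_raises(self):
        with pytest.raises(MatchingError):
            match_ontology(D(2001, 1, 15), [D(2001, 2, 1)])


class TestPropagateEdition:
    def test_chain_closure(self, chain_edition):
        edition = AnnotationEdition(
            "human", DATE, frozenset({AnnotationRecord("P1", gid(3), "IDA")})
        )
        prop = propagate_edition(edition, chain_edition)
        assert prop.gene_to_direct["P1"] == frozenset({gid(3)})
        assert prop.gene_to_propagated["P1"] == frozenset({gid(3), gid(2), gid(1)})

    def test_gene_with_only_obsolete_term_dropped(self):
        ontology = make_edition([(gid(2), gid(1))])
        dead = Term(gid(9), "dead", "biological_process", obsolete=True)
        ontology = type(ontology)(
            ontology.edition_date, {**ontology.terms, gid(9): dead}, ontology.edges
        )
        edition = AnnotationEdition(
            "human", DATE, frozenset({AnnotationRecord("P1", gid(9), "IEA")})
        )
        prop = propagate_edition(edition, ontology)
        assert "P1" not in prop.gene_to_propagated

    def test_diamond_union_and_alt_id(self, diamond_edition):
        edition = AnnotationEdition(
            "human", DATE,
            frozenset({AnnotationRecord("P1", gid(2), "IEA"),
                       AnnotationRecord("P1", gid(3), "IEA")}),
        )
        prop = propagate_edition(edition, diamond_edition)
        assert prop.gene_to_propagated["P1"] == frozenset({gid(2), gid(3), gid(1)})

    def test_propagated_at_least_direct(self, diamond_edition):
        records = frozenset(
            AnnotationRecord(f"P{i}", t, "IEA")
            for i, t in enumerate([gid(4), gid(2), gid(1)])
        )
        prop = propagate_edition(AnnotationEdition("human", DATE, records), diamond_edition)
        for gene, direct in prop.gene_to_direct.items():
            assert direct <= prop.gene_to_propagated[gene]
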