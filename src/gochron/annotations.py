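"""Dated GOA editions: GAF parsing, accession harmonization, propagation.

Each species has a sequence of dated annotation editions read from GAF
2.x files. Gene products are identified by UniProt-style accessions;
merges and splits over the years leave secondary accessions behind, so a
secondary->primary mapping table is applied to harmonize identifiers
across editions. An annotation edition is matched to the ontology
release closest *before* its own date, and direct annotations are then
propagated up the DAG per the true-path rule.
"""

from __future__ import annotations

import bisect
import datetime
import gzip
import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import IO, Iterable, Mapping, Sequence

from gochron.errors import AmbiguousMappingError, GafParseError, MatchingError
from gochron.ontology import ASPECT_CODES, ASPECTS, OntologyEdition, propagate_terms

logger = logging.getLogger(__name__)

#: Evidence categories used in term-history breakdowns: IEA annotations are
#: assigned electronically without curator review; everything else has seen
#: a curator.
AUTOMATIC_EVIDENCE = frozenset({"IEA"})


def evidence_category(evidence_code: str) -> str:
    return "Automatic" if evidence_code in AUTOMATIC_EVIDENCE else "Curated"


@dataclass(frozen=True)
class AnnotationRecord:
    """One direct gene-product -> term association with its evidence."""

    accession: str
    term_id: str
    evidence_code: str
    qualifier: str = ""
    aspect: str = "biological_process"

    def __post_init__(self):
        if not (self.evidence_code.isalpha() and self.evidence_code.isupper()):
            raise ValueError(f"bad evidence code {self.evidence_code!r}")
        if self.aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {self.aspect!r}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.accession, self.term_id, self.evidence_code)


@dataclass(frozen=True)
class AnnotationEdition:
    """One dated snapshot of a species' direct annotations."""

    species: str
    edition_date: datetime.date
    records: frozenset[AnnotationRecord]

    def __post_init__(self):
        triples = {r.triple for r in self.records}
        if len(triples) != len(self.records):
            raise ValueError("duplicate (accession, term, evidence) triples")


@dataclass(frozen=True)
class AccessionMapping:
    """Secondary -> primary accession map with chains collapsed."""

    secondary_to_primary: Mapping[str, str]

    def __post_init__(self):
        for sec, prim in self.secondary_to_primary.items():
            if sec == prim:
                raise ValueError(f"accession {sec} maps to itself")
            if prim in self.secondary_to_primary:
                raise ValueError(f"primary {prim} also appears as a secondary")

    def resolve(self, accession: str) -> str:
        return self.secondary_to_primary.get(accession, accession)


def parse_gaf(
    stream: IO[str] | Iterable[str],
    species: str,
    edition_date: datetime.date,
) -> AnnotationEdition:
    """Parse GAF 2.x text into an :class:`AnnotationEdition`.

    Keeps column 2 (accession), 5 (GO id), 7 (evidence), 4 (qualifier) and
    9 (aspect). Records whose qualifier contains ``NOT`` are excluded; rows
    duplicating an (accession, term, evidence) triple collapse to one.
    """
    records: dict[tuple[str, str, str], AnnotationRecord] = {}
    excluded_not = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 15:
            raise GafParseError(
                f"expected >= 15 tab-separated columns, got {len(fields)}", line=lineno
            )
        qualifier = fields[3]
        if "NOT" in qualifier.split("|"):
            excluded_not += 1
            continue
        aspect = ASPECT_CODES.get(fields[8])
        if aspect is None:
            raise GafParseError(f"unknown aspect code {fields[8]!r}", line=lineno)
        try:
            record = AnnotationRecord(
                accession=fields[1],
                term_id=fields[4],
                evidence_code=fields[6],
                qualifier=qualifier,
                aspect=aspect,
            )
        except ValueError as exc:
            raise GafParseError(str(exc), line=lineno) from exc
        records.setdefault(record.triple, record)
    if excluded_not:
        logger.info("parse_gaf(%s, %s): excluded %d NOT-qualified records",
                    species, edition_date, excluded_not)
    return AnnotationEdition(
        species=species, edition_date=edition_date, records=frozenset(records.values())
    )


def read_gaf(path, species: str, edition_date: datetime.date) -> AnnotationEdition:
    """Open a (possibly gzipped) GAF file and parse it."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        return parse_gaf(handle, species, edition_date)


def parse_secondary_mapping(stream: IO[str] | Iterable[str]) -> AccessionMapping:
    """Parse two-column (secondary, primary) text into an AccessionMapping.

    Header or rule lines (anything without exactly two whitespace-separated
    tokens, or with non-accession punctuation) are tolerated and skipped.
    Chains (A->B, B->C) are collapsed to the terminal primary.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        tokens = line.split()
        if len(tokens) != 2 or any(not t.replace("-", "").isalnum() for t in tokens):
            continue
        sec, prim = tokens
        if sec == prim:
            continue
        if sec in raw and raw[sec] != prim:
            raise AmbiguousMappingError(
                f"secondary accession {sec} maps to both {raw[sec]} and {prim}"
            )
        raw[sec] = prim

    def terminal(acc: str) -> str:
        seen = {acc}
        while acc in raw:
            acc = raw[acc]
            if acc in seen:
                raise AmbiguousMappingError(f"cyclic accession mapping involving {acc}")
            seen.add(acc)
        return acc

    collapsed = {sec: terminal(sec) for sec in raw}
    return AccessionMapping(secondary_to_primary=collapsed)


def harmonize(edition: AnnotationEdition, mapping: AccessionMapping) -> AnnotationEdition:
    """Replace secondary accessions with their primaries; collapse merges.

    Accessions absent from the mapping pass through unchanged (most are
    already primary); the number rewritten is logged.
    """
    out: dict[tuple[str, str, str], AnnotationRecord] = {}
    rewritten = 0
    for record in sorted(edition.records, key=lambda r: r.triple):
        primary = mapping.resolve(record.accession)
        if primary != record.accession:
            rewritten += 1
            record = AnnotationRecord(
                accession=primary,
                term_id=record.term_id,
                evidence_code=record.evidence_code,
                qualifier=record.qualifier,
                aspect=record.aspect,
            )
        out.setdefault(record.triple, record)
    if rewritten:
        logger.info("harmonize(%s, %s): rewrote %d secondary accessions",
                    edition.species, edition.edition_date, rewritten)
    return AnnotationEdition(
        species=edition.species,
        edition_date=edition.edition_date,
        records=frozenset(out.values()),
    )


def match_ontology(
    annotation_date: datetime.date, ontology_dates: Sequence[datetime.date]
) -> datetime.date:
    """Latest ontology release date at or before the annotation date."""
    if not ontology_dates:
        raise MatchingError("no ontology dates available")
    dates = sorted(ontology_dates)
    idx = bisect.bisect_right(dates, annotation_date)
    if idx == 0:
        raise MatchingError(
            f"no ontology edition at or before {annotation_date.isoformat()}"
        )
    return dates[idx - 1]


@dataclass(frozen=True)
class PropagatedEdition:
    """An annotation edition joined to its ontology with inference materialized."""

    annotation_edition: AnnotationEdition
    ontology: OntologyEdition = field(compare=False)
    gene_to_direct: Mapping[str, frozenset[str]]
    gene_to_propagated: Mapping[str, frozenset[str]]

    @property
    def edition_date(self) -> datetime.date:
        return self.annotation_edition.edition_date

    @property
    def ontology_date(self) -> datetime.date:
        return self.ontology.edition_date

    @property
    def species(self) -> str:
        return self.annotation_edition.species

    @cached_property
    def direct_records(self) -> Mapping[str, tuple[AnnotationRecord, ...]]:
        """Resolved direct records per gene (obsolete/unknown terms dropped)."""
        per_gene: dict[str, list[AnnotationRecord]] = {}
        for record in self.annotation_edition.records:
            resolved = self.ontology.resolve(record.term_id)
            if resolved is None or self.ontology.terms[resolved].obsolete:
                continue
            if resolved != record.term_id:
                record = AnnotationRecord(record.accession, resolved,
                                          record.evidence_code, record.qualifier,
                                          record.aspect)
            per_gene.setdefault(record.accession, []).append(record)
        return {g: tuple(sorted(rs, key=lambda r: r.triple)) for g, rs in per_gene.items()}

    def term_to_genes(self, mode: str = "propagated") -> Mapping[str, frozenset[str]]:
        """Invert the gene->terms map; cached per mode."""
        cache = self.__dict__.setdefault("_term_index", {})
        if mode not in cache:
            source = self.gene_to_propagated if mode == "propagated" else self.gene_to_direct
            index: dict[str, set[str]] = {}
            for gene, terms in source.items():
                for term in terms:
                    index.setdefault(term, set()).add(gene)
            cache[mode] = {t: frozenset(g) for t, g in index.items()}
        return cache[mode]


def propagate_edition(
    edition: AnnotationEdition, ontology: OntologyEdition
) -> PropagatedEdition:
    """Materialize true-path-rule propagated annotations for one edition.

    Direct annotations to terms unknown to (or obsolete in) the matched
    ontology edition are dropped and counted in the log; alt_ids resolve
    to their primary term first.
    """
    direct: dict[str, set[str]] = {}
    dropped = 0
    for record in edition.records:
        resolved = ontology.resolve(record.term_id)
        if resolved is None or ontology.terms[resolved].obsolete:
            dropped += 1
            continue
        direct.setdefault(record.accession, set()).add(resolved)
    if dropped:
        logger.info("propagate_edition(%s, %s): dropped %d records to obsolete/unknown terms",
                    edition.species, edition.edition_date, dropped)
    gene_to_direct = {g: frozenset(ts) for g, ts in direct.items() if ts}
    gene_to_propagated = {
        g: frozenset(propagate_terms(ts, ontology)) for g, ts in gene_to_direct.items()
    }
    return PropagatedEdition(
        annotation_edition=edition,
        ontology=ontology,
        gene_to_direct=gene_to_direct,
        gene_to_propagated=gene_to_propagated,
    )
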