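"""Plain-text serialization: OBO and GAF writers, GMT and date tables.

Writers emit deterministic, sorted output so that identical in-memory
editions always serialize to identical bytes; the writers and the
parsers in :mod:`gochron.ontology` / :mod:`gochron.annotations` round-trip.
"""

from __future__ import annotations

import datetime
from typing import IO, Iterable, Sequence

from gochron.annotations import AnnotationEdition
from gochron.errors import GochronError
from gochron.ontology import IS_A, ASPECT_TO_CODE, OntologyEdition
from gochron.stability import DatedHitList


def write_obo(edition: OntologyEdition, stream: IO[str]) -> None:
    """Serialize one ontology edition as OBO 1.2 text."""
    stream.write("format-version: 1.2\n")
    stream.write(f"date: {edition.edition_date.isoformat()}\n\n")
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in edition.edges:
        by_child.setdefault(child, []).append((parent, relation))
    for term_id in sorted(edition.terms):
        term = edition.terms[term_id]
        stream.write("[Term]\n")
        stream.write(f"id: {term.term_id}\n")
        stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.aspect}\n")
        for alt in sorted(term.alt_ids):
            stream.write(f"alt_id: {alt}\n")
        for parent, relation in sorted(by_child.get(term_id, [])):
            if relation == IS_A:
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: part_of {parent}\n")
        if term.obsolete:
            stream.write("is_obsolete: true\n")
        stream.write("\n")


def write_gaf(edition: AnnotationEdition, stream: IO[str]) -> None:
    """Serialize one annotation edition as 17-column GAF 2.2 text."""
    stream.write("!gaf-version: 2.2\n")
    stream.write(f"!date: {edition.edition_date.isoformat()}\n")
    stamp = edition.edition_date.strftime("%Y%m%d")
    for record in sorted(edition.records, key=lambda r: r.triple):
        fields = [
            "UniProtKB",
            record.accession,
            record.accession,
            record.qualifier,
            record.term_id,
            "GO_REF:0000001",
            record.evidence_code,
            "",
            ASPECT_TO_CODE[record.aspect],
            "",
            "",
            "protein",
            "taxon:32644",
            stamp,
            "gochron",
            "",
            "",
        ]
        stream.write("\t".join(fields) + "\n")


def write_gene_term_table(
    gene_to_terms: dict[str, frozenset[str]], stream: IO[str], flag: str | None = None
) -> None:
    """Tab-separated gene -> term list export for generic enrichment tools."""
    for gene in sorted(gene_to_terms):
        terms = "|".join(sorted(gene_to_terms[gene]))
        row = [gene, terms] if flag is None else [gene, terms, flag]
        stream.write("\t".join(row) + "\n")


def write_gmt(hit_lists: Iterable[DatedHitList], stream: IO[str]) -> None:
    for hit_list in hit_lists:
        description = (
            hit_list.publication_date.isoformat() if hit_list.publication_date else "NA"
        )
        stream.write("\t".join([hit_list.name, description, *sorted(hit_list.genes)]) + "\n")


def read_gmt(stream: IO[str] | Iterable[str]) -> list[DatedHitList]:
    """Read GMT gene sets; a date-shaped description becomes the publication date."""
    out = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GochronError(f"GMT line {lineno}: expected name, description, >=1 gene")
        date = _maybe_date(fields[1])
        out.append(DatedHitList(name=fields[0], genes=frozenset(fields[2:]), publication_date=date))
    return out


def read_hitlist(stream: IO[str] | Iterable[str], name: str = "hitlist") -> DatedHitList:
    """One accession per line; blank lines and '#' comments ignored."""
    genes = {line.strip() for line in stream if line.strip() and not line.startswith("#")}
    return DatedHitList(name=name, genes=frozenset(genes))


def write_dates_table(hit_lists: Iterable[DatedHitList], stream: IO[str]) -> None:
    for hit_list in hit_lists:
        if hit_list.publication_date is not None:
            stream.write(f"{hit_list.name}\t{hit_list.publication_date.isoformat()}\n")


def read_dates_table(stream: IO[str] | Iterable[str]) -> dict[str, datetime.date]:
    dates = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise GochronError(f"dates table line {lineno}: expected 'name<TAB>date'")
        dates[fields[0]] = datetime.date.fromisoformat(fields[1])
    return dates


def apply_dates(
    hit_lists: Sequence[DatedHitList], dates: dict[str, datetime.date]
) -> list[DatedHitList]:
    """Attach publication dates from a name->date table (existing dates win)."""
    out = []
    for hit_list in hit_lists:
        date = hit_list.publication_date or dates.get(hit_list.name)
        out.append(DatedHitList(hit_list.name, hit_list.genes, date))
    return out


def _maybe_date(text: str) -> datetime.date | None:
    try:
        return datetime.date.fromisoformat(text)
    except ValueError:
        return None
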