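"""Dated editions of the GO DAG.

One OBO file per release date is parsed into an :class:`OntologyEdition`:
terms (including obsolete ones, flagged) plus typed child->parent edges
restricted to ``is_a`` and ``part_of``. Edges that cross the three GO
aspects, use any other relationship type, or touch an obsolete term are
discarded at parse time, so every retained edge supports the true-path
rule. Ancestor queries and reflexive-transitive closure over a term set
are the primitives annotation propagation is built on.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import IO, Iterable, Mapping

import networkx as nx

from gochron.errors import OboParseError, OntologyStructureError, TermLookupError

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

ASPECTS = ("biological_process", "molecular_function", "cellular_component")

#: GAF single-letter aspect codes <-> OBO namespace names.
ASPECT_CODES = {"P": "biological_process", "F": "molecular_function", "C": "cellular_component"}
ASPECT_TO_CODE = {v: k for k, v in ASPECT_CODES.items()}

IS_A = "IS_A"
PART_OF = "PART_OF"


@dataclass(frozen=True)
class Term:
    """One GO term as declared in a single edition."""

    term_id: str
    name: str
    aspect: str
    obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if not GO_ID_PATTERN.match(self.term_id):
            raise ValueError(f"not a GO accession: {self.term_id!r}")
        if self.aspect not in ASPECTS:
            raise ValueError(f"unknown aspect: {self.aspect!r}")
        if self.term_id in self.alt_ids:
            raise ValueError(f"{self.term_id} lists itself as an alt_id")


@dataclass(frozen=True)
class OntologyEdition:
    """One dated snapshot of the ontology: terms plus typed edges.

    ``edges`` holds ``(child, parent, relation)`` triples with relation in
    {IS_A, PART_OF}; following edges child->parent ascends toward roots.
    """

    edition_date: datetime.date
    terms: Mapping[str, Term]
    edges: frozenset[tuple[str, str, str]]
    _alt_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for child, parent, rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyStructureError(
                    f"edge ({child} -> {parent}) references an undeclared term"
                )
            if rel not in (IS_A, PART_OF):
                raise OntologyStructureError(f"unknown relation {rel!r}")
            if self.terms[child].obsolete:
                raise OntologyStructureError(f"obsolete term {child} has an outgoing edge")
        graph = nx.DiGraph()
        graph.add_nodes_from(t for t, term in self.terms.items() if not term.obsolete)
        graph.add_edges_from((c, p) for c, p, _ in self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            member = next(iter(nx.find_cycle(graph)))[0]
            raise OntologyStructureError(f"cycle detected involving {member}")
        object.__setattr__(self, "_graph", graph)
        alt = {}
        for term in self.terms.values():
            for alt_id in term.alt_ids:
                if alt_id in alt and alt[alt_id] != term.term_id:  # pragma: no cover
                    logger.warning("alt_id %s claimed by multiple terms", alt_id)
                    continue
                alt[alt_id] = term.term_id
        object.__setattr__(self, "_alt_index", alt)

    # -- lookups ---------------------------------------------------------

    def resolve(self, term_id: str) -> str | None:
        """Resolve a possibly-secondary accession to the primary term id.

        Returns None when the id is unknown in this edition.
        """
        if term_id in self.terms:
            return term_id
        return self._alt_index.get(term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @cached_property
    def _ancestor_cache(self) -> dict[str, frozenset[str]]:
        graph = self._graph
        cache: dict[str, frozenset[str]] = {}
        for node in nx.topological_sort(graph.reverse(copy=False)):
            acc: set[str] = set()
            for parent in graph.successors(node):
                acc.add(parent)
                acc |= cache[parent]
            cache[node] = frozenset(acc)
        return cache


def parse_obo(stream: IO[str] | Iterable[str], edition_date: datetime.date) -> OntologyEdition:
    """Parse OBO 1.2 text into a validated :class:`OntologyEdition`.

    Only ``is_a:`` and ``relationship: part_of`` lines become edges; all
    other relationship types are dropped, as are edges crossing aspects
    or touching obsolete terms. An edge to a term never declared in the
    file is a structural error, as is any cycle.
    """
    default_namespace = None
    stanzas: list[dict] = []
    current: dict | None = None
    in_term_stanza = False

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            in_term_stanza = line == "[Term]"
            current = {"lineno": lineno, "is_a": [], "part_of": [], "alt_ids": []} if in_term_stanza else None
            if current is not None:
                stanzas.append(current)
            continue
        if ":" not in line:
            raise OboParseError(f"expected 'tag: value', got {line!r}", line=lineno)
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.split("!")[0].strip()  # trailing comments
        if current is None or not in_term_stanza:
            if tag == "default-namespace":
                default_namespace = value
            continue
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "namespace":
            current["namespace"] = value
        elif tag == "alt_id":
            current["alt_ids"].append(value)
        elif tag == "is_a":
            current["is_a"].append((value, lineno))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"malformed relationship line: {value!r}", line=lineno)
            if parts[0] == "part_of":
                current["part_of"].append((parts[1], lineno))
            # other relationship types (regulates, ...) are discarded
        elif tag == "is_obsolete":
            current["obsolete"] = value.lower() == "true"

    terms: dict[str, Term] = {}
    for stanza in stanzas:
        if "id" not in stanza:
            raise OboParseError("[Term] stanza without an id", line=stanza["lineno"])
        namespace = stanza.get("namespace", default_namespace)
        if namespace is None:
            raise OboParseError(
                f"term {stanza['id']} has no namespace and the file declares no default",
                line=stanza["lineno"],
            )
        try:
            term = Term(
                term_id=stanza["id"],
                name=stanza.get("name", ""),
                aspect=namespace,
                obsolete=stanza.get("obsolete", False),
                alt_ids=frozenset(stanza["alt_ids"]),
            )
        except ValueError as exc:
            raise OboParseError(str(exc), line=stanza["lineno"]) from exc
        terms[term.term_id] = term

    edges: set[tuple[str, str, str]] = set()
    dropped_cross_aspect = 0
    dropped_obsolete = 0
    for stanza in stanzas:
        child = stanza["id"]
        for relation, pairs in ((IS_A, stanza["is_a"]), (PART_OF, stanza["part_of"])):
            for parent, lineno in pairs:
                if parent not in terms:
                    raise OntologyStructureError(
                        f"line {lineno}: edge from {child} to undeclared term {parent}"
                    )
                if terms[child].obsolete or terms[parent].obsolete:
                    dropped_obsolete += 1
                    continue
                if terms[child].aspect != terms[parent].aspect:
                    dropped_cross_aspect += 1
                    continue
                edges.add((child, parent, relation))
    if dropped_cross_aspect or dropped_obsolete:
        logger.info(
            "parse_obo(%s): dropped %d cross-aspect and %d obsolete-endpoint edges",
            edition_date, dropped_cross_aspect, dropped_obsolete,
        )
    return OntologyEdition(edition_date=edition_date, terms=terms, edges=frozenset(edges))


def ancestors(edition: OntologyEdition, term_id: str) -> set[str]:
    """All terms reachable from ``term_id`` via IS_A/PART_OF, excluding itself."""
    if term_id not in edition.terms:
        raise TermLookupError(f"unknown term {term_id}")
    if edition.terms[term_id].obsolete:
        raise TermLookupError(f"term {term_id} is obsolete in this edition")
    return set(edition._ancestor_cache[term_id])


def propagate_terms(term_ids: Iterable[str], edition: OntologyEdition) -> set[str]:
    """Reflexive transitive closure of a term set under IS_A/PART_OF ancestry."""
    closed: set[str] = set()
    for term_id in term_ids:
        if term_id not in edition.terms:
            raise TermLookupError(f"unknown term {term_id}")
        closed.add(term_id)
        closed |= edition._ancestor_cache.get(term_id, frozenset())
    return closed
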