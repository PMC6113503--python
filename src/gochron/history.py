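"""Historical statistics over a series of propagated annotation editions.

These are the quantities a curator or enrichment user inspects to judge
how a gene's or term's annotation record has evolved: per-gene direct and
propagated term counts with the species mean, the Jaccard semantic
similarity of a gene's annotations to a reference edition, gene
multifunctionality, per-term gene counts (optionally split into
automatic/IEA vs curated evidence), species-wide trend rows, and the
rank stability of per-gene annotation counts between two dates.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gochron.annotations import PropagatedEdition, evidence_category
from gochron.errors import InsufficientDataError, TermLookupError
from gochron.ontology import propagate_terms


@dataclass(frozen=True)
class EditionSeries:
    """Date-ordered sequence of propagated editions for one species."""

    species: str
    editions: tuple[PropagatedEdition, ...]

    def __post_init__(self):
        dates = [e.edition_date for e in self.editions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("edition dates must be strictly increasing")

    @property
    def dates(self) -> list[datetime.date]:
        return [e.edition_date for e in self.editions]

    def at(self, date: datetime.date) -> PropagatedEdition:
        for edition in self.editions:
            if edition.edition_date == date:
                return edition
        raise TermLookupError(f"no edition dated {date.isoformat()}")


def _gene_sets(edition: PropagatedEdition, mode: str):
    if mode not in ("direct", "propagated"):
        raise ValueError(f"mode must be 'direct' or 'propagated', got {mode!r}")
    return edition.gene_to_direct if mode == "direct" else edition.gene_to_propagated


def gene_count_series(
    series: EditionSeries, accession: str, mode: str = "direct"
) -> pd.DataFrame:
    """Per-edition term count for one gene, with the species mean overlaid.

    Genes absent from an edition count 0; the species mean is taken over
    genes with at least one direct annotation at that date.
    """
    rows = []
    for edition in series.editions:
        sets = _gene_sets(edition, mode)
        mean = float(np.mean([len(s) for s in sets.values()])) if sets else 0.0
        rows.append(
            {
                "date": edition.edition_date,
                "count": len(sets.get(accession, ())),
                "species_mean": mean,
            }
        )
    return pd.DataFrame(rows)


def semantic_similarity_series(
    series: EditionSeries,
    accession: str,
    reference_date: datetime.date,
    mode: str = "direct",
) -> pd.DataFrame:
    """Jaccard index of the gene's term set at each edition vs the reference.

    Direct annotations are the default: curation churn is visible there,
    whereas propagated sets are buffered by shared ancestors. Two empty
    sets have similarity 1 (an unannotated gene has not changed).
    """
    reference = _gene_sets(series.at(reference_date), mode).get(accession, frozenset())
    rows = []
    for edition in series.editions:
        current = _gene_sets(edition, mode).get(accession, frozenset())
        union = len(current | reference)
        value = 1.0 if union == 0 else len(current & reference) / union
        rows.append({"date": edition.edition_date, "jaccard": value})
    return pd.DataFrame(rows)


def multifunctionality(edition: PropagatedEdition, accession: str) -> float:
    """Specificity-weighted annotation load of one gene.

    MF(g) = sum over propagated terms t of g of 1 / (n_t * (N - n_t)),
    where n_t is the number of genes propagated-annotated to t and N the
    number of annotated genes in the edition. Terms annotated to every
    gene carry no information and contribute 0.
    """
    if accession not in edition.gene_to_propagated:
        raise TermLookupError(f"gene {accession} is not annotated in this edition")
    term_index = edition.term_to_genes("propagated")
    n_genes = len(edition.gene_to_propagated)
    score = 0.0
    for term in edition.gene_to_propagated[accession]:
        n_t = len(term_index[term])
        if n_t < n_genes:
            score += 1.0 / (n_t * (n_genes - n_t))
    return score


def multifunctionality_ranks(edition: PropagatedEdition) -> dict[str, float]:
    """Rank-normalized multifunctionality in [0, 1] for every annotated gene.

    Average ranks for ties, scaled so the most multifunctional gene scores 1.
    """
    genes = sorted(edition.gene_to_propagated)
    scores = np.array([multifunctionality(edition, g) for g in genes])
    if len(genes) == 1:
        return {genes[0]: 1.0}
    ranks = stats.rankdata(scores)  # average ranks
    normalized = (ranks - 1) / (len(genes) - 1)
    return dict(zip(genes, normalized.tolist()))


def term_gene_count_series(
    series: EditionSeries,
    term_id: str,
    breakdown: str = "total",
    mode: str = "direct",
) -> pd.DataFrame:
    """Per-edition count of distinct genes carrying a term.

    With ``breakdown='by_evidence_category'`` the count splits into
    Automatic (IEA) and Curated genes, judged from the evidence of any
    direct record supporting the term at or beneath it; a gene with both
    kinds of support counts in both columns. Terms absent at a date
    report 0.
    """
    if breakdown not in ("total", "by_evidence_category"):
        raise ValueError(f"unknown breakdown {breakdown!r}")
    rows = []
    for edition in series.editions:
        genes = edition.term_to_genes(mode).get(term_id, frozenset())
        row: dict = {"date": edition.edition_date, "total": len(genes)}
        if breakdown == "by_evidence_category":
            automatic = curated = 0
            for gene in genes:
                categories = {
                    evidence_category(r.evidence_code)
                    for r in edition.direct_records.get(gene, ())
                    if _supports(r.term_id, term_id, edition, mode)
                }
                automatic += "Automatic" in categories
                curated += "Curated" in categories
            row["automatic"] = automatic
            row["curated"] = curated
        rows.append(row)
    return pd.DataFrame(rows)


def _supports(direct_term: str, term_id: str, edition: PropagatedEdition, mode: str) -> bool:
    """Does a direct annotation to ``direct_term`` support ``term_id``?"""
    if mode == "direct":
        return direct_term == term_id
    return term_id in propagate_terms({direct_term}, edition.ontology)


def species_trends(series: EditionSeries) -> pd.DataFrame:
    """Taxon-wide per-edition summary statistics.

    One row per edition: number of annotated genes, mean direct and mean
    inferred (direct included) annotations per annotated gene, and mean
    propagated gene count over terms used by at least one gene.
    """
    rows = []
    for edition in series.editions:
        direct_sizes = [len(s) for s in edition.gene_to_direct.values()]
        prop_sizes = [len(s) for s in edition.gene_to_propagated.values()]
        term_sizes = [len(g) for g in edition.term_to_genes("propagated").values()]
        rows.append(
            {
                "date": edition.edition_date,
                "annotated_genes": len(direct_sizes),
                "mean_annotations_per_term": float(np.mean(term_sizes)) if term_sizes else 0.0,
                "mean_direct_per_gene": float(np.mean(direct_sizes)) if direct_sizes else 0.0,
                "mean_inferred_per_gene": float(np.mean(prop_sizes)) if prop_sizes else 0.0,
            }
        )
    return pd.DataFrame(rows)


def annotation_rank_stability(
    series: EditionSeries, date_a: datetime.date, date_b: datetime.date
) -> float:
    """Spearman correlation of per-gene direct counts between two editions.

    Restricted to genes annotated at both dates; this is the statistic
    behind the observation that annotation inequality between genes
    persists over long periods.
    """
    counts_a = {g: len(s) for g, s in series.at(date_a).gene_to_direct.items()}
    counts_b = {g: len(s) for g, s in series.at(date_b).gene_to_direct.items()}
    shared = sorted(set(counts_a) & set(counts_b))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} genes annotated at both dates; need >= 3"
        )
    rho = stats.spearmanr([counts_a[g] for g in shared], [counts_b[g] for g in shared]).statistic
    return float(rho)
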