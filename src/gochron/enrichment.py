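"""Time-point-anchored overrepresentation analysis.

A hit list is tested against the propagated annotations of one edition
with the one-sided hypergeometric test. The background is the set of all
annotated genes at that time point; it is deliberately not settable.
Terms are filtered to one or more aspects and to a propagated-gene-count
window (default 20-200 genes, biological process only) before testing,
and the Benjamini-Hochberg step-up procedure controls the FDR over the
tested set.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gochron.annotations import PropagatedEdition
from gochron.errors import ConfigurationError, EmptyOverlapError, GochronError

__all__ = [
    "EnrichmentParams",
    "ContingencyCounts",
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_adjust",
    "run_enrichment",
]


@dataclass(frozen=True)
class EnrichmentParams:
    """Term filters and significance threshold for one analysis."""

    min_term_size: int = 20
    max_term_size: int = 200
    aspect_filter: frozenset[str] = frozenset({"biological_process"})
    fdr_threshold: float = 0.05
    #: measure term size on propagated (default) or direct annotations
    term_size_mode: str = "propagated"

    def __post_init__(self):
        if self.min_term_size > self.max_term_size:
            raise ValueError("min_term_size > max_term_size")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ContingencyCounts:
    """Hypergeometric urn counts: k hits in the term, n drawn, K marked, N total."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise GochronError(
                f"invalid contingency counts k={self.k}, n={self.n}, K={self.K}, N={self.N}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """All tested terms with p/q values and the significant subset."""

    edition_date: datetime.date
    tested: tuple[tuple[str, ContingencyCounts, float, float], ...]
    significant: frozenset[str]
    background_size: int
    params: EnrichmentParams = field(compare=False, default=EnrichmentParams())

    def as_records(self) -> list[dict]:
        return [
            {
                "term_id": term,
                "k": c.k,
                "K": c.K,
                "n": c.n,
                "N": c.N,
                "p": p,
                "q": q,
                "significant": term in self.significant,
            }
            for term, c, p, q in self.tested
        ]

    def top_terms(self, top_k: int = 5) -> list[str]:
        """Top significant terms by ascending p (ties: q, then term id)."""
        ranked = sorted(
            (row for row in self.tested if row[0] in self.significant),
            key=lambda row: (row[2], row[3], row[0]),
        )
        return [row[0] for row in ranked[:top_k]]


def hypergeometric_tail(c: ContingencyCounts) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise GochronError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    hit_list: Iterable[str],
    edition: PropagatedEdition,
    params: EnrichmentParams = EnrichmentParams(),
) -> EnrichmentResult:
    """Overrepresentation analysis of a hit list at one edition.

    The background is every gene with at least one (propagated)
    annotation at this date. Hit-list genes outside the background are
    dropped before testing; terms pass the aspect filter and the
    term-size window measured on the background.
    """
    background = set(edition.gene_to_propagated)
    if not background:
        raise ConfigurationError("edition has no annotated genes (empty background)")
    hits = set(hit_list) & background
    if not hits:
        raise EmptyOverlapError("hit list shares no genes with the annotated background")

    term_index = edition.term_to_genes(params.term_size_mode)
    propagated_index = edition.term_to_genes("propagated")
    N, n = len(background), len(hits)
    tested_terms = []
    for term in sorted(term_index):
        info = edition.ontology.terms.get(term)
        if info is None or info.aspect not in params.aspect_filter:
            continue
        if params.min_term_size <= len(term_index[term]) <= params.max_term_size:
            tested_terms.append(term)

    counts, pvalues = [], []
    for term in tested_terms:
        term_genes = propagated_index.get(term, frozenset())
        c = ContingencyCounts(k=len(hits & term_genes), n=n, K=len(term_genes), N=N)
        counts.append(c)
        pvalues.append(hypergeometric_tail(c))
    qvalues = bh_adjust(pvalues) if pvalues else np.array([])
    tested = tuple(
        (term, c, float(p), float(q))
        for term, c, p, q in zip(tested_terms, counts, pvalues, qvalues)
    )
    significant = frozenset(
        term for term, _, _, q in tested if q <= params.fdr_threshold
    )
    return EnrichmentResult(
        edition_date=edition.edition_date,
        tested=tested,
        significant=significant,
        background_size=N,
        params=params,
    )
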