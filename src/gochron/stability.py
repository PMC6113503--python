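"""Stability of enrichment results over time, calibrated against a null.

For each dated hit list, enrichment is run at an edition near its
publication date (t0) and at a recent edition (t_now), and the two
significant term sets are compared with the complete Jaccard index and a
top-terms-plus-parents Jaccard. Raw Jaccard values are hard to interpret
(the number of significant terms grows over the years, depressing the
index), so they are calibrated against a permutation null built by
re-pairing t0 results with t_now results of *different* hit lists: a
result is "stable" when its complete Jaccard exceeds the null's 95th
percentile.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as scipy_stats

from gochron.enrichment import EnrichmentParams, EnrichmentResult, run_enrichment
from gochron.errors import ConfigurationError, EmptyOverlapError
from gochron.history import EditionSeries
from gochron.ontology import OntologyEdition, propagate_terms

logger = logging.getLogger(__name__)

#: a hit list enters the analysis only if at least one of its two results
#: has this many significant terms
MIN_SIGNIFICANT_TERMS = 5

#: age bins (years since t0), right-closed, as used in the corpus analysis
AGE_BINS = (("recent", 0.0, 10.0), ("old", 10.0, 12.0), ("oldest", 12.0, 16.0))

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class DatedHitList:
    """A named gene hit list with an optional publication date."""

    name: str
    genes: frozenset[str]
    publication_date: datetime.date | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"hit list {self.name!r} is empty")


@dataclass(frozen=True)
class StabilityReport:
    """One hit list's t0-vs-t_now comparison."""

    name: str
    t0: datetime.date
    t_now: datetime.date
    n_sig_t0: int
    n_sig_now: int
    complete_jaccard: float
    top_parents_jaccard: float
    null_percentile: float
    stable: bool
    age_years: float
    age_bin: str


def nearest_edition(
    publication_date: datetime.date, edition_dates: Iterable[datetime.date]
) -> datetime.date:
    """Edition date minimizing |days to publication|; ties go earlier."""
    dates = sorted(edition_dates)
    if not dates:
        raise ConfigurationError("no edition dates available")
    return min(dates, key=lambda d: (abs((d - publication_date).days), d))


def complete_jaccard(e0: Iterable[str], e1: Iterable[str]) -> float:
    """|E0 n E1| / |E0 u E1|; two empty sets compare as identical (1)."""
    s0, s1 = set(e0), set(e1)
    union = len(s0 | s1)
    return 1.0 if union == 0 else len(s0 & s1) / union


def top_term_parents_jaccard(
    r0: EnrichmentResult,
    r1: EnrichmentResult,
    ont0: OntologyEdition,
    ont1: OntologyEdition,
    top_k: int = 5,
) -> float:
    """Jaccard of the top-k significant terms expanded by their ancestors.

    Each result's top terms are expanded in its *own* ontology edition,
    so renamed or restructured regions of the DAG are compared as they
    stood at the time.
    """
    expanded0 = propagate_terms(r0.top_terms(top_k), ont0)
    expanded1 = propagate_terms(r1.top_terms(top_k), ont1)
    if not expanded0 and not expanded1:
        return 1.0
    if not expanded0 or not expanded1:
        return 0.0
    return complete_jaccard(expanded0, expanded1)


def build_null(
    corpus: Sequence[tuple[frozenset[str], frozenset[str]]],
    n_rounds: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Pooled null Jaccard sample from re-paired significant term sets.

    Each round draws a uniform random permutation without fixed points and
    compares E0 of list i with E1 of its permuted partner, keeping pairs
    where at least one member has >= 5 significant terms (the same filter
    the observed corpus passes). Values from all rounds are pooled.
    """
    if len(corpus) < 2:
        raise ConfigurationError("null construction needs a corpus of at least 2 hit lists")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(corpus)
    values: list[float] = []
    for _ in range(n_rounds):
        perm = rng.permutation(m)
        while np.any(perm == np.arange(m)):
            perm = rng.permutation(m)
        for i, j in enumerate(perm):
            e0, e1 = corpus[i][0], corpus[int(j)][1]
            if len(e0) >= MIN_SIGNIFICANT_TERMS or len(e1) >= MIN_SIGNIFICANT_TERMS:
                values.append(complete_jaccard(e0, e1))
    return np.array(values)


def _age_bin(age_years: float) -> str:
    for label, low, high in AGE_BINS:
        if (age_years <= high if label == "recent" else low < age_years <= high):
            return label
    logger.warning("hit list older than 16 years (%.1f); binned as 'oldest'", age_years)
    return "oldest"


def null_percentile(null: np.ndarray, observed: float) -> float:
    """Fraction of null values strictly below the observed value, x100."""
    return 100.0 * float(np.mean(null < observed)) if null.size else 0.0


def stability_analysis(
    hit_lists: Sequence[DatedHitList],
    series: EditionSeries,
    params: EnrichmentParams,
    t_now: datetime.date,
    fixed_t0: datetime.date | None = None,
    n_rounds: int = 1000,
    seed: int = 0,
) -> tuple[list[StabilityReport], dict]:
    """Corpus-wide stability experiment.

    For every hit list, run enrichment at its t0 (the edition nearest its
    publication date, or the edition nearest ``fixed_t0``) and at
    ``t_now``; discard lists with fewer than 5 significant terms at both
    time points; calibrate the complete Jaccard against the re-pairing
    null and flag lists beating the null's 95th percentile as stable.

    Returns per-list reports plus a summary dict (null 95th percentile,
    fraction stable overall and per age bin, Spearman correlation of
    Jaccard with age, mean significant-term counts at the two dates).
    """
    edition_dates = series.dates
    now_edition = series.at(t_now)
    retained: list[tuple[DatedHitList, datetime.date, EnrichmentResult, EnrichmentResult]] = []
    skipped_filter = 0
    for hit_list in hit_lists:
        if hit_list.publication_date is not None:
            t0 = nearest_edition(hit_list.publication_date, edition_dates)
        elif fixed_t0 is not None:
            t0 = nearest_edition(fixed_t0, edition_dates)
        else:
            raise ConfigurationError(
                f"hit list {hit_list.name!r} has no publication date and no fixed t0 was given"
            )
        try:
            r0 = run_enrichment(hit_list.genes, series.at(t0), params)
            r1 = run_enrichment(hit_list.genes, now_edition, params)
        except EmptyOverlapError:
            skipped_filter += 1
            continue
        if (
            len(r0.significant) < MIN_SIGNIFICANT_TERMS
            and len(r1.significant) < MIN_SIGNIFICANT_TERMS
        ):
            skipped_filter += 1
            continue
        retained.append((hit_list, t0, r0, r1))
    if skipped_filter:
        logger.info("stability_analysis: %d hit lists below the %d-significant-term filter",
                    skipped_filter, MIN_SIGNIFICANT_TERMS)

    corpus = [(r0.significant, r1.significant) for _, _, r0, r1 in retained]
    null = build_null(corpus, n_rounds=n_rounds, seed=seed)
    threshold = float(np.quantile(null, 0.95)) if null.size else 1.0

    reports: list[StabilityReport] = []
    for hit_list, t0, r0, r1 in retained:
        jaccard = complete_jaccard(r0.significant, r1.significant)
        age = (t_now - t0).days / DAYS_PER_YEAR
        reports.append(
            StabilityReport(
                name=hit_list.name,
                t0=t0,
                t_now=t_now,
                n_sig_t0=len(r0.significant),
                n_sig_now=len(r1.significant),
                complete_jaccard=jaccard,
                top_parents_jaccard=top_term_parents_jaccard(
                    r0, r1, series.at(t0).ontology, now_edition.ontology
                ),
                null_percentile=null_percentile(null, jaccard),
                stable=jaccard > threshold,
                age_years=age,
                age_bin=_age_bin(age),
            )
        )

    summary: dict = {
        "n_retained": len(reports),
        "n_skipped": skipped_filter,
        "null_size": int(null.size),
        "null_95th_percentile": threshold,
        "fraction_stable": float(np.mean([r.stable for r in reports])) if reports else float("nan"),
        "mean_significant_t0": float(np.mean([r.n_sig_t0 for r in reports])) if reports else float("nan"),
        "mean_significant_now": float(np.mean([r.n_sig_now for r in reports])) if reports else float("nan"),
    }
    for label, _, _ in AGE_BINS:
        in_bin = [r.stable for r in reports if r.age_bin == label]
        summary[f"n_{label}"] = len(in_bin)
        summary[f"fraction_stable_{label}"] = float(np.mean(in_bin)) if in_bin else float("nan")
    if len(reports) >= 3 and len({r.age_years for r in reports}) > 1:
        rho = scipy_stats.spearmanr(
            [r.complete_jaccard for r in reports], [r.age_years for r in reports]
        ).statistic
        summary["jaccard_age_spearman"] = float(rho)
    else:
        summary["jaccard_age_spearman"] = float("nan")
    return reports, summary
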