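"""Synthetic GO/GOA histories with realistic temporal structure.

The generator emulates, at desk scale, the phenomena observed in real
annotation archives: a growing DAG ontology with occasional leaf
obsoletion; per-edition direct annotations that accrete over time;
annotation churn (the same gene-term pair removed for an edition or two
and then restored, on automatically assigned IEA records); global
discontinuity events in which redundant high-level direct annotations
are purged in a single edition (direct counts drop, propagated counts
do not); a persistent heavy-tailed inequality in per-gene annotation
counts; and an optional slow drift that rewires gene-term memberships,
so that enrichment results anchored at older editions degrade more.

Everything is deterministic given ``SimulationParams.seed``; independent
named substreams keep the ontology, annotation and corpus draws
decoupled from one another.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from gochron.annotations import (
    AnnotationEdition,
    AnnotationRecord,
    match_ontology,
    propagate_edition,
)
from gochron.errors import ConfigurationError
from gochron.ontology import IS_A, PART_OF, OntologyEdition, Term
from gochron.stability import DatedHitList

logger = logging.getLogger(__name__)

START_DATE = datetime.date(2001, 1, 15)

ASPECT_WEIGHTS = {"biological_process": 0.8, "molecular_function": 0.1, "cellular_component": 0.1}

CURATED_CODES = ("IDA", "IMP", "ISS", "TAS")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic history; defaults emulate a small real archive."""

    n_terms_initial: int = 300
    term_birth_rate: float = 10.0
    n_genes: int = 400
    n_editions: int = 24
    edition_spacing_days: int = 28
    annotation_gain_rate: float = 0.4
    churn_probability: float = 0.05
    discontinuity_editions: frozenset[int] = frozenset()
    inequality_exponent: float = 0.75
    drift_rate: float = 0.0
    seed: int = 0
    #: probability per edition of retiring one leaf term as obsolete
    obsoletion_probability: float = 0.1
    #: mean number of initial direct annotations per gene at edition 0;
    #: kept low so the annotated background grows across the history
    initial_annotations_per_gene: float = 1.0
    #: fraction of new annotations carrying the automatic IEA code
    iea_fraction: float = 0.7
    #: probability that a gained annotation lands adjacent (parent/child in
    #: the DAG) to a term the gene already carries, emulating curation that
    #: deepens along a gene's known biology rather than jumping randomly
    gain_locality: float = 0.7
    #: when a new term is born, each gene directly annotated to one of its
    #: parents picks up the child with this probability (IEA), emulating
    #: electronic refinement of annotations as GO grows more granular
    refine_probability: float = 0.3

    def __post_init__(self):
        if self.n_editions < 2:
            raise ValueError("n_editions must be >= 2")
        if not 0 <= self.churn_probability <= 1 or not 0 <= self.drift_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.term_birth_rate, self.annotation_gain_rate, self.inequality_exponent) < 0:
            raise ValueError("rates must be >= 0")

    def edition_dates(self) -> list[datetime.date]:
        return [
            START_DATE + datetime.timedelta(days=e * self.edition_spacing_days)
            for e in range(self.n_editions)
        ]


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed % (2**31), stream])


def _term_id(counter: int) -> str:
    return f"GO:{counter:07d}"


def simulate_ontology_history(params: SimulationParams) -> list[OntologyEdition]:
    """Grow a rooted DAG per aspect across dated editions.

    Edition 0 seeds each aspect with a root and attaches the remaining
    initial terms under 1-2 existing same-aspect parents. Later editions
    add Poisson(term_birth_rate) terms and occasionally retire a leaf as
    obsolete. Editions listed in ``discontinuity_editions`` freeze the
    ontology (the purge there is an annotation event, not a GO event).
    """
    rng = _rng(params, 1)
    dates = params.edition_dates()
    aspects = list(ASPECT_WEIGHTS)
    weights = np.array(list(ASPECT_WEIGHTS.values()))

    counter = 1
    terms: dict[str, Term] = {}
    edges: set[tuple[str, str, str]] = set()
    roots: dict[str, str] = {}
    for aspect in aspects:
        tid = _term_id(counter)
        counter += 1
        roots[aspect] = tid
        terms[tid] = Term(tid, f"{aspect} root", aspect)

    def add_term(aspect: str) -> None:
        nonlocal counter
        tid = _term_id(counter)
        counter += 1
        terms[tid] = Term(tid, f"synthetic {aspect.split('_')[-1]} term {counter}", aspect)
        candidates = [t for t, term in terms.items()
                      if term.aspect == aspect and not term.obsolete and t != tid]
        n_parents = 1 if len(candidates) < 2 or rng.random() < 0.7 else 2
        for parent in rng.choice(candidates, size=n_parents, replace=False):
            relation = IS_A if rng.random() < 0.8 else PART_OF
            edges.add((tid, str(parent), relation))

    for _ in range(max(0, params.n_terms_initial - len(roots))):
        add_term(aspects[rng.choice(len(aspects), p=weights)])

    editions: list[OntologyEdition] = []
    for e, date in enumerate(dates):
        if e > 0 and e not in params.discontinuity_editions:
            for _ in range(rng.poisson(params.term_birth_rate)):
                add_term(aspects[rng.choice(len(aspects), p=weights)])
            if rng.random() < params.obsoletion_probability:
                children = {c for c, _, _ in edges}
                parents_of = {p for _, p, _ in edges}
                leaves = sorted(
                    t for t in terms
                    if not terms[t].obsolete and t not in parents_of
                    and t not in roots.values() and t in children
                )
                if leaves:
                    victim = str(rng.choice(leaves))
                    terms[victim] = replace(terms[victim], obsolete=True)
                    edges -= {edge for edge in edges if victim in edge[:2]}
        editions.append(OntologyEdition(date, dict(terms), frozenset(edges)))
    return editions


@dataclass
class _AnnotationState:
    """Lifecycle of one gene-term pair inside the simulation."""

    evidence: str
    aspect: str
    created: int
    removed_at: int | None = None
    absent: frozenset[int] = frozenset()  # churn window (edition indices)

    def active(self, e: int) -> bool:
        return (
            self.created <= e
            and (self.removed_at is None or e < self.removed_at)
            and e not in self.absent
        )


def simulate_annotation_history(
    ontology_history: Sequence[OntologyEdition], params: SimulationParams
) -> list[AnnotationEdition]:
    """Accrete, churn, drift and purge direct annotations across editions.

    Per-gene gain propensities follow a Zipf-like weight with exponent
    ``inequality_exponent``, producing the persistent inequality in
    annotation counts; churn affects only IEA records; at a discontinuity
    edition the edition is copied from its predecessor and every direct
    annotation whose term is an ancestor of another direct annotation of
    the same gene is removed, so direct counts drop while propagated
    counts are untouched.
    """
    rng = _rng(params, 2)
    dates = params.edition_dates()
    genes = [f"P{i + 10001:05d}" for i in range(params.n_genes)]
    # preferential attachment: the next annotation lands on gene g with
    # probability ~ (count_g + 1) ** inequality_exponent, so early luck
    # compounds into a persistent heavy-tailed inequality
    gain_counts = np.zeros(params.n_genes)

    def draw_genes(n_gains: int) -> list[int]:
        chosen = []
        for _ in range(n_gains):
            weights = (gain_counts + 1.0) ** params.inequality_exponent
            idx = int(rng.choice(params.n_genes, p=weights / weights.sum()))
            gain_counts[idx] += 1
            chosen.append(idx)
        return chosen

    state: dict[tuple[str, str], _AnnotationState] = {}

    def annotatable_terms(e: int) -> list[str]:
        ontology = ontology_history[min(e, len(ontology_history) - 1)]
        return sorted(t for t, term in ontology.terms.items() if not term.obsolete)

    def gain(gene: str, e: int, candidates: list[str], ontology: OntologyEdition,
             local: bool = True) -> None:
        term = None
        if local and rng.random() < params.gain_locality:
            anchors = sorted(t for (g, t), st in state.items()
                             if g == gene and st.removed_at is None
                             and t in ontology.terms and not ontology.terms[t].obsolete)
            if anchors:
                anchor = str(rng.choice(anchors))
                graph = ontology._graph
                neighborhood = sorted(
                    set(graph.predecessors(anchor)) | set(graph.successors(anchor))
                )
                if neighborhood:
                    term = str(rng.choice(neighborhood))
        if term is None:
            term = str(rng.choice(candidates))
        key = (gene, term)
        existing = state.get(key)
        if existing is not None and existing.removed_at is None:
            return  # pair already live
        evidence = "IEA" if rng.random() < params.iea_fraction else str(rng.choice(CURATED_CODES))
        absent: frozenset[int] = frozenset()
        if evidence == "IEA" and rng.random() < params.churn_probability:
            start = e + int(rng.integers(1, 4))
            absent = frozenset(range(start, start + int(rng.integers(1, 3))))
        state[key] = _AnnotationState(
            evidence=evidence,
            aspect=ontology.terms[term].aspect,
            created=e,
            absent=absent,
        )

    def realized(e: int) -> set[tuple[str, str]]:
        return {key for key, st in state.items() if st.active(e)}

    editions: list[AnnotationEdition] = []
    prev_pairs: set[tuple[str, str]] = set()
    for e, date in enumerate(dates):
        ontology = ontology_history[min(e, len(ontology_history) - 1)]
        if e in params.discontinuity_editions:
            # copy the previous edition, then purge redundant high-level directs
            per_gene: dict[str, set[str]] = {}
            for gene, term in prev_pairs:
                per_gene.setdefault(gene, set()).add(term)
            purged_keys: set[tuple[str, str]] = set()
            for gene, terms_g in per_gene.items():
                redundant = set()
                for term in terms_g:
                    if term in ontology.terms and not ontology.terms[term].obsolete:
                        redundant |= ontology._ancestor_cache.get(term, frozenset())
                for term in terms_g & redundant:
                    state[(gene, term)] = replace(state[(gene, term)], removed_at=e)
                    purged_keys.add((gene, term))
            logger.info("edition %d: discontinuity purge removed %d redundant annotations",
                        e, len(purged_keys))
            pairs = prev_pairs - purged_keys  # no additions at a purge edition
        else:
            candidates = annotatable_terms(e)
            if e > 0:
                prev_ontology = ontology_history[min(e - 1, len(ontology_history) - 1)]
                born = sorted(set(ontology.terms) - set(prev_ontology.terms))
                parents_of_born = {
                    t: sorted(p for c, p, _ in ontology.edges if c == t) for t in born
                }
                by_term: dict[str, list[str]] = {}
                for (g, t), st in state.items():
                    if st.active(e - 1):
                        by_term.setdefault(t, []).append(g)
                for child in born:
                    carriers = sorted({g for p in parents_of_born[child]
                                       for g in by_term.get(p, [])})
                    for gene in carriers:
                        if rng.random() < params.refine_probability:
                            key = (gene, child)
                            if key not in state:
                                state[key] = _AnnotationState(
                                    evidence="IEA",
                                    aspect=ontology.terms[child].aspect,
                                    created=e,
                                )
            n_gains = (
                rng.poisson(params.initial_annotations_per_gene * params.n_genes)
                if e == 0
                else rng.poisson(params.annotation_gain_rate * params.n_genes)
            )
            for idx in draw_genes(n_gains):
                gain(genes[idx], e, candidates, ontology)
            if params.drift_rate > 0 and e > 0:
                drifting = np.nonzero(rng.random(params.n_genes) < params.drift_rate)[0]
                for idx in drifting:
                    gene = genes[int(idx)]
                    live = sorted(t for (g, t), st in state.items()
                                  if g == gene and st.active(e))
                    if not live:
                        continue
                    lost = str(rng.choice(live))
                    state[(gene, lost)] = replace(state[(gene, lost)], removed_at=e)
                    # drifted genes jump to an unrelated region of the DAG
                    gain(gene, e, candidates, ontology, local=False)
            pairs = realized(e)

        records = frozenset(
            AnnotationRecord(
                accession=gene,
                term_id=term,
                evidence_code=state[(gene, term)].evidence,
                qualifier="",
                aspect=state[(gene, term)].aspect,
            )
            for gene, term in pairs
        )
        editions.append(AnnotationEdition("synthetic", date, records))
        prev_pairs = pairs
    return editions


def simulate_hitlist_corpus(
    annotation_history: Sequence[AnnotationEdition],
    ontology_history: Sequence[OntologyEdition],
    params: SimulationParams,
    n_lists: int = 40,
    genes_per_list: int = 30,
    module_fraction: float = 0.8,
    membership_horizon: int = 6,
) -> list[DatedHitList]:
    """Sample dated hit lists around true term modules.

    Each list picks a publication edition (spread across the history,
    excluding the final comparison edition), a mid-size biological-process
    term at that edition, and draws ``module_fraction`` of its genes from
    the term's propagated gene set plus background noise genes. Membership
    is taken from the union of the publication edition and an edition
    ``membership_horizon`` editions later: the experiment sees the true
    module while curation lags behind it, so enrichment strengthens as
    annotations catch up. When the history drifts, module membership
    erodes after publication, so older lists see more enrichment drift.
    """
    if genes_per_list > params.n_genes:
        raise ConfigurationError("genes_per_list exceeds the number of simulated genes")
    if not annotation_history or not ontology_history:
        raise ConfigurationError("histories must be nonempty")
    rng = _rng(params, 3)
    ontology_dates = [o.edition_date for o in ontology_history]

    propagated_cache: dict[int, dict] = {}

    def propagated(e: int):
        if e not in propagated_cache:
            edition = annotation_history[e]
            matched = match_ontology(edition.edition_date, ontology_dates)
            ontology = ontology_history[ontology_dates.index(matched)]
            prop = propagate_edition(edition, ontology)
            propagated_cache[e] = {
                "background": sorted(prop.gene_to_propagated),
                "term_index": prop.term_to_genes("propagated"),
                "ontology": ontology,
            }
        return propagated_cache[e]

    hit_lists: list[DatedHitList] = []
    n_editions = len(annotation_history)
    ann_dates = [a.edition_date for a in annotation_history]
    span_years = (ann_dates[-1] - ann_dates[0]).days / 365.25
    if span_years > 12.0:
        # long histories: draw publication ages bin-balanced so each of the
        # three age bins of the stability analysis is similarly populated
        bins = [(0.0, 10.0), (10.0, 12.0), (12.0, min(16.0, span_years))]
        pools = [
            [e for e, d in enumerate(ann_dates[:-1])
             if lo_y < (ann_dates[-1] - d).days / 365.25 <= hi_y]
            for lo_y, hi_y in bins
        ]
        pools = [p for p in pools if p]

        def draw_pub() -> int:
            pool = pools[int(rng.integers(len(pools)))]
            return int(pool[int(rng.integers(len(pool)))])
    else:
        # enrichment studies postdate a usable annotation resource: skip the
        # sparse burn-in editions at the start of a short history
        first = min(max(1, n_editions // 5), n_editions - 2)

        def draw_pub() -> int:
            return int(rng.integers(first, max(first + 1, n_editions - 1)))

    used_modules: set[str] = set()
    for i in range(n_lists):
        e_pub = draw_pub()
        snapshot = propagated(e_pub)
        background = snapshot["background"]
        lo = max(5, genes_per_list // 2)
        hi = max(lo + 1, 3 * genes_per_list)
        candidates = sorted(
            term
            for term, members in snapshot["term_index"].items()
            if lo <= len(members) <= hi
            and snapshot["ontology"].terms[term].aspect == "biological_process"
        )
        # distinct studies examine distinct processes: avoid reusing a module
        fresh = [t for t in candidates if t not in used_modules]
        if fresh:
            candidates = fresh
        if not candidates:
            candidates = sorted(snapshot["term_index"],
                                key=lambda t: -len(snapshot["term_index"][t]))[:1]
        module_term = str(rng.choice(candidates))
        used_modules.add(module_term)
        e_mature = min(e_pub + membership_horizon, n_editions - 1)
        mature_members = propagated(e_mature)["term_index"].get(module_term, frozenset())
        members = sorted(set(snapshot["term_index"][module_term]) | set(mature_members))
        n_module = min(len(members), int(round(module_fraction * genes_per_list)))
        chosen = {str(g) for g in rng.choice(members, size=n_module, replace=False)}
        noise_pool = [g for g in background if g not in chosen]
        n_noise = min(genes_per_list - len(chosen), len(noise_pool))
        if n_noise > 0:
            chosen |= {str(g) for g in rng.choice(noise_pool, size=n_noise, replace=False)}
        hit_lists.append(
            DatedHitList(
                name=f"HL{i:04d}",
                genes=frozenset(chosen),
                publication_date=annotation_history[e_pub].edition_date,
            )
        )
    return hit_lists


# ---------------------------------------------------------------------------
# presets

def preset_enrichment_params():
    """Term-size window scaled to the synthetic background.

    The default 20-200 window suits a genome-scale background of ~20,000
    genes; for the simulated ~400-gene background the same idea (exclude
    uninformative tiny terms and near-universal terms) maps to 5-150.
    """
    from gochron.enrichment import EnrichmentParams

    return EnrichmentParams(min_term_size=5, max_term_size=150)


def preset_params(name: str, seed: int = 0) -> SimulationParams:
    """Named study conditions for the end-to-end experiments.

    ``stable``: two years of monthly editions, no drift — enrichment
    results should replicate across time. ``drift``: ~16 years of
    quarterly editions with membership drift, populating all three age
    bins with decaying stability. ``churn``: heavy IEA churn plus one
    mid-history redundancy purge.
    """
    if name == "stable":
        return SimulationParams(n_editions=26, seed=seed)
    if name == "drift":
        return SimulationParams(
            n_editions=65,
            edition_spacing_days=90,
            term_birth_rate=4.0,
            annotation_gain_rate=0.15,
            initial_annotations_per_gene=2.0,
            drift_rate=0.08,
            seed=seed,
        )
    if name == "churn":
        return SimulationParams(
            n_editions=24,
            churn_probability=0.3,
            discontinuity_editions=frozenset({12}),
            seed=seed,
        )
    raise ConfigurationError(f"unknown preset {name!r}")
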