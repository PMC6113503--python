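"""Shared fixtures: toy DAGs, toy file texts, and seeded synthetic histories."""

import datetime

import pytest

from gochron.annotations import match_ontology, propagate_edition
from gochron.history import EditionSeries
from gochron.ontology import IS_A, OntologyEdition, Term
from gochron.stability import stability_analysis
from gochron.synthetic import (
    preset_enrichment_params,
    preset_params,
    simulate_annotation_history,
    simulate_hitlist_corpus,
    simulate_ontology_history,
)

D = datetime.date


def make_edition(edges, extra_terms=(), date=D(2005, 1, 1), aspect="biological_process"):
    """Build an OntologyEdition from (child, parent) pairs, all IS_A, one aspect."""
    ids = {t for pair in edges for t in pair} | set(extra_terms)
    terms = {t: Term(t, f"term {t}", aspect) for t in ids}
    return OntologyEdition(date, terms, frozenset((c, p, IS_A) for c, p in edges))


def gid(i: int) -> str:
    return f"GO:{i:07d}"


@pytest.fixture
def chain_edition():
    # c -> b -> a
    return make_edition([(gid(3), gid(2)), (gid(2), gid(1))])


@pytest.fixture
def diamond_edition():
    # d -> b, d -> c, b -> a, c -> a
    return make_edition([(gid(4), gid(2)), (gid(4), gid(3)), (gid(2), gid(1)), (gid(3), gid(1))])


def build_series(params):
    ontology_history = simulate_ontology_history(params)
    annotation_history = simulate_annotation_history(ontology_history, params)
    dates = [o.edition_date for o in ontology_history]
    series = EditionSeries(
        "synthetic",
        tuple(
            propagate_edition(a, ontology_history[dates.index(match_ontology(a.edition_date, dates))])
            for a in annotation_history
        ),
    )
    return ontology_history, annotation_history, series


@pytest.fixture(scope="session")
def stable_history():
    params = preset_params("stable", seed=1)
    return (params, *build_series(params))


@pytest.fixture(scope="session")
def churn_history():
    params = preset_params("churn", seed=3)
    return (params, *build_series(params))


@pytest.fixture(scope="session")
def stable_analysis(stable_history):
    params, onts, anns, series = stable_history
    corpus = simulate_hitlist_corpus(anns, onts, params, n_lists=60, genes_per_list=25)
    reports, summary = stability_analysis(
        corpus, series, preset_enrichment_params(),
        t_now=series.dates[-1], n_rounds=300, seed=7,
    )
    return corpus, series, reports, summary


@pytest.fixture(scope="session")
def drift_analysis():
    params = preset_params("drift", seed=1)
    onts, anns, series = build_series(params)
    corpus = simulate_hitlist_corpus(anns, onts, params, n_lists=120, genes_per_list=25)
    reports, summary = stability_analysis(
        corpus, series, preset_enrichment_params(),
        t_now=series.dates[-1], n_rounds=300, seed=7,
    )
    return corpus, series, reports, summary
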