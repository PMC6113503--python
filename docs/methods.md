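# Methods

This note documents the models and procedures implemented in `gochron`,
the parameters that matter, the design choices made where more than one
reasonable option existed, and what the synthetic benchmark does and does
not demonstrate.

## Versioned ontology and annotation model

A GO **edition** is one dated release of the ontology: terms (with name,
aspect, obsolescence flag and alternate ids) plus typed child→parent
edges restricted to `is_a` and `part_of`. Other relationship types
(`regulates`, `occurs_in`, …) do not support the true-path rule and are
discarded at parse time, as are edges crossing the three aspects and any
edge touching an obsolete term. The retained edge set over non-obsolete
terms must be acyclic; a cycle or an edge to an undeclared term is a hard
structural error rather than a warning, because every downstream
statistic assumes a valid DAG.

An **annotation edition** is one dated species release of direct
gene-product→term associations with evidence codes, read from GAF 2.x.
Records whose qualifier contains `NOT` are excluded (they assert the
absence of a function, which would corrupt counting statistics), and rows
duplicating an (accession, term, evidence) triple collapse to one record.
Counting statistics are over distinct gene–term pairs; evidence codes are
retained separately and grouped into two categories, Automatic = {IEA}
and Curated = everything else, for term-history breakdowns.

Gene identifiers are UniProt-style accessions. Merges and splits leave
secondary accessions behind; a two-column secondary→primary table is
applied to every edition, with chains collapsed to their terminal primary
and a secondary mapping to two distinct primaries treated as a data error.
Accessions absent from the table pass through unchanged — most accessions
are already primary — and the number rewritten is logged.

Each annotation edition is joined to the ontology release with the
**closest date at or before** its own (annotations are produced against
the ontology that existed when they were made, never a later one).
Direct annotations are then propagated: a gene's propagated set is the
reflexive transitive closure of its direct terms under `is_a`/`part_of`
ancestry. Alternate ids are resolved to their primary term first;
annotations to terms unknown to or obsolete in the matched release are
dropped with a logged count — remapping them would require information
the files do not carry, and dropping is conservative and auditable.

## Historical statistics

- **Gene counts**: per edition, the size of a gene's direct or propagated
  term set (0 when unannotated), with the mean over annotated genes as
  the species reference curve. The mean is over *annotated* genes: the
  set of "all known genes" is not defined by the GAF alone.
- **Semantic similarity**: Jaccard index of a gene's term set at each
  edition against a chosen reference edition; two empty sets score 1 (an
  unannotated gene has not changed). The default uses direct sets, where
  curation churn is visible; propagated sets are buffered by shared
  ancestors and available as an option.
- **Multifunctionality**: MF(g) = Σ_t 1/(n_t·(N−n_t)) over the gene's
  propagated terms, where n_t is the term's propagated gene count and N
  the number of annotated genes; terms with n_t = N carry no information
  and contribute 0. A rank-normalized form in [0, 1] (average ranks for
  ties) is exposed for cross-edition comparison.
- **Species trends**: per edition, the number of annotated genes, mean
  direct and mean propagated annotations per annotated gene, and the
  mean propagated gene count over terms used by at least one gene.
  Never-used terms are excluded from that last mean so the statistic
  reflects annotation activity, not ontology size.
- **Rank persistence**: Spearman correlation (average ranks for ties,
  via scipy) of per-gene direct counts between two editions, restricted
  to genes annotated at both; fewer than 3 shared genes is an error.

## Enrichment

Overrepresentation of a hit list at one edition uses the hypergeometric
upper tail P(X ≥ k) with N = all annotated genes at that date (the
background is deliberately not user-settable), n = hit-list genes present
in the background, K = a term's propagated gene count and k = hits in the
term. Hit-list genes outside the background are dropped with a logged
count — the model requires the sample to be drawn from the urn. Tested
terms must pass an aspect filter (default biological process) and a size
window (default 20–200 genes, measured on propagated annotations; a
switch allows direct counts, since either convention is defensible).
Benjamini–Hochberg q-values are computed over the tested set only —
filtering happens before testing, so the multiplicity correction sees
exactly the hypotheses actually tested — and significance is q ≤ 5% by
default. An empty background and a hit list disjoint from the background
are distinct errors, both distinguishable from "no significant terms".

## Stability analysis

For each hit list with a publication date, t₀ is the edition **nearest**
that date (absolute day distance, ties to the earlier edition — note this
differs deliberately from the closest-*before* rule used for GO↔GOA
matching, where causality matters). Enrichment runs at t₀ and at t_now;
lists with fewer than five significant terms at both time points are
discarded. Two similarity measures compare the significant sets:

- **complete Jaccard** |E0∩E1|/|E0∪E1| (both-empty defined as 1 in the
  library, though unreachable through the ≥5-term corpus filter);
- **top-term-parents Jaccard**: the top five significant terms by
  ascending p (ties by q, then term id — the ranking needs a total order
  to be reproducible), each expanded by its ancestors *in its own
  edition's ontology*, then compared with the complete Jaccard.

Raw Jaccard values are uninterpretable on their own — the number of
significant terms grows over the years, mechanically depressing the
index — so they are calibrated against a **permutation null**: in each of
1,000 rounds the corpus is re-paired by a uniform random permutation with
fixed points rejected, E0 of list i is compared to E1 of its partner
(keeping pairs where at least one member has ≥5 significant terms, the
same constraint the observed corpus passes), and all rounds are pooled.
A result is **stable** when its complete Jaccard strictly exceeds the
empirical 95th percentile of the pooled null; the reported percentile is
the fraction of null values strictly below the observed value. When
pseudo-observations are themselves drawn from the re-pairing process,
about 5% are flagged stable (verified in the test suite within a 99%
binomial interval).

Reports carry the hit-list age in years ((t_now − t₀)/365.25) and an age
bin — recent ≤ 10, old (10, 12], oldest (12, 16] years, right-closed;
anything older falls into the oldest bin with a warning. The summary
includes stable fractions overall and per bin and the Spearman
correlation of Jaccard with age.

## Synthetic histories

The generator exists so that every statistic above can be exercised, at
desk scale and fully offline, on data with the temporal structure real
archives show. One integer seed determines everything; the ontology,
annotation and corpus stages draw from independent named substreams, so
changing corpus size does not perturb the histories.

**Ontology.** Edition 0 seeds a root per aspect (80% of terms biological
process, 10% each for the other aspects) and attaches the remaining
initial terms under one or two existing same-aspect parents (80% `is_a`,
20% `part_of`). Later editions add Poisson(`term_birth_rate`) terms and
occasionally retire a leaf as obsolete, dropping its edges.

**Annotations.** Per-edition gains are allocated to genes by sublinear
preferential attachment — the next annotation lands on gene g with
probability ∝ (count_g + 1)^`inequality_exponent` — which yields the
persistent heavy-tailed inequality in per-gene counts without letting
any hub swallow the ontology. Gains land adjacent (parent/child) to a
term the gene already carries with probability `gain_locality`, emulating
curation that deepens along known biology; with the complementary
probability they land uniformly. When a new term is born, each gene
directly annotated to one of its parents picks it up with probability
`refine_probability` (as IEA), emulating the electronic refinement that
accompanies increasing granularity — this is what drives the growth in
significant terms over time. New IEA annotations churn with probability
`churn_probability`: the pair disappears for 1–2 editions shortly after
creation and then returns (churn is restricted to automatic records, as
observed churn predominantly carries IEA evidence). At each listed
discontinuity edition the edition is copied from its predecessor, the
ontology is frozen, and every direct annotation whose term is an ancestor
of another direct annotation of the same gene is removed: direct means
drop sharply while propagated means are *exactly* unchanged — the
signature of a redundancy purge. With `drift_rate` > 0, each gene per
edition loses one random annotation and gains one *non-local* one with
that probability, slowly rewiring gene function.

**Hit lists.** Each list picks a publication edition, a distinct mid-size
biological-process module term there (distinct studies examine distinct
processes; reusing modules would correlate "unrelated" null pairs), and
draws 80% of its genes from the module's propagated membership and 20%
background noise. Membership is taken from the union of the publication
edition and an edition `membership_horizon` (default 6) editions later:
the experiment detects the true module while curation lags, so enrichment
strengthens as annotation catches up. On short histories publication
dates skip the sparse first fifth of editions (published enrichment
studies postdate a usable resource); on histories spanning more than 12
years they are drawn bin-balanced across the three age bins so each bin
is similarly populated.

Defaults — 300 initial terms, 400 genes, 24 editions spaced 28 days,
gain rate 0.4 annotations/gene/edition, 70% IEA, churn 5% — are chosen so
the ratios that govern enrichment behaviour (terms per gene, module size
relative to the background, term-filter window relative to N) resemble
their genome-scale counterparts at roughly 1/50 scale. The enrichment
window used with synthetic data is 5–150 genes of a ~400-gene background
for the same reason (the 20–200 default assumes ~20,000). The `drift`
preset spans ~16 years as 65 editions spaced 90 days so all three age
bins exist at desk scale; the `churn` preset adds heavy churn and one
mid-history purge.

**What the generator does not emulate:** real GAF metadata (references,
assigned-by, annotation extensions), evidence-code ecology beyond the
IEA/curated split, taxon mixtures, correlated curation campaigns across
species, or parameters fitted to real archives. Passing tests therefore
demonstrate that the machinery behaves correctly under realistic
*temporal structure*, not that any quantitative result transfers to a
specific real corpus.

## Numerical choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, N, K, n)`
  and are validated in tests against exact rational binomial summation
  for every urn with N ≤ 30 (tolerance 1e−12).
- BH adjustment delegates to statsmodels' `fdr_bh` and is validated
  against a literal step-up implementation (tolerance 1e−12). Ties in p
  are preserved; significance is exactly q ≤ threshold.
- The null's 95th percentile uses `numpy.quantile` (linear
  interpolation); "stable" requires strictly exceeding it. Pooling order
  cannot affect any percentile.
- Dates are `datetime.date` throughout; edition matching is binary
  search over sorted dates.
- Determinism: all randomness flows from `numpy.random.default_rng`
  seeded from a single integer; writers emit sorted, canonical text, so
  identical inputs and seeds give byte-identical outputs.

## Known limitations

- GPAD/GPI dialects and the pre-2004 three-file flat ontology format are
  not read; annotation extensions (GAF column 16) are ignored.
- The enrichment background is not user-settable by design; users
  wanting a custom background can export the per-date annotation table
  and use any standard tool.
- Multifunctionality-aware enrichment corrections are out of scope.
- The per-edition store is plain text loaded into memory; it targets
  desk-scale species archives, not the full multi-species database a
  server deployment would use.
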