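# Methods

## Counting unit and data model

All statistics count deduplicated **(informant, species, ailment)** triples
— the "use citation". An informant naming the same species for the same
ailment twice (e.g. via two plant parts) contributes one citation;
descriptive attributes (plant part, preparation mode, administration route)
are therefore multi-valued *attribute sets* on the triple, and composite
comma-separated cells in input tables are split into sets rather than extra
rows. This is the only counting basis under which a species' printed
fidelity levels partition to 100 (verified on the transcribed nine-ailment
spot row, which sums to 100.00 at 2 dp), and it is what the per-category
citation totals of published consensus tables sum over. The raw row count
before merging is still surfaced by validation, which reports duplicate
triples, unknown species, unmapped ailments and route violations without
raising.

Free-text ailments are binned into ailment categories by a total
ailment→category map. A starter taxonomy with the 16 Heinrich-style
category labels ships as an editable CSV resource
(`ethnokit/data/ailment_categories.csv`); maps whose categories extend
beyond the canonical list define their own category universe.

## Consensus and fidelity statistics

ICF = (nur − nt)/(nur − 1) per category. The nur = 1 case is the formula's
0/0: a single citation carries no consensus evidence, so the package
returns 0.0 and flags the row as degenerate — a bounded, conservative
convention. FL = 100·Np/N per (species, ailment) pair; N is the species'
total citation count by default. A separate `basis="informants"` mode
counts distinct informants instead (the two coincide whenever each
informant names one ailment per species; the informant basis does not
partition to 100 and exists for comparison only).

All internal arithmetic is full precision; the reporting layer rounds ICF
and FL to 2 dp and percentages to 1 dp with **round-half-up**
(`decimal.ROUND_HALF_UP`), mirroring how printed survey tables round (the
Diabetes-style ICF 155/164 = 0.94512 must print 0.95). Every table is fully
sorted (statistic descending, ties by count descending then label) so
outputs are byte-stable.

Family summaries emit both counting bases — share of distinct species
mentioned and share of citations — because survey write-ups mix the two;
both columns are labelled. The FL = 100 species list takes a
`min_reports` threshold (default 2) to exclude species mentioned only once,
whose perfect fidelity is vacuous.

## Two-mode network analysis

The incidence matrix has ailment categories as rows (raw ailments by
option), species as columns, use-report counts as entries; its marginals
are exactly the (nur, n) quantities of the consensus module, which the
tests assert as a conservation law. The category projection counts *shared
species* on the binary view (a set notion — two categories are close when
the same plants treat both), not min-weight sums.

Interchange: UCINET DL fullmatrix dialect (header
`dl nr=<R> nc=<C> format=fullmatrix`, quoted label blocks, integer data
rows, LF endings) with a bundled reader, plus GraphML and a weighted TSV
edge list. The layout is a seeded Fruchterman–Reingold embedding scaled to
the unit box; layouts are deterministic given (seed, iterations) but are a
visualisation aid, not an analysis contract.

Published group structure in this literature comes from visual inspection
of NetDraw layouts, which is not a stable algorithmic target. The
reproducible contract here is **greedy (Clauset–Newman–Moore) modularity
maximisation on the weighted category projection**: deterministic, seedable
in interface, emitting contiguous group ids (ordered by group size, then
smallest member label) and the partition's modularity. Fewer than two
categories yield a single group; on planted 4-block synthetic surveys with
≤ 5 % cross-block species sharing the partition recovers the blocks with
Adjusted Rand = 1 in ≥ 95 % of seeds (measured by the acceptance script).

## Synthetic survey generator

Per category c: a species-preference distribution over its pool of size
S_c is drawn once from a symmetric Dirichlet(α/S_c); each informant cites
Poisson(λ_c) *distinct* species from it (without replacement within the
informant-category, matching the deduplicated counting unit), and each
citation receives 1–2 plant parts, 1–3 preparation modes and a route
(oral with probability p_oral). Ailment labels are category-specific, so
triples are unique by construction. A single seeded generator drives the
whole run; identical configs produce byte-identical files.

Numerics: at small α the Dirichlet underflows in linear space, so
preferences are kept as **log-weights** via the Gamma representation
Gamma(a) = Gamma(a+1)·U^(1/a), and without-replacement draws use Gumbel
top-k (exact Plackett–Luce sampling) — the preference ranking stays exact
at any concentration. An informant's distinct-citation count truncates,
with a ledger note, at the pool size and at the preference's *effective
support* (species within 12 orders of magnitude of the modal preference
mass); in the α → 0 limit the support is a single species, so the
degenerate survey has nt = 1 and ICF = 1 exactly. α = 0 itself is treated
as an infinitesimal concentration (the ranking limit: a fixed random
permutation).

Defaults are the study conditions: 208 informants; 16 categories whose
pool sizes equal the published per-category taxa counts and whose
intensities are the published citation counts divided by 208 (≈ 14,037
citations in expectation); a 200-species universe assigned to 87 families
with Zipf-weighted (heavy-tailed) sizes; 27 plant-part and 51
preparation-mode labels; p_oral = 0.848.

A with-replacement "oracle mode" (`with_replacement=True`, optionally
`uniform_weights=True`) exists solely so the closed-form occupancy
expectation E[distinct] = S·(1 − (1 − 1/S)^nur) applies exactly;
`simulate_occupancy` draws it directly for Monte-Carlo checks.

The `GeneratorLedger` records per-category species counts, per-pair
citation counts, attribute tallies, family assignment and truncation
counts while emitting — tests assert ledger = recount for every statistic
the pipeline computes.

What the generator does *not* emulate: informant-level heterogeneity
(age/gender effects), ailment labels shared across categories, correlation
between species and preparation mode, and seasonal/geographic structure.
Passing tests therefore demonstrate correctness of the computations and
the stated statistical contracts, not fidelity to any real community's
knowledge distribution.

## Pipeline and determinism

`run_pipeline` validates (JSON-lines issue report; hard stop without
`--force`, which instead drops the offending rows with a warning), computes
all tables, writes the network exports, renders a markdown report and a
manifest with the package version, seed and SHA-256 input digests — no
timestamps, so reruns are byte-identical. Exit codes: 0 success, 2
validation failure, 1 unexpected error. A `from-counts` mode computes the
ICF table directly from a published (category, nt, nur) CSV, since surveys
publish counts rather than raw reports.

## Problem sizes used in checks

The test suite and acceptance script run on deliberately small synthetic
surveys chosen to estimate each property comfortably: fidelity partition
on 100 surveys of 10 informants × 4 categories; the consensus trend on
200 seeds per concentration in {0.01, 0.1, 1, 10, 100} at 30 informants ×
4 categories (pool 25, λ = 2); occupancy on 20,000 replicates of 40 draws
from a 20-species pool; planted-partition recovery on 100 surveys of 4
blocks × 4 categories (pool 12, 40 informants, 5 % sharing); round trips
on 50 random instances. The full 208-informant default configuration is
exercised directly in the generator tests and the worked example.

## Known limitations

- Published family-share percentages in this literature are sometimes
  internally inconsistent between the species and citation bases; the
  package emits both, labelled, and asserts neither against any single
  printed value.
- Dataset-wide tallies that require the raw survey (total practice count,
  oral-administration share, the FL = 100 species count, distinct part and
  preparation counts) are exercised on synthetic data only.
- No other ethnobotanical indices (use value, RFC, cultural importance)
  and no inferential statistics on ICF differences in this version; no
  fuzzy vernacular-name matching or taxonomic-backbone lookups.
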