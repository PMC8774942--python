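# Methods

## Cohort model and filter cascade

The package models a small case/control exome design: per-sample variant
calls annotated with depth (DP), genotype quality (GQ), consequence class,
population allele frequencies (ExAC and CSVS reference panels), and three
functional predictors (SIFT, PolyPhen humDiv, CADD phred). Filters are
per-call predicates with these defaults:

| parameter | default | meaning |
|---|---|---|
| `dp_min` | 10 reads | minimum per-sample coverage |
| `gq_min` | 30 (phred-like) | minimum genotype quality |
| `maf_max` | 0.005 | rarity bound, applied to each panel independently |
| `cadd_min` | 20 | CADD phred floor (≈ top 1% most deleterious) |
| `excluded_consequences` | {synonymous} | consequence classes removed |
| `missing_prediction_policy` | pass | unscored variants are not excluded |

Decisions made where the design was genuinely open:

- **Boundary semantics.** All thresholds are inclusive (≥ / ≤). The rarity
  bound is ≤ 0.005; both the bound and its inclusivity are configurable.
- **Prioritization rule.** Exclusion is the *disjunction* of failure
  criteria: CADD < 20, or SIFT = tolerated, or PolyPhen = benign. This is
  fixed by the worked DAAM2 p.(K776T) example, where a lone "tolerated"
  call removes a variant that PolyPhen and CADD consider damaging.
  PolyPhen "possibly damaging" is never an exclusion.
- **Missing annotations pass** by default: truncating variants are often
  unscored by SIFT/PolyPhen, and absence of a score is not evidence of
  benignity. A `fail` policy is available for sensitivity analysis.
- **Absent allele frequency = rare.** A variant never observed in a panel
  cannot have a frequency above the bound; the reader maps empty fields to
  "absent", never to 0, so the two are distinguishable downstream even
  though the filter treats them alike.
- **Control subtraction identity** is exact `(chrom, pos, ref, alt)`,
  zygosity-blind, 1-based, on pre-normalized (decomposed, left-aligned)
  input. The reader rejects multi-allelic records rather than guessing a
  decomposition; no re-normalization or liftover is performed.
- **Stage order** is controls → QC → consequence → rarity (→
  prioritization). The three per-call stages commute (property-tested), so
  the order only affects the intermediate counts in the stage report.
- DP/GQ are applied **per sample**, from the VCF FORMAT fields.

## Recurrence

A *carrier* is a distinct case sample with ≥ 1 qualifying variant in a
gene, counted once regardless of variant multiplicity or zygosity;
homozygous carriers are flagged separately. Classification uses carrier
count first (>2 carriers beats any shared-variant structure), then
distinguishes two carriers sharing one variant from two carriers with
distinct variants. A gene can simultaneously have a shared variant and
extra private ones; the `shared_variant` flag is kept independent of the
category so either view of recurrence can be reconstructed. Gene symbols
match case-insensitively, with an optional alias map for synonyms;
unresolvable symbols pass through verbatim with a warning.

The packaged recurrence-table transcription stores the published per-gene
counts as printed. Its per-category arithmetic does not total to the
published overall variant count (270 by our recount vs. 272 stated); the
fixture preserves the table verbatim and the discrepancy is documented
here rather than resolved. The symbol "5-Sep" is likewise kept as printed
(a spreadsheet-mangled SEPT5).

## Gene sets and enrichment

Gene identity is the symbol, case-folded for comparison, first-seen
spelling preserved. Enrichment is the upper-tail hypergeometric
P(X ≥ k) for k query hits in a term of size K, query size n, universe N
(via `scipy.stats.hypergeom`), with Benjamini–Hochberg adjustment across
terms (`statsmodels`). This is a deliberate, generic stand-in for
app-based GO enrichment: terms arrive as flat GMT input and no ontology
structure is used.

The bone/AFF candidate list and the prior study's 34-gene list are not
publicly printed; the package ships a clearly labeled synthetic candidate
list (the 12 published candidates plus canonical bone genes absent from
the recurrence table) and a generator that plants a 9-gene/4-damaging
overlap structure into a synthetic 34-gene prior. These reproduce the
published *structure* of the intersections, not their actual membership.

## Interactome and skeleton extraction

Undirected interactions are stored as arc pairs in a directed graph
(`networkx.DiGraph`), mirroring how symmetric interaction data is usually
fed to shortest-path tooling. Duplicate edges across sources merge with
provenance union. Weights default to 1 (hop counting); an optional
STRING-confidence mode uses `1 − combined_score/1000` clamped to
`[0.001, 1]`, so confident edges are cheap.

For each unordered seed pair, the shortest-path distance comes from
Dijkstra. With `ties="all"` (default) the skeleton is the union of *all*
tied minimum paths, computed exactly from the two-sided distance
criterion: node x lies on a tied path iff d(u,x) + d(x,v) = d(u,v), and
arc (x,y) iff d(u,x) + w(x,y) + d(y,v) = d(u,v) (tolerance 1e-9 relative).
With `ties="one"` a single deterministic path per pair is extracted by
walking the tie DAG and choosing the lexicographically smallest successor.
Both readings of "all pairwise shortest paths" are exposed because the
original tooling's behavior is not determinable; `ties="one"` is always a
subgraph of `ties="all"`. `max_len` bounds the accepted pair distance
(unbounded by default); unreachable or too-far pairs are reported, not
errors. The direct-interaction view is the seed-induced subgraph,
equivalent to a skeleton restricted to distance-1 pairs.

Node annotation maps the gnomAD-style o/e LoF ratio, clamped to [0, 2],
linearly onto a size range (default 10–50; absent → midpoint), so the most
loss-of-function-constrained genes are drawn smallest; border classes mark
why a node is present (mutated in ≥ 2 cases, bone-related, both, other);
the fill color comes from the expression overlay. Export formats are
GraphML and Cytoscape JSON (lossless, round-tripping) and SIF (topology
only). There is no web service or graph database: static files are the
interface, and layout is the consumer's concern.

## Expression overlay

The two-group contrast (treated − untreated, log2 scale) uses the standard
hierarchical variance model: gene-wise residual variance s² on d = n₁+n₂−2
df, prior s₀² with d₀ df, posterior s²_post = (d₀s₀² + ds²)/(d₀ + d), and
moderated t = logfc / (s_post·√(1/n₁+1/n₂)) on d₀ + d df. Hyperparameters
are estimated by method of moments on z = log s²: Var(z) = ψ′(d/2) +
ψ′(d₀/2) gives d₀ by numerically inverting the trigamma (Brent bracketing
on [1e−6, 1e8]), and the mean of z, corrected by the digamma offsets,
gives s₀². When the empirical Var(z) does not exceed ψ′(d/2), d₀ = ∞ and
every gene gets the common variance s₀² with a normal reference
distribution — the correct degenerate limit. Moderation is re-implemented
from these standard formulas (no external DE package is called); the
d₀ → ∞ closed form and recovery of known (d₀, s₀²) from scaled-inverse-χ²
draws serve as its checks.

Preprocessing is deliberately minimal: log2(x+1) unless the matrix is
flagged as already logged, no quantile or array-level normalization
(a warning fires if group medians differ by > 1 log2 unit), no missing
values, two groups only. Which fold change a real osteoclast experiment's
contrast corresponds to (which bisphosphonate arm, which timepoint) is a
property of the supplied sample sheet, not of this module.

The fill scale is piecewise-linear in logfc: dark blue (#00008b) at −cap,
yellow at 0, red at +cap, clamped outside, neutral grey for genes without
expression data; cap defaults to 1 log2 unit. The scale encodes the fold
change, not a test statistic.

## Synthetic generators

Each generator owns its random stream (`numpy` Generator seeded per
component), so reconfiguring one does not perturb the others, and reruns
are byte-identical.

- **Cohort** (defaults: 12 cases, 4 controls, 300 genes, 8 planted
  recurrent genes, 200 background variants, DP centered near deep-coverage
  values): plants one variant failing each filter individually, case
  variants duplicated into controls, and recurrent genes of every
  category — including a 4-variants/3-carriers gene and a
  3-carriers/one-homozygote gene with an extra SIFT-tolerated carrier.
  Ground truth is recorded by an independent predicate recount at
  generation time, and the planted patterns are self-checked before the
  fixture is returned.
- **Interactome**: `planted_paths` joins every seed pair by a unique
  geodesic of configured length through fresh intermediates, then adds
  background edges under rejection sampling that verifies, after every
  candidate edge, that each planted geodesic is still the unique shortest
  path (uniqueness is guaranteed, not probabilistic). Erdős–Rényi and
  Barabási–Albert backgrounds are available for oracle testing.
- **Expression**: gene variances drawn scaled-inverse-χ²(d₀, s₀²) (or a
  fixed sd), treated means shifted by planted log2 fold changes.

What the generators do *not* emulate: linkage between variants, realistic
site-frequency spectra, annotation correlation structure (SIFT/PolyPhen/
CADD are drawn independently), interactome degree distributions or hub
structure, and array intensity artifacts. Passing recovery tests therefore
demonstrates the pipeline's correctness on data satisfying its stated
assumptions, not robustness to the full messiness of real cohorts.

## Problem sizes used in the test suite

Oracle-equivalence suites run at sizes chosen to make exhaustive checks
exact: shortest-path distances on 100 random graphs of 20–200 nodes
against an independent sparse-graph implementation (BFS for unit weights,
Floyd–Warshall for random positive weights); tied-path unions and skeleton
minimality by exhaustive simple-path enumeration on ≤ 12-node graphs;
planted-geodesic recovery on 50 simulated interactomes; hypergeometric
tails against exact rational enumeration for every instance with N ≤ 20;
differential-expression recovery at 1,000 genes (sign and mean of a
planted logfc = 2 at sd = 0.5, n = 5+5) and hyperparameter recovery at
2,000 genes; filter-cascade algebraic properties on ~1,000 randomized
inputs.

## Known limitations

- Annotation values (SIFT/PolyPhen/CADD, allele frequencies) are inputs,
  never computed; there is no alignment, calling, normalization or
  liftover.
- No burden statistic: with 12 cases and 4 controls no calibrated
  case/control rate test is defined, so recurrence counting is descriptive.
- Cross-namespace gene identity (Entrez/Ensembl) is out of scope beyond a
  simple alias map.
- The real cohort's variant tables, the curated bone-gene list, the prior
  study's list and the original interactome release are unavailable, so
  all quantitative end-to-end claims are made on fixtures and synthetic
  data with planted truth.
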