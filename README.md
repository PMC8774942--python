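# affnet

Rare-variant filtering, cross-patient gene recurrence, and seed-gene
interaction-subnetwork extraction for small case/control exome cohorts —
built around the genetics of **atypical femoral fractures (AFF)**, the rare
fragility fractures of the subtrochanteric/diaphyseal femur associated with
long-term bisphosphonate (BP) treatment.

## Who this is for

Groups analyzing small, deeply sequenced cohorts (here: 12 AFF cases and 4
BP-treated controls, whole-exome at ~140×) under a multigenic
susceptibility model: no single causal gene is expected, so the analysis
looks for *accumulations* of rare damaging variants recurring across
patients, anchors them in known bone-biology genes, and asks how the
candidates interact.

## The analysis chain

1. **Filter cascade** (`affnet.variants`). Per-sample annotated calls pass
   through: control subtraction (any variant seen in a control, at any
   zygosity, is removed by exact `(chrom, pos, ref, alt)` identity), then
   genotype QC (DP ≥ 10, GQ ≥ 30), synonymous exclusion, and population
   rarity (MAF ≤ 0.005 in both the ExAC and CSVS panels; an allele absent
   from a panel counts as rare). The three per-call stages commute.
2. **Damaging-variant prioritization**. A variant is retained only if
   CADD ≥ 20 **and** SIFT ≠ tolerated **and** PolyPhen (humDiv) ≠ benign —
   exclusion is a disjunction, so a single "tolerated" call drops a variant
   even when the other predictors disagree. "Possibly damaging" is kept;
   unscored variants pass by default (configurable).
3. **Gene recurrence** (`affnet.recurrence`). Survivors aggregate per gene;
   a *carrier* is a distinct case with ≥ 1 qualifying variant (counted once
   regardless of multiplicity or zygosity). Genes are classified as
   two-cases/one-shared-variant, two-cases/two-variants,
   more-than-two-cases, or singleton.
4. **Gene sets** (`affnet.genesets`). Intersection with a bone/AFF
   candidate list, overlap with a prior study's gene list, and a
   hypergeometric over-representation test with Benjamini–Hochberg
   adjustment.
5. **Interactome** (`affnet.interactome`). BioGRID-tab-like and
   STRING-link-like edge lists merge into a bidirected graph; for every
   unordered pair of seed genes Dijkstra shortest paths are computed and
   their union (all tied paths, or one deterministic path per pair) forms
   the *skeleton subnetwork*. Nodes carry gnomAD-style o/e LoF sizes,
   constraint-outlier flags and an expression fill; export to GraphML, SIF
   or Cytoscape JSON.
6. **Expression overlay** (`affnet.expression`). Two-group (BP-treated vs.
   untreated osteoclast precursors) differential expression with
   empirical-Bayes variance moderation: s²_post = (d0·s0² + d·s²)/(d0 + d),
   moderated t on d0 + d df, hyperparameters by method of moments on
   log s². Log-fold-changes map onto a red–yellow–dark-blue fill scale.
7. **Synthetic data** (`affnet.simulate`). Seed-deterministic generators
   for cohorts, interactomes with planted unique geodesics, and expression
   matrices — each with recorded ground truth for exact recovery checks.

## Worked example

The two Wnt-pathway genes that anchor the candidate network come packaged
as a variant fixture (protein notation real, coordinates synthetic):

```python
from affnet.fixtures import s31_variant_calls
from affnet.variants import prioritize_damaging
from affnet.recurrence import aggregate_by_gene, recurrence_report

calls = prioritize_damaging(s31_variant_calls())
cases = sorted({c.sample_id for c in s31_variant_calls()})
records = aggregate_by_gene(calls, cases)
print("\n".join(recurrence_report(records).listing))
```

prints

```
DAAM2	3 (3, one homoz)
LRP5	4 (3)
```

i.e. after prioritization DAAM2 retains 3 variants in 3 carriers (one
homozygous — the fourth carrier's p.(K776T) is dropped because SIFT calls
it tolerated, although PolyPhen and CADD consider it damaging), and LRP5
has 4 variants in 3 carriers (one patient carries two). Intersecting the
132 recurrently mutated genes with the packaged bone/AFF candidate list
yields exactly the 12 candidate genes (CUL7, DAAM2, DNAH10, DNAH12, LAMA1,
LRP5, MEX3D, PTH1R, SLC34A3, SPTBN1, TNRC6B, TNXB).

An end-to-end synthetic run (cohort → cascade → recurrence → candidate
intersection → skeleton → annotated export, verified against planted
truth) is one command:

```bash
affnet pipeline --outdir run/ --seed 11
```

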