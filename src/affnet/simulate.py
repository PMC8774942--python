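"""Synthetic fixture generators with recorded ground truth.

Every generator is seed-deterministic and records the fate of everything
it plants, so downstream recovery can be checked exactly:

- :func:`simulate_cohort` emulates the cohort structure of a small
  case/control exome study (12 cases, 4 controls by default) and plants
  (i) variants that fail each filter individually, (ii) case variants
  duplicated into controls, and (iii) recurrent genes of every category,
  including a multi-variant carrier and a homozygous carrier pattern;
- :func:`simulate_interactome` builds random or planted-geodesic
  interactomes where each seed pair is joined by a unique shortest path
  whose intermediates are known;
- :func:`simulate_expression` draws gene variances from a
  scaled-inverse-chi-square prior and plants log2 fold changes.

Ground truth is computed by an independent recount (plain predicate scans
and dictionary counting), not by the pipeline under test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import GeneSet
from .interactome import InteractionEdge
from .expression import ExpressionMatrix
from .variants import (Cohort, Consequence, FilterConfig, PolyphenCall,
                       SiftCall, VariantCall, Zygosity)

__all__ = [
    "CohortSimConfig",
    "NetworkSimConfig",
    "CohortSim",
    "NetworkSim",
    "ExpressionSim",
    "simulate_cohort",
    "simulate_interactome",
    "simulate_expression",
]


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Study-shaped cohort simulation parameters.

    Defaults mirror the cohort the pipeline is designed for: 12 cases and
    4 controls, deep exome coverage (DP around 140), rare qualifying
    variants concentrated in a handful of recurrent genes.
    """

    n_cases: int = 12
    n_controls: int = 4
    n_genes: int = 300
    n_planted_recurrent: int = 8
    fraction_shared_variant: float = 0.3
    n_background_variants: int = 200
    homozygote_rate: float = 0.05
    mean_depth: float = 140.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_genes) < 0 or self.n_planted_recurrent < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.fraction_shared_variant, self.homozygote_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        # planted recurrent genes + LRP5/DAAM2 patterns + per-filter failure
        # genes all need their own symbol
        if self.n_planted_recurrent + 20 > self.n_genes:
            raise ValueError("n_genes too small for the planted structure")


@dataclass
class CohortSim:
    cohort: Cohort
    config: CohortSimConfig
    surviving_variant_ids: set  # (sample, chrom, pos, ref, alt) after full cascade
    recurrent_genes_by_category: dict[str, list[str]]
    planted_multi_variant_gene: str  # 4 variants / 3 carriers pattern
    planted_homozygote_gene: str     # 3 carriers, one homozygous (+1 tolerated carrier)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .variants import write_variant_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"variants": outdir / "cohort_variants.tsv",
                 "cases": outdir / "cases.txt",
                 "controls": outdir / "controls.txt",
                 "truth": outdir / "cohort_truth.json"}
        write_variant_table(self.cohort.calls, paths["variants"])
        paths["cases"].write_text("\n".join(self.cohort.cases) + "\n")
        paths["controls"].write_text("\n".join(self.cohort.controls) + "\n")
        truth = {
            "surviving_variant_ids": sorted(map(list, self.surviving_variant_ids)),
            "recurrent_genes_by_category": self.recurrent_genes_by_category,
            "planted_multi_variant_gene": self.planted_multi_variant_gene,
            "planted_homozygote_gene": self.planted_homozygote_gene,
        }
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
        return paths


def _passing_call(rng: np.random.Generator, sample: str, gene: str, chrom: str,
                  pos: int, zyg: Zygosity = Zygosity.heterozygous,
                  ref: str = "A", alt: str = "G") -> VariantCall:
    """A call that survives every filter and the prioritization rule."""
    return VariantCall(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        zygosity=zyg,
        depth=int(rng.integers(60, 220)),
        genotype_quality=int(rng.integers(60, 100)),
        consequence=Consequence.missense,
        maf_exac=float(rng.uniform(0, 0.004)) if rng.random() < 0.7 else None,
        maf_csvs=float(rng.uniform(0, 0.004)) if rng.random() < 0.5 else None,
        sift_call=SiftCall.deleterious,
        polyphen_call=(PolyphenCall.probably_damaging if rng.random() < 0.7
                       else PolyphenCall.possibly_damaging),
        cadd_phred=float(rng.uniform(20.5, 40)),
    )


def _survives(call: VariantCall, control_ids: set, cfg: FilterConfig) -> bool:
    """Independent predicate recount used to record ground truth."""
    if call.variant_id in control_ids:
        return False
    if call.depth < cfg.dp_min or call.genotype_quality < cfg.gq_min:
        return False
    if call.consequence in cfg.excluded_consequences:
        return False
    if call.maf_exac is not None and call.maf_exac > cfg.maf_max:
        return False
    if call.maf_csvs is not None and call.maf_csvs > cfg.maf_max:
        return False
    if call.cadd_phred is not None and call.cadd_phred < cfg.cadd_min:
        return False
    if call.sift_call is SiftCall.tolerated:
        return False
    if call.polyphen_call is PolyphenCall.benign:
        return False
    return True


def simulate_cohort(cfg: CohortSimConfig) -> CohortSim:
    rng = np.random.default_rng(cfg.seed)
    cases = [f"CASE{i + 1:02d}" for i in range(cfg.n_cases)]
    controls = [f"CTRL{i + 1:02d}" for i in range(cfg.n_controls)]
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    calls: list[VariantCall] = []
    pos_counter = [1000]

    def next_pos() -> int:
        pos_counter[0] += int(rng.integers(50, 500))
        return pos_counter[0]

    gene_iter = iter(genes)

    # -- pattern 1: multi-variant carrier (4 variants, 3 carriers) ----------
    g_multi = next(gene_iter)
    s1, s2, s3 = rng.choice(cases, size=3, replace=False)
    calls += [
        _passing_call(rng, s1, g_multi, "chr1", next_pos()),
        _passing_call(rng, s2, g_multi, "chr1", next_pos()),
        _passing_call(rng, s3, g_multi, "chr1", next_pos()),
        _passing_call(rng, s3, g_multi, "chr1", next_pos()),
    ]

    # -- pattern 2: 3 carriers one homozygous, plus a 4th carrier whose
    #    variant is SIFT-tolerated (dropped at prioritization) -------------
    g_hom = next(gene_iter)
    h1, h2, h3, h4 = rng.choice(cases, size=4, replace=False)
    calls += [
        _passing_call(rng, h1, g_hom, "chr2", next_pos(), zyg=Zygosity.homozygous),
        _passing_call(rng, h2, g_hom, "chr2", next_pos()),
        _passing_call(rng, h3, g_hom, "chr2", next_pos()),
    ]
    tol = _passing_call(rng, h4, g_hom, "chr2", next_pos())
    calls.append(VariantCall(**{**tol.__dict__, "sift_call": SiftCall.tolerated}))

    # -- planted recurrent genes across categories --------------------------
    # every category is represented: fraction_shared_variant of the planted
    # genes share one variant between two cases; the rest alternate between
    # two-distinct-variant pairs and >2-carrier genes
    n_shared = max(1, round(cfg.fraction_shared_variant * cfg.n_planted_recurrent)) \
        if cfg.n_planted_recurrent else 0
    for i in range(cfg.n_planted_recurrent):
        g = next(gene_iter)
        chrom = f"chr{3 + i % 5}"
        if i < n_shared:
            # one shared variant in two cases
            a, b = rng.choice(cases, size=2, replace=False)
            base = _passing_call(rng, a, g, chrom, next_pos())
            calls.append(base)
            calls.append(VariantCall(**{**base.__dict__, "sample_id": b}))
        elif i % 2 == 0:
            a, b = rng.choice(cases, size=2, replace=False)
            calls.append(_passing_call(rng, a, g, chrom, next_pos()))
            calls.append(_passing_call(rng, b, g, chrom, next_pos()))
        else:
            for s in rng.choice(cases, size=3, replace=False):
                calls.append(_passing_call(rng, s, g, chrom, next_pos()))

    # -- one variant failing each individual filter -------------------------
    def failing(gene: str, **overrides) -> VariantCall:
        base = _passing_call(rng, str(rng.choice(cases)), gene, "chr9", next_pos())
        return VariantCall(**{**base.__dict__, **overrides})

    calls.append(failing(next(gene_iter), depth=int(rng.integers(0, 10))))
    calls.append(failing(next(gene_iter), genotype_quality=int(rng.integers(0, 30))))
    calls.append(failing(next(gene_iter), consequence=Consequence.synonymous))
    calls.append(failing(next(gene_iter), maf_exac=float(rng.uniform(0.006, 0.2))))
    calls.append(failing(next(gene_iter), maf_csvs=float(rng.uniform(0.006, 0.2))))
    calls.append(failing(next(gene_iter), cadd_phred=float(rng.uniform(0, 19.9))))
    calls.append(failing(next(gene_iter), sift_call=SiftCall.tolerated))
    calls.append(failing(next(gene_iter), polyphen_call=PolyphenCall.benign))

    # -- case variants duplicated into controls (control subtraction) -------
    control_calls: list[VariantCall] = []
    for _ in range(3):
        g = next(gene_iter)
        case_call = _passing_call(rng, str(rng.choice(cases)), g, "chr10", next_pos())
        calls.append(case_call)
        control_calls.append(VariantCall(**{
            **case_call.__dict__,
            "sample_id": str(rng.choice(controls)),
            "zygosity": Zygosity.heterozygous,
        }))
    # private control-only variants
    for _ in range(5):
        control_calls.append(
            _passing_call(rng, str(rng.choice(controls)), str(rng.choice(genes)),
                          "chr11", next_pos()))

    # -- random background case calls in the remaining gene pool ------------
    background_pool = list(gene_iter)
    for _ in range(cfg.n_background_variants):
        g = str(rng.choice(background_pool))
        s = str(rng.choice(cases))
        zyg = Zygosity.homozygous if rng.random() < cfg.homozygote_rate else Zygosity.heterozygous
        base = _passing_call(rng, s, g, "chr12", next_pos(), zyg=zyg)
        overrides = {}
        r = rng.random()
        if r < 0.10:
            overrides["depth"] = int(rng.integers(0, 10))
        elif r < 0.20:
            overrides["consequence"] = Consequence.synonymous
        elif r < 0.28:
            overrides["maf_exac"] = float(rng.uniform(0.006, 0.3))
        elif r < 0.36:
            overrides["cadd_phred"] = float(rng.uniform(0, 19.5))
        elif r < 0.44:
            overrides["sift_call"] = SiftCall.tolerated
        elif r < 0.50:
            overrides["polyphen_call"] = PolyphenCall.benign
        calls.append(VariantCall(**{**base.__dict__, **overrides}))

    cohort = Cohort(cases=cases, controls=controls, calls=calls + control_calls)

    # -- ground truth by independent recount --------------------------------
    filt = FilterConfig()
    control_ids = {c.variant_id for c in control_calls}
    survivors = [c for c in calls if _survives(c, control_ids, filt)]
    surviving_ids = {(c.sample_id, *c.variant_id) for c in survivors}

    per_gene: dict[str, dict] = {}
    for c in survivors:
        g = per_gene.setdefault(c.gene, {"carriers": set(), "per_variant": {}})
        g["carriers"].add(c.sample_id)
        g["per_variant"].setdefault(c.variant_id, set()).add(c.sample_id)
    by_cat: dict[str, list[str]] = {
        "two_cases_two_variants": [], "two_cases_one_variant": [],
        "more_than_two_cases": [], "singleton": [],
    }
    for gname in sorted(per_gene):
        g = per_gene[gname]
        n = len(g["carriers"])
        shared = any(len(s) >= 2 for s in g["per_variant"].values())
        if n > 2:
            cat = "more_than_two_cases"
        elif n == 2:
            cat = "two_cases_one_variant" if shared else "two_cases_two_variants"
        else:
            cat = "singleton"
        by_cat[cat].append(gname)

    # self-check: the planted patterns must have survived intact
    assert len(per_gene[g_multi]["per_variant"]) == 4 and len(per_gene[g_multi]["carriers"]) == 3
    assert len(per_gene[g_hom]["per_variant"]) == 3 and len(per_gene[g_hom]["carriers"]) == 3

    return CohortSim(cohort=cohort, config=cfg,
                     surviving_variant_ids=surviving_ids,
                     recurrent_genes_by_category=by_cat,
                     planted_multi_variant_gene=g_multi,
                     planted_homozygote_gene=g_hom)


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

@dataclass
class NetworkSimConfig:
    n_nodes: int = 60           # background nodes (planted models add their own)
    model: str = "planted_paths"  # erdos_renyi | barabasi_albert | planted_paths
    edge_density: float = 0.05    # ER edge probability / BA attachment fraction
    n_seeds: int = 4
    planted_path_lengths: Sequence[int] = (2, 3, 4)
    n_background_edges: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("erdos_renyi", "barabasi_albert", "planted_paths"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if any(l < 1 for l in self.planted_path_lengths):
            raise ValueError("planted path lengths must be >= 1")


@dataclass
class NetworkSim:
    edges: list[InteractionEdge]
    seeds: GeneSet
    config: NetworkSimConfig
    planted_intermediates: dict[tuple[str, str], list[str]]  # unique geodesic per pair

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"edges": outdir / "interactome_edges.tsv",
                 "seeds": outdir / "seed_genes.txt",
                 "truth": outdir / "network_truth.json"}
        lines = ["symbol_a\tsymbol_b"]
        lines += [f"{e.source}\t{e.target}" for e in self.edges]
        paths["edges"].write_text("\n".join(lines) + "\n")
        paths["seeds"].write_text("\n".join(self.seeds.sorted()) + "\n")
        truth = {f"{a}|{b}": inter for (a, b), inter in
                 sorted(self.planted_intermediates.items())}
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
        return paths


def _geodesic_intact(g: nx.Graph, seeds: Sequence[str],
                     planted: dict[tuple[str, str], list[str]]) -> bool:
    """Each planted pair keeps its original distance and a unique geodesic."""
    for (a, b), inter in planted.items():
        want = len(inter) + 1
        try:
            paths = list(nx.all_shortest_paths(g, a, b))
        except nx.NetworkXNoPath:
            return False
        if len(paths) != 1 or len(paths[0]) - 1 != want:
            return False
        if paths[0][1:-1] != inter:
            return False
    return True


def simulate_interactome(cfg: NetworkSimConfig) -> NetworkSim:
    rng = np.random.default_rng(cfg.seed)
    if cfg.model in ("erdos_renyi", "barabasi_albert"):
        n = max(cfg.n_nodes, cfg.n_seeds)
        if cfg.model == "erdos_renyi":
            raw = nx.gnp_random_graph(n, cfg.edge_density, seed=int(rng.integers(2**31)))
        else:
            m = max(1, int(round(cfg.edge_density * n)))
            raw = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
        mapping = {i: f"N{i + 1:03d}" for i in raw.nodes}
        raw = nx.relabel_nodes(raw, mapping)
        edges = [InteractionEdge(u, v, origin="custom") for u, v in sorted(raw.edges)]
        seeds = GeneSet(name="sim_seeds",
                        symbols=sorted(mapping.values())[:cfg.n_seeds],
                        provenance=f"{cfg.model} simulation")
        return NetworkSim(edges=edges, seeds=seeds, config=cfg, planted_intermediates={})

    # planted_paths: unique geodesic per seed pair through fresh intermediates
    seeds = [f"S{i + 1}" for i in range(cfg.n_seeds)]
    g = nx.Graph()
    g.add_nodes_from(seeds)
    planted: dict[tuple[str, str], list[str]] = {}
    lengths = list(cfg.planted_path_lengths)
    li = 0
    for i, a in enumerate(seeds):
        for b in seeds[i + 1:]:
            L = lengths[li % len(lengths)]
            li += 1
            inter = [f"P_{a}_{b}_{t + 1}" for t in range(L - 1)]
            chain = [a, *inter, b]
            g.add_edges_from(zip(chain, chain[1:]))
            planted[(a, b)] = inter
    if not _geodesic_intact(g, seeds, planted):
        # seed pairs at planted length 1 can shortcut longer planted paths
        # only if lengths are wildly unbalanced; treat as a config error
        raise ValueError("planted path lengths are mutually inconsistent "
                         "(one planted path shortcuts another); use closer lengths")

    background = [f"B{j + 1:03d}" for j in range(cfg.n_nodes)]
    g.add_nodes_from(background)
    all_nodes = sorted(g.nodes)
    added, attempts = 0, 0
    budget = 60 * cfg.n_background_edges + 100
    while added < cfg.n_background_edges:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                "background-edge rejection budget exhausted; "
                "lower n_background_edges or raise n_nodes")
        u, v = rng.choice(all_nodes, size=2, replace=False)
        if g.has_edge(u, v):
            continue
        g.add_edge(u, v)
        if _geodesic_intact(g, seeds, planted):
            added += 1
        else:
            g.remove_edge(u, v)

    edges = [InteractionEdge(u, v, origin="custom") for u, v in sorted(g.edges)]
    seed_set = GeneSet(name="sim_seeds", symbols=seeds,
                       provenance="planted-geodesic simulation")
    return NetworkSim(edges=edges, seeds=seed_set, config=cfg,
                      planted_intermediates=planted)


# ---------------------------------------------------------------------------
# Prior-study stand-in
# ---------------------------------------------------------------------------

def synthetic_prior_study(
    all_mutated: GeneSet,
    damaging: GeneSet,
    n_total: int = 34,
    n_overlap: int = 9,
    n_damaging: int = 4,
    seed: int = 0,
) -> GeneSet:
    """Synthetic stand-in for an earlier study's gene list.

    The real list is externally sourced and unavailable, so this plants a
    known overlap structure: ``n_overlap`` of its ``n_total`` genes occur in
    ``all_mutated``, of which ``n_damaging`` also occur in ``damaging``
    (which must be a subset of ``all_mutated``).  The remainder are fresh
    ``PRIOR_xx`` symbols.
    """
    if n_damaging > n_overlap or n_overlap > n_total:
        raise ValueError("need n_damaging <= n_overlap <= n_total")
    rng = np.random.default_rng(seed)
    damaging_pool = sorted(s for s in damaging.sorted() if s in all_mutated)
    nondamaging_pool = sorted(s for s in all_mutated.sorted() if s not in damaging)
    if len(damaging_pool) < n_damaging or len(nondamaging_pool) < n_overlap - n_damaging:
        raise ValueError("source sets too small for the requested overlap structure")
    picked = list(rng.choice(damaging_pool, size=n_damaging, replace=False))
    picked += list(rng.choice(nondamaging_pool, size=n_overlap - n_damaging, replace=False))
    fresh = [f"PRIOR_{i + 1:02d}" for i in range(n_total - n_overlap)]
    return GeneSet(name="prior_study_34", symbols=sorted(picked) + fresh,
                   provenance=f"synthetic stand-in (seed={seed})")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    matrix: ExpressionMatrix
    planted_logfc: dict[str, float]
    true_variances: dict[str, float]
    d0: float
    s0_sq: float

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"expression": outdir / "expression.tsv",
                 "samples": outdir / "sample_sheet.tsv",
                 "truth": outdir / "expression_truth.json"}
        self.matrix.values.to_csv(paths["expression"], sep="\t", index_label="gene")
        sheet = pd.DataFrame({"sample": list(self.matrix.groups),
                              "group": list(self.matrix.groups.values())})
        sheet.to_csv(paths["samples"], sep="\t", index=False)
        truth = {"planted_logfc": self.planted_logfc,
                 "d0": self.d0, "s0_sq": self.s0_sq}
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
        return paths


def simulate_expression(
    n_genes: int,
    n_per_group: int,
    planted: Optional[Mapping[str, float]] = None,
    sd: Optional[float] = None,
    d0: float = 4.0,
    s0_sq: float = 0.25,
    baseline_mean: float = 7.0,
    seed: int = 0,
) -> ExpressionSim:
    """Two-group log2-scale expression with planted fold changes.

    Gene standard deviations are either fixed (``sd``) or drawn from the
    scaled-inverse-chi-square prior ``sigma^2 ~ d0*s0_sq / chi2(d0)``; the
    treated-group mean is shifted by the planted logfc.  ``planted`` maps
    gene name -> logfc; gene names default to ``G0001`` ...
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if s0_sq <= 0 or (sd is not None and sd <= 0):
        raise ValueError("sd and s0_sq must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    planted = dict(planted or {})
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside the simulated set: {sorted(unknown)}")

    if sd is not None:
        sigma2 = np.full(n_genes, sd ** 2)
    else:
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n_genes)

    base = rng.normal(baseline_mean, 1.0, size=n_genes)
    lfc = np.array([planted.get(g, 0.0) for g in genes])
    t_samples = [f"T{i + 1}" for i in range(n_per_group)]
    u_samples = [f"U{i + 1}" for i in range(n_per_group)]
    sig = np.sqrt(sigma2)[:, None]
    X_t = rng.normal((base + lfc)[:, None], sig, size=(n_genes, n_per_group))
    X_u = rng.normal(base[:, None], sig, size=(n_genes, n_per_group))
    values = pd.DataFrame(np.hstack([X_t, X_u]), index=genes,
                          columns=t_samples + u_samples)
    groups = {s: "treated" for s in t_samples} | {s: "untreated" for s in u_samples}
    matrix = ExpressionMatrix(values=values, groups=groups, logged=True)
    return ExpressionSim(matrix=matrix, planted_logfc={g: float(planted.get(g, 0.0))
                                                       for g in planted},
                         true_variances=dict(zip(genes, map(float, sigma2))),
                         d0=d0, s0_sq=s0_sq)
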