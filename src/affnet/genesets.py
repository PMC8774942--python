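"""Gene-set algebra, list/GMT IO and hypergeometric enrichment.

Gene identity is the HGNC-style symbol, compared case-insensitively
throughout; the first-seen spelling of each symbol is preserved for output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentRow",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "intersect",
    "overlap_with_prior",
    "PriorOverlapReport",
    "hypergeom_upper_tail",
    "hypergeom_enrichment",
]


@dataclass
class GeneSet:
    """Named, ordered, case-insensitively deduplicated set of gene symbols."""

    name: str
    symbols: Sequence[str] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        seen: dict[str, str] = {}
        for s in self.symbols:
            seen.setdefault(s.casefold(), s)
        self.symbols = list(seen.values())
        self._keys = set(seen)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._keys

    def __iter__(self):
        return iter(self.symbols)

    def sorted(self) -> list[str]:
        return sorted(self.symbols, key=str.casefold)

    def union(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(name=f"{self.name}∪{other.name}",
                       symbols=sorted(list(self.symbols) + list(other.symbols), key=str.casefold))

    def difference(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(name=f"{self.name}\\{other.name}",
                       symbols=[s for s in self.sorted() if s not in other])


def intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    """Case-insensitive intersection, lexicographic order, name 'a∩b'."""
    return GeneSet(name=f"{a.name}∩{b.name}",
                   symbols=[s for s in a.sorted() if s in b],
                   provenance=f"intersection of {a.name} and {b.name}")


def read_gene_list(path: str | Path, name: Optional[str] = None) -> GeneSet:
    """One symbol per line; '#' starts a comment; blank lines ignored."""
    path = Path(path)
    symbols = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return GeneSet(name=name or path.stem, symbols=symbols, provenance=str(path))


def write_gene_list(geneset: GeneSet, path: str | Path) -> None:
    lines = [f"# {geneset.name}"]
    if geneset.provenance:
        lines.append(f"# {geneset.provenance}")
    lines.extend(geneset.sorted())
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: tab-separated lines of (term, description, symbol, symbol, ...)."""
    terms = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line {ln} has fewer than 3 fields")
        terms.append(GeneSet(name=parts[0], symbols=parts[2:], provenance=parts[1]))
    return terms


# ---------------------------------------------------------------------------
# Prior-study overlap
# ---------------------------------------------------------------------------

@dataclass
class PriorOverlapReport:
    overlap: GeneSet           # genes mutated in both studies
    damaging_overlap: GeneSet  # overlap genes whose variants passed prioritization


def overlap_with_prior(all_mutated: GeneSet, prior: GeneSet, damaging: GeneSet) -> PriorOverlapReport:
    """Cross-study replication: genes mutated in both cohorts, and the subset
    whose variants in this cohort were predicted damaging."""
    if len(prior) == 0:
        logger.warning("prior gene list is empty; overlap will be empty")
    overlap = intersect(all_mutated, prior)
    overlap.name = "prior_overlap"
    flagged = intersect(overlap, damaging)
    flagged.name = "prior_overlap_damaging"
    return PriorOverlapReport(overlap=overlap, damaging_overlap=flagged)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    term: str
    k: int  # query genes in the term
    K: int  # term size
    n: int  # query size
    N: int  # universe size
    p_value: float
    q_value: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    query: GeneSet, terms: Sequence[GeneSet], universe: GeneSet
) -> list[EnrichmentRow]:
    """Over-representation of each term in the query, with BH adjustment.

    The query and every term must be subsets of the universe.  Rows come
    back sorted by p-value (ties broken by term name).
    """
    offenders = [s for s in query if s not in universe]
    if offenders:
        raise ValueError(f"query genes outside universe: {sorted(offenders, key=str.casefold)}")
    for t in terms:
        out = [s for s in t if s not in universe]
        if out:
            raise ValueError(f"term {t.name!r} genes outside universe: {sorted(out, key=str.casefold)}")

    N, n = len(universe), len(query)
    rows = []
    for t in terms:
        k = len(intersect(query, t))
        rows.append(EnrichmentRow(term=t.name, k=k, K=len(t), n=n, N=N,
                                  p_value=hypergeom_upper_tail(k, len(t), n, N),
                                  q_value=float("nan")))
    if rows:
        _, q, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["term", "k", "K", "n", "N", "p_value", "q_value"])
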