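"""Cross-patient gene recurrence: carrier counting and category assignment.

After filtering, surviving case variants are aggregated per gene.  A
*carrier* is a distinct case sample harboring at least one qualifying
variant in the gene, counted once regardless of how many variants it
carries or of zygosity; homozygous carriers are flagged.  Genes are then
classified by how the recurrence arose:

- ``two_cases_one_variant``   — exactly two carriers sharing one variant
- ``two_cases_two_variants``  — exactly two carriers, distinct variants
- ``more_than_two_cases``     — three or more carriers
- ``singleton``               — a single carrier
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genesets import GeneSet
from .variants import VariantCall, Zygosity

logger = logging.getLogger(__name__)

__all__ = [
    "RecurrenceCategory",
    "GeneRecurrenceRecord",
    "aggregate_by_gene",
    "classify",
    "recurrent_genes",
    "recurrence_report",
    "write_report",
    "read_report",
]


class RecurrenceCategory(str, enum.Enum):
    two_cases_two_variants = "two_cases_two_variants"
    two_cases_one_variant = "two_cases_one_variant"
    more_than_two_cases = "more_than_two_cases"
    singleton = "singleton"


@dataclass
class GeneRecurrenceRecord:
    gene: str
    variant_ids: frozenset[tuple[str, int, str, str]]
    carrier_ids: frozenset[str]
    homozygous_carrier_ids: frozenset[str]
    shared_variant: bool  # some single variant carried by >= 2 distinct cases

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)

    @property
    def n_homozygous_carriers(self) -> int:
        return len(self.homozygous_carrier_ids)

    @property
    def category(self) -> RecurrenceCategory:
        return classify(self)


def classify(record: GeneRecurrenceRecord) -> RecurrenceCategory:
    """Category from carrier count first, then shared-variant structure."""
    if record.n_carriers > 2:
        return RecurrenceCategory.more_than_two_cases
    if record.n_carriers == 2:
        if record.shared_variant:
            return RecurrenceCategory.two_cases_one_variant
        return RecurrenceCategory.two_cases_two_variants
    return RecurrenceCategory.singleton


def aggregate_by_gene(
    calls: Sequence[VariantCall],
    case_ids: Iterable[str],
    alias_map: Optional[Mapping[str, str]] = None,
) -> list[GeneRecurrenceRecord]:
    """Aggregate case calls per gene into recurrence records.

    Gene symbols are matched case-insensitively; ``alias_map`` (old symbol ->
    canonical symbol, case-insensitive keys) resolves synonyms, and symbols
    it cannot resolve pass through verbatim.  Calls from non-case samples
    raise.  Output order is lexicographic by gene.
    """
    case_set = set(case_ids)
    aliases = {k.casefold(): v for k, v in (alias_map or {}).items()}

    per_gene: dict[str, dict] = {}
    display: dict[str, str] = {}
    for call in calls:
        if call.sample_id not in case_set:
            raise ValueError(f"call from non-case sample {call.sample_id!r}")
        symbol = aliases.get(call.gene.casefold(), call.gene)
        key = symbol.casefold()
        g = per_gene.setdefault(key, {"variants": set(), "carriers": set(),
                                      "hom": set(), "per_variant": {}})
        display.setdefault(key, symbol)
        g["variants"].add(call.variant_id)
        g["carriers"].add(call.sample_id)
        if call.zygosity is Zygosity.homozygous:
            g["hom"].add(call.sample_id)
        g["per_variant"].setdefault(call.variant_id, set()).add(call.sample_id)

    records = []
    for key in sorted(per_gene):
        g = per_gene[key]
        shared = any(len(s) >= 2 for s in g["per_variant"].values())
        records.append(GeneRecurrenceRecord(
            gene=display[key],
            variant_ids=frozenset(g["variants"]),
            carrier_ids=frozenset(g["carriers"]),
            homozygous_carrier_ids=frozenset(g["hom"]),
            shared_variant=shared,
        ))
    return records


def recurrent_genes(records: Sequence[GeneRecurrenceRecord], min_carriers: int = 2) -> GeneSet:
    """Genes with at least ``min_carriers`` distinct case carriers."""
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    symbols = sorted(r.gene for r in records if r.n_carriers >= min_carriers)
    return GeneSet(name=f"recurrent_min{min_carriers}", symbols=symbols,
                   provenance=f"genes with >= {min_carriers} carriers")


def _listing_line(r: GeneRecurrenceRecord) -> str:
    """Table-shaped 'GENE<TAB>N (M[, k homoz])' listing entry."""
    note = ""
    if r.n_homozygous_carriers == 1:
        note = ", one homoz"
    elif r.n_homozygous_carriers > 1:
        note = f", {r.n_homozygous_carriers} homoz"
    return f"{r.gene}\t{r.n_variants} ({r.n_carriers}{note})"


@dataclass
class RecurrenceReport:
    totals: dict[str, int]
    table: pd.DataFrame  # gene, n_variants, n_carriers, n_hom, shared_variant, category
    listing: list[str]


def recurrence_report(records: Sequence[GeneRecurrenceRecord]) -> RecurrenceReport:
    """Summary totals plus a per-gene table and human-readable listing."""
    records = sorted(records, key=lambda r: r.gene.casefold())
    totals = {
        "n_genes": len(records),
        "n_variants": sum(r.n_variants for r in records),
    }
    for cat in RecurrenceCategory:
        totals[f"n_{cat.value}"] = sum(1 for r in records if r.category is cat)
    table = pd.DataFrame(
        [{
            "gene": r.gene,
            "n_variants": r.n_variants,
            "n_carriers": r.n_carriers,
            "n_hom": r.n_homozygous_carriers,
            "shared_variant": r.shared_variant,
            "category": r.category.value,
        } for r in records],
        columns=["gene", "n_variants", "n_carriers", "n_hom", "shared_variant", "category"],
    )
    return RecurrenceReport(totals=totals, table=table,
                            listing=[_listing_line(r) for r in records])


def write_report(records: Sequence[GeneRecurrenceRecord], path: str | Path) -> None:
    recurrence_report(records).table.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the report TSV (summary columns only)."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str})
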