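"""Machine-readable study fixtures: recurrence-table gene lists, the
candidate-gene table, and the worked DAAM2/LRP5 variant enumerations.

These transcriptions let the pipeline's gene-set and recurrence logic be
exercised against the published study's printed results without access to
the (restricted) patient-level sequencing data:

- the 132 genes with rare variants in >= 2 cases after prioritization,
  split into the published categories (two cases / two different variants,
  two cases / one shared variant, more than two cases with per-gene
  variant-and-carrier counts);
- the 12 bone-metabolism/AFF candidate genes;
- the two Wnt-pathway worked examples (DAAM2, LRP5) as full variant rows
  with synthetic genomic coordinates (the publication gives protein-level
  notation only, so chromosome positions here are arbitrary but fixed).

Note: "5-Sep" below is transcribed verbatim from the published table (a
spreadsheet-mangled SEPT5).  The bone/AFF candidate list is a *synthetic
fixture*: the literature list it stands in for is not printed anywhere, so
it is reverse-assembled from the candidate-gene table plus a handful of
canonical bone genes that are deliberately absent from the recurrence
table (so the intersection recovers exactly the 12 candidates).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .genesets import GeneSet
from .variants import (Consequence, PolyphenCall, SiftCall, VariantCall,
                       Zygosity, write_variant_table)

__all__ = [
    "RECURRENT_TWO_CASES_TWO_VARIANTS",
    "RECURRENT_TWO_CASES_ONE_VARIANT",
    "RECURRENT_MORE_THAN_TWO_CASES",
    "recurrence_table_genes",
    "recurrence_table_counts",
    "candidate_table_genes",
    "bone_candidate_genes",
    "worked_example_calls",
    "published_fixtures",
]

# Two AFF cases, two different variants (three published columns merged).
RECURRENT_TWO_CASES_TWO_VARIANTS = [
    "AASS", "ABCA10", "ABCA4", "ABL2", "ADAMTS12", "ANAPC11", "ANK3",
    "ANKRD40", "ARHGEF18", "ARID1B", "ASH1L", "ATAD2", "ATP10B", "BIN1",
    "C10orf54", "C12orf42", "C14orf159", "C17orf107", "C6", "C9orf84",
    "CA9", "CDC42BPG", "CERKL", "CHAMP1", "CLCN2", "CRYBA1", "CTSE",
    "CUL7", "CYYR1", "DAB2IP", "DAW1", "DHX34",
    "DNAH10", "DNAH12", "DNAH6", "DYSF", "EFHB", "EP400", "ERCC5", "FAT4",
    "FBLN7", "FLJ00418", "GBP3", "GPX4", "HK3", "HPS6", "IGFN1", "IGSF10",
    "IGSF22", "KLHL33", "LLGL1", "MEX3D", "MKS1", "MMP20", "MSLNL", "NOD2",
    "NUP153", "OPLAH", "PACSIN2", "PARD6B", "PCDHAC1", "PDE4DIP", "PISD",
    "PLA2G4D",
    "PSD3", "PTH1R", "PYHIN1", "R3HDML", "RET", "RMDN1", "RNF157", "RNF34",
    "RTEL1", "SCN9A", "5-Sep", "SH3BP2", "SHROOM4", "SIRT5", "SLC26A9",
    "SLC2A7", "SLC34A3", "SLC52A2", "SPTBN5", "SRCAP", "TAF15", "TENM4",
    "TJP3", "TMEM143", "TNRC6B", "TOPORS", "TSFM", "TTC14", "ZNF34",
    "ZNF646", "ZNF729", "ZSCAN32",
]

# Two AFF cases sharing one variant.
RECURRENT_TWO_CASES_ONE_VARIANT = [
    "ACADL", "C1orf87", "CD1A", "CITED4", "GBA", "IQSEC3", "NSMAF",
    "PPP2R1B", "SERPINB2", "SPTBN1", "SYDE1", "TNFRSF25", "TRAPPC2L",
    "TRIM32",
]

# More than two AFF cases: gene -> (n_variants, n_carriers, n_homozygous).
RECURRENT_MORE_THAN_TWO_CASES = {
    "C8orf46": (1, 3, 0),
    "CHRNG": (3, 3, 0),
    "DAAM2": (3, 3, 1),
    "DNAH14": (4, 4, 0),
    "DNAH2": (3, 3, 0),
    "DNAH9": (3, 3, 0),
    "FSIP2": (3, 3, 0),
    "HLA-DRB1": (2, 4, 0),
    "HRASLS": (1, 3, 0),
    "IGFLR1": (2, 2, 1),
    "KRT10": (1, 5, 0),
    "LAMA1": (3, 3, 0),
    "LRP5": (4, 3, 0),
    "MRPS12": (1, 3, 0),
    "NEB": (4, 4, 0),
    "OBSCN": (5, 5, 0),
    "TCOF1": (3, 4, 0),
    "TNXB": (3, 3, 0),
    "TTN": (8, 8, 0),
    "UTRN": (3, 3, 0),
    "VEGFB": (1, 3, 0),
    "ZC3H3": (3, 3, 0),
}

_CANDIDATE_GENES = [
    "CUL7", "DAAM2", "DNAH10", "DNAH12", "LAMA1", "LRP5", "MEX3D",
    "PTH1R", "SLC34A3", "SPTBN1", "TNRC6B", "TNXB",
]

# Canonical bone-biology genes, none of which appears in the recurrence
# table; padding for the synthetic stand-in candidate list.
_BONE_EXTRAS = [
    "ALPL", "COL1A1", "CTSK", "FGF23", "GGPS1", "RUNX2", "SOST", "WNT16",
]


def recurrence_table_genes() -> GeneSet:
    """All 132 recurrently mutated genes of the prioritized recurrence table."""
    symbols = (RECURRENT_TWO_CASES_TWO_VARIANTS + RECURRENT_TWO_CASES_ONE_VARIANT
               + list(RECURRENT_MORE_THAN_TWO_CASES))
    return GeneSet(name="recurrence_table_gene_list", symbols=symbols,
                   provenance="published recurrence table transcription")


def recurrence_table_counts() -> pd.DataFrame:
    """The >2-cases column as 'N variants (M carriers[, homoz])' parsed out."""
    rows = [{"gene": g, "n_variants": v, "n_carriers": c, "n_hom": h}
            for g, (v, c, h) in RECURRENT_MORE_THAN_TWO_CASES.items()]
    return pd.DataFrame(rows, columns=["gene", "n_variants", "n_carriers", "n_hom"])


def candidate_table_genes() -> GeneSet:
    """The 12 bone-metabolism/AFF candidate genes."""
    return GeneSet(name="candidate_gene_list", symbols=_CANDIDATE_GENES,
                   provenance="published candidate-gene table transcription")


def bone_candidate_genes() -> GeneSet:
    """Synthetic stand-in for the literature bone/AFF gene list (see module docs)."""
    return GeneSet(name="bone_aff_candidates", symbols=_CANDIDATE_GENES + _BONE_EXTRAS,
                   provenance="synthetic fixture: candidate-gene table + canonical bone genes")


def _call(sample: str, chrom: str, pos: int, ref: str, alt: str, gene: str,
          hgvs: str, zyg: Zygosity, sift: SiftCall, poly: PolyphenCall,
          cadd: float) -> VariantCall:
    return VariantCall(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        hgvs_p=hgvs, zygosity=zyg, depth=120, genotype_quality=99,
        consequence=Consequence.missense, maf_exac=0.0002, maf_csvs=None,
        sift_call=sift, polyphen_call=poly, cadd_phred=cadd,
    )


def worked_example_calls() -> list[VariantCall]:
    """The DAAM2 and LRP5 worked-example variants as full call rows.

    Coordinates are synthetic (fixed placeholders in the genes' genomic
    neighborhoods).  DAAM2 p.(K776T) carries SIFT=tolerated despite damaging
    PolyPhen/CADD calls, so prioritization drops it and the gene aggregates
    to 3 variants in 3 carriers (one homozygous); LRP5 aggregates to 4
    variants in 3 carriers — one carrier holds both p.(R1036Q) and
    p.(S1482L).
    """
    het, hom = Zygosity.heterozygous, Zygosity.homozygous
    dele, tol = SiftCall.deleterious, SiftCall.tolerated
    prob, poss = PolyphenCall.probably_damaging, PolyphenCall.possibly_damaging
    return [
        _call("AFF01", "chr6", 39760001, "C", "T", "DAAM2", "p.(P555L)", hom, dele, prob, 26.1),
        _call("AFF02", "chr6", 39760100, "C", "A", "DAAM2", "p.(P582H)", het, dele, prob, 24.3),
        _call("AFF03", "chr6", 39760500, "G", "T", "DAAM2", "p.(R989L)", het, dele, poss, 27.8),
        _call("AFF04", "chr6", 39760300, "A", "C", "DAAM2", "p.(K776T)", het, tol, prob, 23.5),
        _call("AFF05", "chr11", 68080001, "C", "T", "LRP5", "p.(R258C)", het, dele, prob, 29.4),
        _call("AFF06", "chr11", 68200000, "C", "T", "LRP5", "p.(P1504L)", het, dele, poss, 25.0),
        _call("AFF07", "chr11", 68150000, "G", "A", "LRP5", "p.(R1036Q)", het, dele, prob, 28.2),
        _call("AFF07", "chr11", 68190000, "C", "T", "LRP5", "p.(S1482L)", het, dele, poss, 24.7),
    ]


def published_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle; returns {fixture name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "recurrence_table_genes.txt"
    p.write_text("# recurrence-table gene symbols (all five columns)\n"
                 + "\n".join(recurrence_table_genes().sorted()) + "\n")
    paths["recurrence_table_genes"] = p

    p = outdir / "recurrence_table_counts.tsv"
    recurrence_table_counts().to_csv(p, sep="\t", index=False)
    paths["recurrence_table_counts"] = p

    p = outdir / "candidate_table_genes.txt"
    p.write_text("# bone-metabolism/AFF candidate genes\n"
                 + "\n".join(candidate_table_genes().sorted()) + "\n")
    paths["candidate_table_genes"] = p

    p = outdir / "bone_candidate_genes.txt"
    p.write_text("# SYNTHETIC fixture: candidate genes + canonical bone genes\n"
                 + "\n".join(bone_candidate_genes().sorted()) + "\n")
    paths["bone_candidate_genes"] = p

    p = outdir / "worked_example_variants.tsv"
    write_variant_table(worked_example_calls(), p)
    paths["worked_example_variants"] = p
    return paths
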