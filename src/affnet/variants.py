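"""Variant data model, table IO and the cohort filter cascade.

The pipeline mirrors a small-cohort exome study design: annotated variant
calls from case and control samples are passed through a fixed cascade —
control subtraction, genotype QC (DP/GQ), consequence exclusion, population
rarity (ExAC + CSVS panels) — followed by an optional damaging-variant
prioritization step driven by SIFT / PolyPhen (humDiv) / CADD predictions.

All per-call filters are pure predicates, so QC, consequence and rarity
commute; only control subtraction depends on the cohort as a whole.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Zygosity",
    "Consequence",
    "SiftCall",
    "PolyphenCall",
    "VariantCall",
    "Cohort",
    "FilterConfig",
    "VcfAnnotationConfig",
    "read_variant_table",
    "write_variant_table",
    "qc_filter",
    "consequence_filter",
    "rarity_filter",
    "control_subtract",
    "prioritize_damaging",
    "run_cascade",
    "CascadeResult",
]


class Zygosity(str, enum.Enum):
    heterozygous = "heterozygous"
    homozygous = "homozygous"


class Consequence(str, enum.Enum):
    synonymous = "synonymous"
    missense = "missense"
    stop_gained = "stop_gained"
    frameshift = "frameshift"
    splice = "splice"
    inframe_indel = "inframe_indel"
    other = "other"


class SiftCall(str, enum.Enum):
    deleterious = "deleterious"
    tolerated = "tolerated"


class PolyphenCall(str, enum.Enum):
    probably_damaging = "probably_damaging"
    possibly_damaging = "possibly_damaging"
    benign = "benign"


@dataclass(frozen=True)
class VariantCall:
    """One annotated variant observation in one sample.

    Absent annotations are ``None`` — never 0: a missing population
    frequency means the allele was not observed in the panel, which the
    rarity filter treats as rare, and a missing prediction means the tool
    produced no call for this variant class.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    zygosity: Zygosity
    depth: int
    genotype_quality: int
    consequence: Consequence
    hgvs_p: Optional[str] = None
    maf_exac: Optional[float] = None
    maf_csvs: Optional[float] = None
    sift_call: Optional[SiftCall] = None
    polyphen_call: Optional[PolyphenCall] = None
    cadd_phred: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.genotype_quality < 0:
            raise ValueError(f"genotype_quality must be >= 0, got {self.genotype_quality}")
        for name in ("maf_exac", "maf_csvs"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be >= 0, got {self.cadd_phred}")

    @property
    def variant_id(self) -> tuple[str, int, str, str]:
        """Identity used for control subtraction and recurrence: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Cohort:
    """Case/control sample partition plus all calls observed in either arm."""

    cases: list[str]
    controls: list[str]
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.cases) & set(self.controls)
        if overlap:
            raise ValueError(f"samples in both arms: {sorted(overlap)}")
        known = set(self.cases) | set(self.controls)
        stray = {c.sample_id for c in self.calls} - known
        if stray:
            raise ValueError(f"calls from unknown samples: {sorted(stray)}")

    @property
    def case_calls(self) -> list[VariantCall]:
        cases = set(self.cases)
        return [c for c in self.calls if c.sample_id in cases]

    @property
    def control_calls(self) -> list[VariantCall]:
        controls = set(self.controls)
        return [c for c in self.calls if c.sample_id in controls]


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    Defaults are the cascade premises of the study design: DP >= 10,
    GQ >= 30, synonymous excluded, MAF <= 0.005 in both reference panels,
    CADD >= 20, SIFT 'tolerated' and PolyPhen 'benign' excluded.  A missing
    prediction cannot count as tolerated/benign under the default
    ``missing_prediction_policy='pass'`` (truncating variants are often
    unscored).
    """

    dp_min: int = 10
    gq_min: int = 30
    maf_max: float = 0.005
    cadd_min: float = 20.0
    excluded_consequences: frozenset[Consequence] = frozenset({Consequence.synonymous})
    missing_prediction_policy: str = "pass"  # 'pass' | 'fail'

    def __post_init__(self) -> None:
        if min(self.dp_min, self.gq_min) < 0 or self.maf_max < 0 or self.cadd_min < 0:
            raise ValueError("thresholds must be non-negative")
        if self.maf_max > 1:
            raise ValueError("maf_max must be <= 1")
        if self.missing_prediction_policy not in ("pass", "fail"):
            raise ValueError("missing_prediction_policy must be 'pass' or 'fail'")
        object.__setattr__(self, "excluded_consequences", frozenset(self.excluded_consequences))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "excluded_consequences" in raw:
            raw["excluded_consequences"] = frozenset(
                Consequence(c) for c in raw["excluded_consequences"]
            )
        return cls(**raw)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_p", "zygosity",
    "dp", "gq", "consequence", "maf_exac", "maf_csvs", "sift", "polyphen", "cadd",
]


def _opt_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def _parse_consequence(raw: str) -> Consequence:
    try:
        return Consequence(raw)
    except ValueError:
        logger.warning("unknown consequence %r mapped to 'other'", raw)
        return Consequence.other


def _row_to_call(row: dict[str, str]) -> VariantCall:
    return VariantCall(
        sample_id=row["sample_id"],
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        gene=row["gene"],
        hgvs_p=row["hgvs_p"] or None,
        zygosity=Zygosity(row["zygosity"]),
        depth=int(row["dp"]),
        genotype_quality=int(row["gq"]),
        consequence=_parse_consequence(row["consequence"]),
        maf_exac=_opt_float(row["maf_exac"]),
        maf_csvs=_opt_float(row["maf_csvs"]),
        sift_call=SiftCall(row["sift"]) if row["sift"] else None,
        polyphen_call=PolyphenCall(row["polyphen"]) if row["polyphen"] else None,
        cadd_phred=_opt_float(row["cadd"]),
    )


def _read_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            calls.append(_row_to_call(row))
        except (ValueError, KeyError) as exc:
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: unparseable row at line {i + 2}: {exc}") from exc
    return calls


@dataclass
class VcfAnnotationConfig:
    """Where to find functional annotations in a VCF.

    ``info_key`` names the INFO field holding pipe-delimited, VEP-CSQ-like
    per-variant subfields; ``subfields`` maps our annotation slots to the
    subfield names declared in the VCF header (``Format: A|B|...``).
    """

    info_key: str = "CSQ"
    subfields: dict[str, str] = field(default_factory=lambda: {
        "gene": "SYMBOL",
        "consequence": "Consequence",
        "hgvs_p": "HGVSp",
        "sift": "SIFT",
        "polyphen": "PolyPhen",
        "cadd": "CADD_PHRED",
        "maf_exac": "ExAC_AF",
        "maf_csvs": "CSVS_AF",
    })


_VEP_CONSEQUENCE_MAP = {
    "synonymous_variant": Consequence.synonymous,
    "missense_variant": Consequence.missense,
    "stop_gained": Consequence.stop_gained,
    "frameshift_variant": Consequence.frameshift,
    "splice_acceptor_variant": Consequence.splice,
    "splice_donor_variant": Consequence.splice,
    "splice_region_variant": Consequence.splice,
    "inframe_insertion": Consequence.inframe_indel,
    "inframe_deletion": Consequence.inframe_indel,
}
# plain enum names accepted too
_VEP_CONSEQUENCE_MAP.update({c.value: c for c in Consequence})


def _strip_score(call: str) -> str:
    """'tolerated(0.24)' -> 'tolerated'; VEP appends scores in parentheses."""
    return call.split("(", 1)[0].strip()


def _read_vcf(path: Path, annot: VcfAnnotationConfig) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    header_line = None
    for h in vcf.header_iter():
        info = h.info()
        if info.get("ID") == annot.info_key and "Description" in info:
            header_line = info["Description"]
    field_names: list[str] = []
    if header_line and "Format:" in header_line:
        field_names = [f.strip() for f in header_line.split("Format:", 1)[1].strip(' "').split("|")]

    calls: list[VariantCall] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} — "
                "decompose to one ALT per record before loading"
            )
        raw = rec.INFO.get(annot.info_key)
        ann: dict[str, str] = {}
        if raw is not None and field_names:
            # first annotation block only (one transcript per record expected)
            values = str(raw).split(",")[0].split("|")
            ann = dict(zip(field_names, values))

        def sub(slot: str) -> str:
            return ann.get(annot.subfields.get(slot, ""), "") or ""

        cons_raw = sub("consequence")
        consequence = _VEP_CONSEQUENCE_MAP.get(cons_raw.split("&")[0])
        if consequence is None:
            if cons_raw:
                logger.warning("unknown consequence %r mapped to 'other'", cons_raw)
            consequence = Consequence.other

        sift_raw = _strip_score(sub("sift"))
        poly_raw = _strip_score(sub("polyphen")).replace(" ", "_")
        gts = rec.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        depths = rec.format("DP")
        gqs = rec.format("GQ")
        for i, sample in enumerate(samples):
            if gts[i] not in (1, 3):
                continue
            calls.append(VariantCall(
                sample_id=sample,
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                gene=sub("gene"),
                hgvs_p=sub("hgvs_p") or None,
                zygosity=Zygosity.homozygous if gts[i] == 3 else Zygosity.heterozygous,
                depth=int(depths[i][0]) if depths is not None else 0,
                genotype_quality=int(gqs[i][0]) if gqs is not None else 0,
                consequence=consequence,
                maf_exac=float(ann[annot.subfields["maf_exac"]]) if sub("maf_exac") else None,
                maf_csvs=float(ann[annot.subfields["maf_csvs"]]) if sub("maf_csvs") else None,
                sift_call=SiftCall(sift_raw) if sift_raw else None,
                polyphen_call=PolyphenCall(poly_raw) if poly_raw else None,
                cadd_phred=float(ann[annot.subfields["cadd"]]) if sub("cadd") else None,
            ))
    return calls


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    vcf_annotation: Optional[VcfAnnotationConfig] = None,
) -> list[VariantCall]:
    """Read per-sample variant calls from a flat TSV or an annotated VCF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, vcf_annotation or VcfAnnotationConfig())
    raise ValueError(f"unknown dialect {dialect!r}")


def calls_to_frame(calls: Iterable[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "gene": c.gene,
            "hgvs_p": c.hgvs_p or "", "zygosity": c.zygosity.value,
            "dp": c.depth, "gq": c.genotype_quality,
            "consequence": c.consequence.value,
            "maf_exac": "" if c.maf_exac is None else repr(c.maf_exac),
            "maf_csvs": "" if c.maf_csvs is None else repr(c.maf_csvs),
            "sift": c.sift_call.value if c.sift_call else "",
            "polyphen": c.polyphen_call.value if c.polyphen_call else "",
            "cadd": "" if c.cadd_phred is None else repr(c.cadd_phred),
        })
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls to the flat TSV dialect (empty string = absent)."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def passes_qc(call: VariantCall, cfg: FilterConfig) -> bool:
    return call.depth >= cfg.dp_min and call.genotype_quality >= cfg.gq_min


def passes_consequence(call: VariantCall, cfg: FilterConfig) -> bool:
    return call.consequence not in cfg.excluded_consequences


def passes_rarity(call: VariantCall, cfg: FilterConfig) -> bool:
    # an allele never observed in a panel is by definition rare
    return (call.maf_exac is None or call.maf_exac <= cfg.maf_max) and (
        call.maf_csvs is None or call.maf_csvs <= cfg.maf_max
    )


def passes_prioritization(call: VariantCall, cfg: FilterConfig) -> bool:
    """Retention requires CADD >= cadd_min AND SIFT != tolerated AND PolyPhen != benign.

    Exclusion is the disjunction of failure criteria: a single 'tolerated'
    call is enough to drop a variant even when the other predictors call it
    damaging.  PolyPhen 'possibly_damaging' is retained.  Absent predictions
    follow ``missing_prediction_policy``.
    """
    missing_ok = cfg.missing_prediction_policy == "pass"
    if call.cadd_phred is None:
        if not missing_ok:
            return False
    elif call.cadd_phred < cfg.cadd_min:
        return False
    if call.sift_call is None:
        if not missing_ok:
            return False
    elif call.sift_call is SiftCall.tolerated:
        return False
    if call.polyphen_call is None:
        if not missing_ok:
            return False
    elif call.polyphen_call is PolyphenCall.benign:
        return False
    return True


def qc_filter(calls: Sequence[VariantCall], cfg: FilterConfig) -> list[VariantCall]:
    """Keep calls with DP >= dp_min and GQ >= gq_min (both boundaries inclusive)."""
    return [c for c in calls if passes_qc(c, cfg)]


def consequence_filter(calls: Sequence[VariantCall], cfg: FilterConfig) -> list[VariantCall]:
    """Drop calls whose consequence class is excluded (default: synonymous)."""
    return [c for c in calls if passes_consequence(c, cfg)]


def rarity_filter(calls: Sequence[VariantCall], cfg: FilterConfig) -> list[VariantCall]:
    """Keep calls rare (or unobserved) in both reference panels."""
    return [c for c in calls if passes_rarity(c, cfg)]


def prioritize_damaging(calls: Sequence[VariantCall], cfg: Optional[FilterConfig] = None) -> list[VariantCall]:
    """Keep calls predicted damaging by the SIFT/PolyPhen/CADD disjunction rule."""
    cfg = cfg or FilterConfig()
    return [c for c in calls if passes_prioritization(c, cfg)]


def control_subtract(cohort: Cohort) -> list[VariantCall]:
    """Remove case calls whose (chrom, pos, ref, alt) occurs in any control.

    Matching is zygosity-blind: a variant heterozygous in a single control
    removes every case observation of that allele.  Returns case calls only.
    """
    control_ids = {c.variant_id for c in cohort.control_calls}
    return [c for c in cohort.case_calls if c.variant_id not in control_ids]


@dataclass
class CascadeResult:
    survivors: list[VariantCall]
    stage_counts: pd.DataFrame  # columns: stage, n_calls

    @property
    def report(self) -> pd.DataFrame:
        return self.stage_counts


def run_cascade(
    cohort: Cohort,
    cfg: Optional[FilterConfig] = None,
    prioritize: bool = False,
) -> CascadeResult:
    """Run the full cascade, recording survivor counts per stage.

    Order: control subtraction, then QC, consequence and rarity (these three
    commute), then optionally the damaging-variant prioritization.
    """
    cfg = cfg or FilterConfig()
    stages: list[tuple[str, list[VariantCall]]] = []
    calls = cohort.case_calls
    stages.append(("input_case_calls", calls))
    calls = control_subtract(cohort)
    stages.append(("control_subtract", calls))
    calls = qc_filter(calls, cfg)
    stages.append(("qc", calls))
    calls = consequence_filter(calls, cfg)
    stages.append(("consequence", calls))
    calls = rarity_filter(calls, cfg)
    stages.append(("rarity", calls))
    if prioritize:
        calls = prioritize_damaging(calls, cfg)
        stages.append(("prioritize_damaging", calls))
    counts = pd.DataFrame(
        [(name, len(cs)) for name, cs in stages], columns=["stage", "n_calls"]
    )
    return CascadeResult(survivors=calls, stage_counts=counts)
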