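"""Variant model, table IO and the filter cascade."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affnet.variants import (Cohort, Consequence, FilterConfig, PolyphenCall,
                             SiftCall, VariantCall, Zygosity,
                             consequence_filter, control_subtract,
                             prioritize_damaging, qc_filter, rarity_filter,
                             read_variant_table, run_cascade,
                             write_variant_table)
from conftest import make_call


# ---------------------------------------------------------------------------
# Data model invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kwargs", [
    {"pos": 0},
    {"ref": "A", "alt": "A"},
    {"depth": -1},
    {"genotype_quality": -5},
    {"maf_exac": 1.5},
    {"maf_csvs": -0.1},
    {"cadd_phred": -2.0},
])
def test_invalid_call_rejected(kwargs):
    with pytest.raises(ValueError):
        make_call(**kwargs)


def test_cohort_rejects_overlapping_arms_and_stray_samples():
    with pytest.raises(ValueError):
        Cohort(cases=["A"], controls=["A"])
    with pytest.raises(ValueError):
        Cohort(cases=["A"], controls=["B"], calls=[make_call(sample_id="C")])


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def _random_calls(n, seed=0):
    rng = np.random.default_rng(seed)
    calls = []
    for i in range(n):
        calls.append(make_call(
            sample_id=f"CASE{int(rng.integers(1, 13)):02d}",
            chrom=f"chr{int(rng.integers(1, 23))}",
            pos=int(rng.integers(1, 10**7)),
            gene=f"GENE{int(rng.integers(1, 50)):03d}",
            hgvs_p=f"p.(X{i}Y)" if rng.random() < 0.5 else None,
            zygosity=Zygosity.homozygous if rng.random() < 0.1 else Zygosity.heterozygous,
            depth=int(rng.integers(0, 300)),
            genotype_quality=int(rng.integers(0, 100)),
            consequence=list(Consequence)[int(rng.integers(0, len(Consequence)))],
            maf_exac=float(rng.uniform(0, 0.05)) if rng.random() < 0.6 else None,
            maf_csvs=float(rng.uniform(0, 0.05)) if rng.random() < 0.4 else None,
            sift_call=None if rng.random() < 0.3 else list(SiftCall)[int(rng.integers(0, 2))],
            polyphen_call=None if rng.random() < 0.3 else list(PolyphenCall)[int(rng.integers(0, 3))],
            cadd_phred=float(rng.uniform(0, 45)) if rng.random() < 0.8 else None,
        ))
    return calls


def test_tsv_round_trip(tmp_path):
    calls = _random_calls(50, seed=7)
    path = tmp_path / "calls.tsv"
    write_variant_table(calls, path)
    assert read_variant_table(path, dialect="tsv") == calls


def test_tsv_empty_field_is_absent(tmp_path):
    calls = [make_call(sift_call=None, maf_exac=None, cadd_phred=None)]
    path = tmp_path / "c.tsv"
    write_variant_table(calls, path)
    back = read_variant_table(path)[0]
    assert back.sift_call is None and back.maf_exac is None and back.cadd_phred is None


def test_tsv_bad_row_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    good = "S1\tchr1\t100\tA\tG\tG1\t\theterozygous\t50\t90\tmissense\t\t\t\t\t25"
    bad = "S1\tchr1\tNOTANUMBER\tA\tG\tG1\t\theterozygous\t50\t90\tmissense\t\t\t\t\t25"
    header = "sample_id\tchrom\tpos\tref\talt\tgene\thgvs_p\tzygosity\tdp\tgq\tconsequence\tmaf_exac\tmaf_csvs\tsift\tpolyphen\tcadd"
    path.write_text("\n".join([header, good, bad]) + "\n")
    with pytest.raises(ValueError, match="line 3"):
        read_variant_table(path)


def test_tsv_unknown_consequence_maps_to_other(tmp_path, caplog):
    path = tmp_path / "c.tsv"
    header = "sample_id\tchrom\tpos\tref\talt\tgene\thgvs_p\tzygosity\tdp\tgq\tconsequence\tmaf_exac\tmaf_csvs\tsift\tpolyphen\tcadd"
    row = "S1\tchr1\t100\tA\tG\tG1\t\theterozygous\t50\t90\tweird_consequence\t\t\t\t\t25"
    path.write_text(header + "\n" + row + "\n")
    with caplog.at_level("WARNING"):
        calls = read_variant_table(path)
    assert calls[0].consequence is Consequence.other
    assert "weird_consequence" in caplog.text


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: SYMBOL|Consequence|HGVSp|SIFT|PolyPhen|CADD_PHRED|ExAC_AF|CSVS_AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t12345\t.\tC\tT\t50\tPASS\tCSQ=GENEA|missense_variant|p.(P555L)|deleterious(0.01)|probably_damaging(0.98)|26.1|0.0002|\tGT:DP:GQ\t0/1:140:99\t0/0:80:99
chr1\t22345\t.\tG\tA\t50\tPASS\tCSQ=GENEB|synonymous_variant||||5.0||\tGT:DP:GQ\t1/1:60:80\t0/1:70:90
"""


def test_vcf_reading(tmp_path):
    path = tmp_path / "cohort.vcf"
    path.write_text(VCF_TEXT)
    calls = read_variant_table(path, dialect="vcf")
    # S1 het at site 1, S1 hom + S2 het at site 2
    assert len(calls) == 3
    first = calls[0]
    assert first.sample_id == "S1" and first.depth == 140 and first.genotype_quality == 99
    assert first.gene == "GENEA" and first.consequence is Consequence.missense
    assert first.sift_call is SiftCall.deleterious
    assert first.polyphen_call is PolyphenCall.probably_damaging
    assert first.cadd_phred == pytest.approx(26.1)
    assert first.maf_exac == pytest.approx(0.0002) and first.maf_csvs is None
    hom = [c for c in calls if c.zygosity is Zygosity.homozygous]
    assert len(hom) == 1 and hom[0].sample_id == "S1" and hom[0].pos == 22345


def test_vcf_rejects_multiallelic(tmp_path):
    text = VCF_TEXT.replace("chr1\t12345\t.\tC\tT", "chr1\t12345\t.\tC\tT,G")
    path = tmp_path / "multi.vcf"
    path.write_text(text)
    with pytest.raises(ValueError, match="multi-allelic"):
        read_variant_table(path, dialect="vcf")


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def test_qc_boundaries():
    cfg = FilterConfig()
    low_dp = make_call(depth=9, genotype_quality=99)
    boundary = make_call(depth=10, genotype_quality=30)
    assert qc_filter([low_dp], cfg) == []
    assert qc_filter([boundary], cfg) == [boundary]


def test_qc_matches_brute_force_scan():
    cfg = FilterConfig()
    calls = _random_calls(100, seed=3)
    expected = [c for c in calls if c.depth >= 10 and c.genotype_quality >= 30]
    assert qc_filter(calls, cfg) == expected


def test_consequence_filter():
    cfg = FilterConfig()
    syn = make_call(consequence=Consequence.synonymous)
    mis = make_call(consequence=Consequence.missense)
    assert consequence_filter([syn, mis], cfg) == [mis]
    assert consequence_filter([], cfg) == []


def test_rarity_filter():
    cfg = FilterConfig()
    rare = make_call(maf_exac=0.004, maf_csvs=0.001)
    common = make_call(maf_exac=0.01)
    unseen = make_call(maf_exac=None, maf_csvs=None)
    boundary = make_call(maf_exac=0.005)
    assert rarity_filter([rare, common, unseen, boundary], cfg) == [rare, unseen, boundary]


def test_control_subtract_removes_any_zygosity_match():
    shared = make_call(sample_id="CASE01", pos=500, zygosity=Zygosity.homozygous)
    in_control = make_call(sample_id="CTRL01", pos=500, zygosity=Zygosity.heterozygous)
    private = make_call(sample_id="CASE01", pos=900)
    cohort = Cohort(cases=["CASE01"], controls=["CTRL01"],
                    calls=[shared, private, in_control])
    assert control_subtract(cohort) == [private]


def test_control_subtract_zero_controls_is_identity():
    calls = [make_call(sample_id="CASE01", pos=p) for p in (1, 2, 3)]
    cohort = Cohort(cases=["CASE01"], controls=[], calls=calls)
    assert control_subtract(cohort) == calls


def test_control_subtract_matches_set_oracle():
    rng = np.random.default_rng(11)
    cases = [f"CASE{i:02d}" for i in range(1, 7)]
    controls = [f"CTRL{i:02d}" for i in range(1, 4)]
    calls = []
    for _ in range(120):
        who = str(rng.choice(cases + controls))
        calls.append(make_call(sample_id=who, pos=int(rng.integers(1, 40))))
    cohort = Cohort(cases=cases, controls=controls, calls=calls)
    control_ids = {c.variant_id for c in calls if c.sample_id in controls}
    expected = [c for c in calls
                if c.sample_id in cases and c.variant_id not in control_ids]
    assert control_subtract(cohort) == expected
    # post-condition: no survivor identity occurs in any control
    assert all(c.variant_id not in control_ids for c in control_subtract(cohort))


# ---------------------------------------------------------------------------
# Damaging-variant prioritization
# ---------------------------------------------------------------------------

def test_single_tolerated_call_excludes_despite_damaging_others():
    # mirrors the excluded fourth DAAM2 carrier: tolerated by SIFT although
    # PolyPhen and CADD both call the variant damaging
    call = make_call(cadd_phred=25.0, sift_call=SiftCall.tolerated,
                     polyphen_call=PolyphenCall.probably_damaging)
    assert prioritize_damaging([call]) == []


def test_cadd_below_20_excludes():
    call = make_call(cadd_phred=19.9, sift_call=SiftCall.deleterious,
                     polyphen_call=PolyphenCall.probably_damaging)
    assert prioritize_damaging([call]) == []


def test_possibly_damaging_is_retained():
    call = make_call(cadd_phred=25.0, sift_call=SiftCall.deleterious,
                     polyphen_call=PolyphenCall.possibly_damaging)
    assert prioritize_damaging([call]) == [call]


def test_benign_polyphen_excludes():
    call = make_call(polyphen_call=PolyphenCall.benign)
    assert prioritize_damaging([call]) == []


def test_missing_prediction_policy():
    unscored = make_call(cadd_phred=None, sift_call=None, polyphen_call=None)
    assert prioritize_damaging([unscored], FilterConfig()) == [unscored]
    strict = FilterConfig(missing_prediction_policy="fail")
    assert prioritize_damaging([unscored], strict) == []


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def test_cascade_stage_order_is_cosmetic():
    cfg = FilterConfig()
    calls = _random_calls(150, seed=5)
    a = rarity_filter(consequence_filter(qc_filter(calls, cfg), cfg), cfg)
    b = qc_filter(rarity_filter(consequence_filter(calls, cfg), cfg), cfg)
    c = consequence_filter(qc_filter(rarity_filter(calls, cfg), cfg), cfg)
    assert set(a) == set(b) == set(c)


def test_cascade_all_control_cohort_yields_nothing():
    calls = [make_call(sample_id="CTRL01", pos=p) for p in (1, 2)]
    cohort = Cohort(cases=[], controls=["CTRL01"], calls=calls)
    result = run_cascade(cohort)
    assert result.survivors == []
    assert (result.stage_counts["n_calls"] == 0).all()


def test_cascade_reports_stage_counts():
    cohort = Cohort(
        cases=["CASE01"], controls=["CTRL01"],
        calls=[
            make_call(sample_id="CASE01", pos=1),
            make_call(sample_id="CASE01", pos=2, depth=5),
            make_call(sample_id="CASE01", pos=3),
            make_call(sample_id="CTRL01", pos=3),
        ])
    result = run_cascade(cohort)
    counts = dict(zip(result.stage_counts["stage"], result.stage_counts["n_calls"]))
    assert counts == {"input_case_calls": 3, "control_subtract": 2,
                      "qc": 1, "consequence": 1, "rarity": 1}


# ---------------------------------------------------------------------------
# Filter properties (randomized)
# ---------------------------------------------------------------------------

_call_strategy = st.builds(
    make_call,
    depth=st.integers(0, 60),
    genotype_quality=st.integers(0, 60),
    consequence=st.sampled_from(list(Consequence)),
    maf_exac=st.one_of(st.none(), st.floats(0, 0.02, allow_nan=False)),
    maf_csvs=st.one_of(st.none(), st.floats(0, 0.02, allow_nan=False)),
    sift_call=st.one_of(st.none(), st.sampled_from(list(SiftCall))),
    polyphen_call=st.one_of(st.none(), st.sampled_from(list(PolyphenCall))),
    cadd_phred=st.one_of(st.none(), st.floats(0, 45, allow_nan=False)),
    pos=st.integers(1, 30),
)
_calls_strategy = st.lists(_call_strategy, max_size=25)

_FILTERS = [qc_filter, consequence_filter, rarity_filter, prioritize_damaging]


@settings(max_examples=250, derandomize=True, deadline=None)
@given(calls=_calls_strategy, order=st.permutations(list(range(3))))
def test_per_call_filters_commute(calls, order):
    cfg = FilterConfig()
    stages = [qc_filter, consequence_filter, rarity_filter]
    out = list(calls)
    for i in order:
        out = stages[i](out, cfg)
    ref = rarity_filter(consequence_filter(qc_filter(calls, cfg), cfg), cfg)
    assert set(out) == set(ref)


@settings(max_examples=250, derandomize=True, deadline=None)
@given(calls=_calls_strategy, which=st.integers(0, 3))
def test_filters_idempotent(calls, which):
    cfg = FilterConfig()
    f = _FILTERS[which]
    once = f(calls, cfg)
    assert f(once, cfg) == once


@settings(max_examples=250, derandomize=True, deadline=None)
@given(calls=_calls_strategy)
def test_relaxing_thresholds_never_shrinks_survivors(calls):
    strict = FilterConfig()
    loose = FilterConfig(dp_min=5, gq_min=15, maf_max=0.01, cadd_min=10.0)
    for f in (qc_filter, rarity_filter, prioritize_damaging):
        assert set(f(calls, strict)) <= set(f(calls, loose))


@settings(max_examples=250, derandomize=True, deadline=None)
@given(calls=_calls_strategy)
def test_filters_preserve_order_and_are_pure(calls):
    cfg = FilterConfig()
    for f in _FILTERS:
        out = f(calls, cfg)
        # order-preserving subsequence
        it = iter(calls)
        assert all(any(c == x for x in it) for c in out)
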