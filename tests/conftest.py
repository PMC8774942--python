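import pytest

from affnet.variants import (Consequence, PolyphenCall, SiftCall, VariantCall,
                             Zygosity)


def make_call(
    sample_id="CASE01",
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="G",
    gene="GENE1",
    zygosity=Zygosity.heterozygous,
    depth=100,
    genotype_quality=90,
    consequence=Consequence.missense,
    hgvs_p=None,
    maf_exac=None,
    maf_csvs=None,
    sift_call=SiftCall.deleterious,
    polyphen_call=PolyphenCall.probably_damaging,
    cadd_phred=25.0,
):
    return VariantCall(
        sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
        gene=gene, zygosity=zygosity, depth=depth,
        genotype_quality=genotype_quality, consequence=consequence,
        hgvs_p=hgvs_p, maf_exac=maf_exac, maf_csvs=maf_csvs,
        sift_call=sift_call, polyphen_call=polyphen_call,
        cadd_phred=cadd_phred,
    )


@pytest.fixture
def call_factory():
    return make_call
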