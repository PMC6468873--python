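from pathlib import Path

import pytest

from twohitpipe.core import Consequence, Origin, VariantRecord
from twohitpipe.synthetic import paper_shaped_fixture


def make_variant(
    sample_id="S01",
    chrom="ctg001",
    pos=1000,
    ref="C",
    alt="T",
    origin=Origin.GERMLINE,
    gene="G001",
    consequence=Consequence.MISSENSE,
    depth=100,
    alt_depth=None,
    predictors=("phylop", "sift", "polyphen2", "mutation_taster", "lrt", "cadd"),
    cadd_phred=25.0,
    pop_allele_count=0,
    pop_allele_number=60706,
) -> VariantRecord:
    if alt_depth is None:
        alt_depth = depth // 2
    return VariantRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        origin=origin,
        gene=gene,
        consequence=consequence,
        depth=depth,
        alt_depth=alt_depth,
        predictor_calls={name: True for name in predictors},
        cadd_phred=cadd_phred,
        pop_allele_count=pop_allele_count,
        pop_allele_number=pop_allele_number,
    )


@pytest.fixture(scope="session")
def paper_shaped_cohort(tmp_path_factory) -> tuple[Path, object]:
    """One shared 18-sample synthetic cohort (seed 7)."""
    outdir = tmp_path_factory.mktemp("cohort")
    _, truth = paper_shaped_fixture(outdir, seed=7)
    return outdir, truth
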