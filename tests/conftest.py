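import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# fully deterministic property tests; no example database on disk
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from multisurv.formats import (
    ClinicalRecord,
    CnvSegment,
    FeatureMatrix,
    GeneModel,
    VariantRecord,
    VitalStatus,
)


@pytest.fixture
def tiny_genome() -> dict[str, str]:
    rng = np.random.default_rng(1234)
    return {f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=400)) for i in range(2)}


@pytest.fixture
def gene_models() -> list[GeneModel]:
    return [
        GeneModel("EGFR", "chr1", 50, 149),
        GeneModel("KRAS", "chr1", 200, 299),
        GeneModel("TP53", "chr2", 10, 109),
    ]


@pytest.fixture
def feature_matrix() -> FeatureMatrix:
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(size=(8, 4)),
        index=[f"S{i}" for i in range(8)],
        columns=["EGFR", "KRAS", "TP53", "MYC"],
    )
    return FeatureMatrix(values, omics="mrna", method="raw")


def make_variant(ref="C", alt="T", pos=100, sample="S1", chrom="chr1", gene="",
                 classification="") -> VariantRecord:
    from multisurv.formats import effect_from_classification

    return VariantRecord(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                         gene=gene, effect=effect_from_classification(classification),
                         variant_classification=classification)


def make_clinical(sample, days, dead, cancer=None) -> ClinicalRecord:
    return ClinicalRecord(sample, days, VitalStatus.DEAD if dead else VitalStatus.ALIVE,
                          cancer)


def make_segment(sample, chrom, start, end, mean) -> CnvSegment:
    return CnvSegment(sample_id=sample, chrom=chrom, start=start, end=end,
                      segment_mean=mean)
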