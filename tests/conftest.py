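import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cnaforest import (  # noqa: E402
    AberrationSegment,
    GeneAnnotation,
    GeneEventMatrix,
    GenomicInterval,
)


def make_segment(
    sample_id="P001",
    chrom="chr19",
    start=1_000_000,
    end=2_000_000,
    event_type="loss",
    marker_count=100,
    mean_log2ratio=-0.4,
    mosaic_fraction=None,
):
    if event_type == "cnLOH":
        mean_log2ratio = None
    return AberrationSegment(
        sample_id, GenomicInterval(chrom, start, end), event_type,
        marker_count, mean_log2ratio, mosaic_fraction,
    )


def single_feature_matrix(n_pos, n_pos_carriers, n_neg, n_neg_carriers,
                          feature_id="PSG1:cnLOH"):
    """A one-column cohort matrix with the given carrier counts per group,
    plus the aligned boolean MRD labels."""
    n = n_pos + n_neg
    values = np.zeros((n, 1), dtype=np.uint8)
    values[:n_pos_carriers, 0] = 1
    values[n_pos:n_pos + n_neg_carriers, 0] = 1
    labels = np.array([True] * n_pos + [False] * n_neg)
    matrix = GeneEventMatrix.from_arrays(
        [f"S{i:03d}" for i in range(n)], [feature_id], values
    )
    return matrix, labels


@pytest.fixture
def tiny_catalog():
    """Ten genes tiled on two chromosomes."""
    genes = []
    for i in range(5):
        start = 1_000_000 + i * 300_000
        genes.append(GeneAnnotation(
            f"A{i}", GenomicInterval("chr1", start, start + 200_000),
            "1p22"))
    for i in range(5):
        start = 5_000_000 + i * 300_000
        genes.append(GeneAnnotation(
            f"B{i}", GenomicInterval("chr2", start, start + 200_000),
            "2q11"))
    return genes
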