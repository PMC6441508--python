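import numpy as np
import pytest

from msisig.containers import (
    ExpressionMatrix,
    Platform,
    SampleAnnotation,
    ValueKind,
)
from msisig.simulate import SyntheticCohortSpec, simulate_paired_cohorts


def make_matrix(
    values,
    gene_ids=None,
    sample_ids=None,
    platform=Platform.RNASEQ,
    value_kind=ValueKind.COUNTS,
):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, gene_ids, sample_ids, platform, value_kind)


def make_annotations(labels, sample_ids=None, batches=None, cohort="test"):
    """Annotations from pooled labels ('MSI'/'MSS') or raw grades."""
    raw_of = {"MSI": "MSI-H", "MSS": "MSS"}
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(len(labels))]
    if batches is None:
        batches = ["b1"] * len(labels)
    return [
        SampleAnnotation(
            sample_id=s,
            msi_status_raw=raw_of.get(lab, lab),
            cohort=cohort,
            batch=b,
        )
        for s, lab, b in zip(sample_ids, labels, batches)
    ]


def labels_for(matrix, annotations):
    by_id = {a.sample_id: a.msi_label for a in annotations}
    return [by_id[s] for s in matrix.sample_ids]


@pytest.fixture(scope="session")
def default_sim():
    """One paired-cohort simulation at generator defaults, shared
    read-only across tests."""
    return simulate_paired_cohorts(SyntheticCohortSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
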