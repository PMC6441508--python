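"""End-to-end signature construction from paired cohorts.

Chains the individual stages in the order the signature is defined:
low-count filtering and TMM/log-CPM on the sequencing cohort, platform
harmonization to the common gene universe, negative-binomial differential
expression with the |log2FC| > 1 and adjusted-p < 0.05 filters, core-list
intersection, and correlation-based redundancy pruning against both
training cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import ExpressionMatrix, GeneSignature, SampleAnnotation
from .diffexpr import estimate_common_dispersion, nb_test_per_gene, select_degs
from .preprocess import filter_low_counts, harmonize_platforms, log_cpm, tmm_factors
from .signature import (
    CoreListSpec,
    PruneTrace,
    build_core_list,
    intersect_with_degs,
    prune_correlated,
)

__all__ = ["SignatureBuildResult", "build_signature"]


@dataclass
class SignatureBuildResult:
    signature: GeneSignature
    degs: GeneSignature
    core: GeneSignature
    de_table: pd.DataFrame
    trace: PruneTrace
    universe: list[str]
    dispersion: float


def build_signature(
    rnaseq_counts: ExpressionMatrix,
    microarray: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    core_sources: list[GeneSignature],
    min_support: int = 1,
    min_cpm: float = 1.0,
    min_samples: int = 10,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
    corr_threshold: float = 0.75,
    seed: int = 0,
) -> SignatureBuildResult:
    """Derive a redundancy-pruned cross-platform MSI signature.

    ``annotations`` must cover the RNA-seq samples (differential
    expression runs on the sequencing development cohort only); the
    microarray cohort contributes the platform universe and the second
    correlation-pruning cohort.
    """
    filtered = filter_low_counts(rnaseq_counts, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    lcpm = log_cpm(filtered, factors)

    lcpm_common, array_common = harmonize_platforms(lcpm, microarray)
    universe = list(lcpm_common.gene_ids)

    dispersion = estimate_common_dispersion(filtered, annotations, factors)
    de = nb_test_per_gene(filtered, annotations, factors, dispersion=dispersion)
    degs = select_degs(de, lfc_cut=lfc_cut, alpha=alpha)

    core = build_core_list(
        CoreListSpec(
            source_signatures=core_sources,
            platform_universe=set(universe),
            min_support=min_support,
        )
    )
    candidate = intersect_with_degs(core, degs)
    signature, trace = prune_correlated(
        candidate,
        [lcpm_common, array_common],
        threshold=corr_threshold,
        seed=seed,
    )
    return SignatureBuildResult(
        signature=signature,
        degs=degs,
        core=core,
        de_table=de.table,
        trace=trace,
        universe=universe,
        dispersion=dispersion,
    )
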