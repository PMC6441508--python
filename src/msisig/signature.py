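"""Cross-platform signature construction.

The signature is built in three steps: (1) a core MSI gene list is formed
from previously published MSI signatures, restricted to genes measured on
both platforms; (2) the core list is intersected with the differentially
expressed genes of the sequencing development cohort; (3) redundancy is
pruned — whenever two signature genes correlate with |Pearson r| above a
threshold in any training cohort, one randomly chosen member of the pair
is removed. Pairs are processed in descending order of their maximal
absolute correlation (ties by gene-ID pair) so the greedy procedure is
deterministic up to the seeded coin flip, and every decision is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, GeneSignature, ValueKind

__all__ = [
    "CoreListSpec",
    "PruneTrace",
    "build_core_list",
    "intersect_with_degs",
    "prune_correlated",
    "signature_redundancy_report",
]


@dataclass
class CoreListSpec:
    """Inputs of the core-list construction.

    ``min_support`` is the number of source signatures a gene must appear
    in; the default of 1 takes the union of the sources, the weakest
    assumption about how published signatures should be combined.
    """

    source_signatures: list[GeneSignature]
    platform_universe: set[str]
    min_support: int = 1

    def __post_init__(self) -> None:
        if not self.source_signatures:
            raise ValueError("at least one source signature is required")
        if not 1 <= self.min_support <= len(self.source_signatures):
            raise ValueError(
                "min_support must be between 1 and the number of sources"
            )


@dataclass
class PruneTraceEntry:
    gene_a: str
    gene_b: str
    r: float
    kept: str
    dropped: str


@dataclass
class PruneTrace:
    """Ordered log of every pruning decision, with the seed used."""

    entries: list[PruneTraceEntry] = field(default_factory=list)
    seed: int = 0
    threshold: float = 0.75

    def __len__(self) -> int:
        return len(self.entries)


def build_core_list(spec: CoreListSpec) -> GeneSignature:
    """Genes supported by >= ``min_support`` sources and on both platforms,
    sorted by descending support then gene ID."""
    support: dict[str, int] = {}
    for sig in spec.source_signatures:
        for gene in set(sig.gene_ids):
            support[gene] = support.get(gene, 0) + 1
    universe = {str(g) for g in spec.platform_universe}
    core = [
        g
        for g, n in support.items()
        if n >= spec.min_support and g in universe
    ]
    if not core:
        raise ValueError(
            f"core list is empty (sources={len(spec.source_signatures)}, "
            f"min_support={spec.min_support}, "
            f"universe={len(universe)} genes)"
        )
    core.sort(key=lambda g: (-support[g], g))
    return GeneSignature(
        core,
        name="core-msi",
        provenance={
            "sources": [s.name for s in spec.source_signatures],
            "min_support": spec.min_support,
        },
    )


def intersect_with_degs(
    core: GeneSignature, degs: GeneSignature
) -> GeneSignature:
    """Intersection of the core list and the DEGs, in DEG order."""
    if not core.gene_ids or not degs.gene_ids:
        raise ValueError("both the core list and the DEGs must be non-empty")
    core_set = set(core.gene_ids)
    genes = [g for g in degs.gene_ids if g in core_set]
    if not genes:
        raise ValueError(
            f"core list ({len(core)} genes) and DEGs ({len(degs)} genes) "
            "do not intersect"
        )
    return GeneSignature(
        genes,
        name="core-x-degs",
        provenance={"core": core.name, "degs": degs.name},
    )


def _pairwise_corr(matrix: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    sub = matrix.subset_genes(genes)
    values = sub.values
    if matrix.value_kind is ValueKind.COUNTS:
        raise ValueError(
            "correlation pruning expects log-scale expression, not counts"
        )
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    return np.nan_to_num(corr, nan=0.0)


def prune_correlated(
    signature: GeneSignature,
    cohorts: list[ExpressionMatrix],
    threshold: float = 0.75,
    seed: int = 0,
) -> tuple[GeneSignature, PruneTrace]:
    """Drop one member of every gene pair correlated beyond ``threshold``.

    A pair is redundant when its |Pearson r| exceeds the threshold in ANY
    of the supplied training cohorts. Redundant pairs are visited in
    descending order of max |r| (ties by gene-ID pair); if both members
    are still present, a seeded coin decides which one is dropped. After
    the sweep no surviving pair exceeds the threshold in any cohort.
    """
    if not cohorts:
        raise ValueError("at least one cohort is required")
    genes = list(signature.gene_ids)
    if len(genes) < 2:
        return signature, PruneTrace(seed=seed, threshold=threshold)

    max_abs = np.zeros((len(genes), len(genes)))
    for cohort in cohorts:
        corr = np.abs(_pairwise_corr(cohort, genes))
        max_abs = np.maximum(max_abs, corr)

    pairs = [
        (max_abs[i, j], genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
        if max_abs[i, j] > threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    rng = np.random.default_rng(seed)
    alive = set(genes)
    trace = PruneTrace(seed=seed, threshold=threshold)
    for r, a, b in pairs:
        if a in alive and b in alive:
            dropped = a if rng.random() < 0.5 else b
            kept = b if dropped == a else a
            alive.discard(dropped)
            trace.entries.append(
                PruneTraceEntry(gene_a=a, gene_b=b, r=float(r), kept=kept, dropped=dropped)
            )
    survivors = [g for g in genes if g in alive]
    pruned = GeneSignature(
        survivors,
        name=signature.name + "-pruned",
        provenance={
            **signature.provenance,
            "prune_threshold": threshold,
            "prune_seed": seed,
            "n_dropped": len(trace.entries),
        },
    )
    return pruned, trace


def signature_redundancy_report(
    signature: GeneSignature,
    cohort: ExpressionMatrix,
    threshold: float = 0.75,
) -> tuple[int, list[tuple[str, str, float]]]:
    """Redundancy diagnostic for an existing signature.

    Returns the number of signature genes involved in at least one pair
    with |Pearson r| above the threshold in the cohort, together with the
    offending pairs.
    """
    genes = list(signature.gene_ids)
    if len(genes) < 2:
        return 0, []
    corr = _pairwise_corr(cohort, genes)
    pairs = []
    involved: set[str] = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = corr[i, j]
            if abs(r) > threshold:
                pairs.append((genes[i], genes[j], float(r)))
                involved.update((genes[i], genes[j]))
    pairs.sort(key=lambda t: -abs(t[2]))
    return len(involved), pairs
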