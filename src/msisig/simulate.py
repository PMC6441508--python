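"""Synthetic paired RNA-seq / microarray cohorts with a planted MSI signal.

The generator emulates the structure of a two-platform MSI study: a
minority MSI class (default 35 of 175 samples, i.e. 20% prevalence), a set
of planted differentially expressed genes with a fixed |log2 fold change|,
blocks of strongly co-expressed genes driven by a shared latent factor,
per-batch additive offsets on the log scale, negative-binomial counts for
the sequencing platform and Gaussian log intensities for the array
platform, and a gene universe only partially shared between platforms.

Both cohorts are drawn from the same generative law but contain distinct
simulated patients, so a classifier trained on one platform faces genuine
cross-platform transfer when applied to the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    ExpressionMatrix,
    GeneSignature,
    Platform,
    SampleAnnotation,
    ValueKind,
)

__all__ = [
    "SyntheticCohortSpec",
    "SimulatedCohorts",
    "simulate_paired_cohorts",
    "empirical_block_correlation",
]

# Baseline log2 relative abundances come from a two-component mixture so a
# low-expression stratum exists for the low-count filter to remove.
_LOW_FRAC = 0.25
_LOW_MEAN, _LOW_SD = -3.0, 1.0
_HIGH_MEAN, _HIGH_SD = 6.0, 1.5
# Per-gene biological variation (log2 scale) for unstructured genes. Set
# high enough (inter-tumour heterogeneity of roughly 2-fold) that the
# co-expression induced among planted signal genes by the class difference
# itself stays well below the 0.75 redundancy-pruning threshold — planted
# genes must not be mutually redundant for recovery metrics to be
# unambiguous. Block genes carry a larger module-level variance split
# between the shared factor and gene-specific noise.
_BIO_SD = 0.8
_BLOCK_SD = 2.0


@dataclass
class SyntheticCohortSpec:
    """Parameters of the paired-cohort generator.

    Defaults mirror the development-cohort regime the pipeline is designed
    for: 140 MSS vs 35 MSI samples per platform, 50 planted signal genes at
    |log2FC| = 2, negative-binomial dispersion 0.1, five 5-gene correlated
    blocks with within-block correlation 0.9, and 90% of the gene universe
    shared between platforms.
    """

    n_mss: int = 140
    n_msi: int = 35
    n_genes: int = 2000
    n_signal_genes: int = 50
    signal_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    array_noise_sd: float = 0.3
    n_corr_blocks: int = 5
    block_size: int = 5
    block_rho: float = 0.9
    batch_sd: float = 0.3
    n_batches: int = 2
    platform_overlap_frac: float = 0.9
    lib_size_range: tuple[float, float] = (5e5, 2e6)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mss, self.n_msi, self.n_genes, self.n_batches) <= 0:
            raise ValueError("sample, gene and batch counts must be positive")
        if self.n_signal_genes < 0 or self.n_corr_blocks < 0:
            raise ValueError("signal-gene and block counts must be >= 0")
        if self.n_corr_blocks > 0 and self.block_size < 2:
            raise ValueError("correlated blocks need block_size >= 2")
        reserved = self.n_signal_genes + self.n_corr_blocks * self.block_size
        if reserved > self.n_genes:
            raise ValueError(
                f"{reserved} signal+block genes exceed n_genes={self.n_genes}"
            )
        if not 0 < self.platform_overlap_frac <= 1:
            raise ValueError("platform_overlap_frac must be in (0, 1]")
        if self.n_corr_blocks > 0 and not 0 < self.block_rho < 1:
            raise ValueError("block_rho must be in (0, 1)")
        if self.signal_log2fc < 0:
            raise ValueError("signal_log2fc is a magnitude; must be >= 0")
        if self.nb_dispersion < 0 or self.array_noise_sd < 0:
            raise ValueError("dispersions and noise SDs must be >= 0")
        lo, hi = self.lib_size_range
        if not 0 < lo <= hi:
            raise ValueError("lib_size_range must satisfy 0 < min <= max")


@dataclass
class SimulatedCohorts:
    """Output bundle of :func:`simulate_paired_cohorts`."""

    rnaseq: ExpressionMatrix
    microarray: ExpressionMatrix
    annotations_rnaseq: list[SampleAnnotation]
    annotations_microarray: list[SampleAnnotation]
    planted_signature: GeneSignature
    block_gene_ids: list[list[str]] = field(default_factory=list)

    @property
    def annotations(self) -> list[SampleAnnotation]:
        return self.annotations_rnaseq + self.annotations_microarray


def simulate_paired_cohorts(spec: SyntheticCohortSpec) -> SimulatedCohorts:
    """Draw one RNA-seq and one microarray cohort from the planted model.

    Per gene, a latent baseline log2 abundance is drawn from a low/high
    mixture; signal genes shift the MSI-class mean by ±``signal_log2fc``
    (sign randomized per gene); block genes add a shared per-sample latent
    factor scaled so the induced within-block correlation equals
    ``block_rho``. RNA-seq counts are negative-binomial around library-size
    scaled abundances; microarray values are the latent log2 abundances
    plus Gaussian noise. Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    gene_ids = [str(100001 + i) for i in range(spec.n_genes)]

    # baseline means
    is_low = rng.random(spec.n_genes) < _LOW_FRAC
    mu = np.where(
        is_low,
        rng.normal(_LOW_MEAN, _LOW_SD, spec.n_genes),
        rng.normal(_HIGH_MEAN, _HIGH_SD, spec.n_genes),
    )

    # choose disjoint signal and block genes from the expressed stratum so
    # planted effects sit above the low-count filter
    high_idx = np.flatnonzero(~is_low)
    needed = spec.n_signal_genes + spec.n_corr_blocks * spec.block_size
    if needed > high_idx.size:
        raise ValueError("too few highly expressed genes for signal + blocks")
    chosen = rng.permutation(high_idx)[:needed]
    signal_idx = np.sort(chosen[: spec.n_signal_genes])
    block_idx = [
        np.sort(
            chosen[
                spec.n_signal_genes
                + b * spec.block_size : spec.n_signal_genes
                + (b + 1) * spec.block_size
            ]
        )
        for b in range(spec.n_corr_blocks)
    ]

    signal_sign = rng.choice([-1.0, 1.0], size=spec.n_signal_genes)

    overlap_size = int(round(spec.platform_overlap_frac * spec.n_genes))
    overlap_idx = np.sort(rng.permutation(spec.n_genes)[:overlap_size])

    def draw_cohort(prefix: str, cohort: str):
        n = spec.n_mss + spec.n_msi
        msi_mask = np.zeros(n, dtype=bool)
        msi_mask[spec.n_mss :] = True
        batches = rng.integers(0, spec.n_batches, size=n)
        batch_offsets = rng.normal(
            0.0, spec.batch_sd, size=(spec.n_batches, spec.n_genes)
        )

        x = np.tile(mu[:, None], (1, n))
        x[signal_idx, :] += np.outer(
            signal_sign * spec.signal_log2fc, msi_mask.astype(float)
        )
        # unstructured biological noise everywhere except block genes
        noise = rng.normal(0.0, _BIO_SD, size=(spec.n_genes, n))
        loading = _BLOCK_SD * np.sqrt(spec.block_rho)
        resid_sd = _BLOCK_SD * np.sqrt(1.0 - spec.block_rho)
        for idx in block_idx:
            factor = rng.normal(0.0, 1.0, size=n)
            noise[idx, :] = loading * factor[None, :] + rng.normal(
                0.0, resid_sd, size=(len(idx), n)
            )
        x += noise
        x += batch_offsets[batches, :].T

        sample_ids = [f"{prefix}{j + 1:04d}" for j in range(n)]
        annotations = [
            SampleAnnotation(
                sample_id=sample_ids[j],
                msi_status_raw="MSI-H" if msi_mask[j] else "MSS",
                cohort=cohort,
                batch=f"b{batches[j] + 1}",
            )
            for j in range(n)
        ]
        return x, sample_ids, annotations

    # RNA-seq cohort: NB counts around library-size scaled abundances
    x_rna, rna_samples, ann_rna = draw_cohort("R", "SIM-RNA")
    lo, hi = spec.lib_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(rna_samples)))
    abundance = np.exp2(x_rna)
    props = abundance / abundance.sum(axis=0, keepdims=True)
    means = props * lib_sizes[None, :]
    if spec.nb_dispersion > 0:
        size = 1.0 / spec.nb_dispersion
        p = size / (size + means)
        counts = rng.negative_binomial(size, p).astype(float)
    else:
        counts = rng.poisson(means).astype(float)

    rnaseq = ExpressionMatrix(
        counts, gene_ids, rna_samples, Platform.RNASEQ, ValueKind.COUNTS
    )

    # microarray cohort: latent log2 abundances + measurement noise, on the
    # overlapping gene subset only
    x_arr, arr_samples, ann_arr = draw_cohort("M", "SIM-ARRAY")
    y = x_arr + rng.normal(0.0, spec.array_noise_sd, size=x_arr.shape)
    microarray = ExpressionMatrix(
        y[overlap_idx, :],
        [gene_ids[i] for i in overlap_idx],
        arr_samples,
        Platform.MICROARRAY,
        ValueKind.LOG_INTENSITY,
    )

    planted = GeneSignature(
        [gene_ids[i] for i in signal_idx],
        name="planted-truth",
        provenance={
            "seed": spec.seed,
            "signal_log2fc": spec.signal_log2fc,
            "signs": [int(s) for s in signal_sign],
        },
    )
    return SimulatedCohorts(
        rnaseq=rnaseq,
        microarray=microarray,
        annotations_rnaseq=ann_rna,
        annotations_microarray=ann_arr,
        planted_signature=planted,
        block_gene_ids=[[gene_ids[i] for i in idx] for idx in block_idx],
    )


def empirical_block_correlation(
    matrix: ExpressionMatrix, block: list[str]
) -> float:
    """Mean absolute pairwise Pearson correlation of a gene block.

    Counts are moved to the log2 scale (pseudo-count 0.5) before the
    correlation is computed; log-scale matrices are used as-is.
    """
    if len(block) < 2:
        raise ValueError("block must contain at least 2 genes")
    sub = matrix.subset_genes(block)
    values = sub.values
    if matrix.value_kind is ValueKind.COUNTS:
        values = np.log2(values + 0.5)
    corr = np.corrcoef(values)
    mask = ~np.eye(len(block), dtype=bool)
    return float(np.mean(np.abs(corr[mask])))
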