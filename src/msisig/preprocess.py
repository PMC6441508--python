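"""Normalization and cross-platform harmonization.

RNA-seq counts go through low-count filtering, trimmed-mean-of-M-values
(TMM) scaling and log2-CPM transformation; microarray log intensities can
be quantile normalized; the two platforms are harmonized by restricting to
their common gene universe. TMM follows the published algorithm: a
reference library is picked by upper-quartile proximity to the mean, M
(log ratio) and A (log abundance) values are doubly trimmed, and the
scaling factor is a precision-weighted mean of the surviving M values,
with factors rescaled to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import (
    ExpressionMatrix,
    SampleAnnotation,
    ValueKind,
    pool_msi_label,
)

__all__ = [
    "NormalizationFactors",
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
    "quantile_normalize",
    "harmonize_platforms",
    "pool_msi_labels",
    "collapse_probes",
]


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors and raw library sizes.

    Effective library size = library size x factor. Factors are rescaled
    so their geometric mean is 1.
    """

    sample_ids: list[str]
    factors: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if not (
            len(self.sample_ids) == self.factors.size == self.lib_sizes.size
        ):
            raise ValueError("sample ids, factors and library sizes disagree")
        if np.any(self.factors <= 0):
            raise ValueError("TMM factors must be positive")

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors


def filter_low_counts(
    counts: ExpressionMatrix, min_cpm: float = 1.0, min_samples: int = 10
) -> ExpressionMatrix:
    """Drop genes expressed below ``min_cpm`` in fewer than ``min_samples``
    libraries; gene order is preserved."""
    _require_counts(counts, "filter_low_counts")
    lib_sizes = counts.values.sum(axis=0)
    if np.any(lib_sizes == 0):
        raise ValueError("library with zero total counts")
    cpm = counts.values / lib_sizes[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            f"no gene passes min_cpm={min_cpm} in >= {min_samples} samples; "
            "lower the thresholds"
        )
    return ExpressionMatrix(
        counts.values[keep, :],
        [g for g, k in zip(counts.gene_ids, keep) if k],
        list(counts.sample_ids),
        counts.platform,
        counts.value_kind,
    )


def tmm_factors(
    counts: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    Parameters follow the method's published defaults: 30% trim on the M
    values, 5% trim on the A values, inverse-asymptotic-variance weighting.
    The reference library is the one whose 75th count percentile (scaled by
    library size) is closest to the mean across libraries, unless
    ``ref_sample`` is given.
    """
    _require_counts(counts, "tmm_factors")
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    data = counts.values
    lib_sizes = data.sum(axis=0)
    if np.any(lib_sizes == 0):
        raise ValueError("library with zero total counts")

    if ref_sample is None:
        f75 = np.quantile(data, 0.75, axis=0) / lib_sizes
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref_sample)

    ref = data[:, ref_idx]
    n_ref = lib_sizes[ref_idx]
    factors = np.ones(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            factors[j] = _tmm_pair(ref, ref, n_ref, n_ref, trim_m, trim_a)
        else:
            factors[j] = _tmm_pair(
                data[:, j], ref, lib_sizes[j], n_ref, trim_m, trim_a
            )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        list(counts.sample_ids), factors, lib_sizes
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Scaling factor of one library against the reference."""
    positive = (obs > 0) & (ref > 0)
    if not positive.any():
        raise ValueError("library shares no positive gene with the reference")
    obs = obs[positive]
    ref = ref[positive]

    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
    # asymptotic (binomial) variance of M, used as precision weight
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0

    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (
        (rank_m >= lo_l)
        & (rank_m <= hi_l)
        & (rank_a >= lo_s)
        & (rank_a <= hi_s)
    )
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def log_cpm(
    counts: ExpressionMatrix,
    factors: NormalizationFactors,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """log2 counts-per-million against TMM-effective library sizes.

    The pseudo-count is scaled per library (proportional to effective
    library size) and the library size is inflated by twice the scaled
    pseudo-count, so the transform is finite at zero counts and strictly
    monotone in the count.
    """
    _require_counts(counts, "log_cpm")
    if list(counts.sample_ids) != list(factors.sample_ids):
        raise ValueError("factors were computed on a different sample set")
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    eff = factors.effective_lib_sizes
    prior_scaled = prior_count * eff / eff.mean()
    adj_lib = eff + 2.0 * prior_scaled
    values = np.log2((counts.values + prior_scaled[None, :]) / adj_lib[None, :] * 1e6)
    return ExpressionMatrix(
        values,
        list(counts.gene_ids),
        list(counts.sample_ids),
        counts.platform,
        ValueKind.LOG_CPM,
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean distribution of order statistics.

    Ties within a sample receive the mean of their target quantiles
    (average-rank convention).
    """
    if matrix.value_kind is ValueKind.COUNTS:
        raise ValueError("quantile_normalize expects log-scale values")
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = matrix.values
    n = matrix.n_genes
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(matrix.n_samples):
        ranks = rankdata(values[:, j])
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return ExpressionMatrix(
        out,
        list(matrix.gene_ids),
        list(matrix.sample_ids),
        matrix.platform,
        matrix.value_kind,
    )


def harmonize_platforms(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in sorted order."""
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("platforms share no genes")
    return a.subset_genes(common), b.subset_genes(common)


def pool_msi_labels(
    annotations: list[SampleAnnotation],
) -> list[SampleAnnotation]:
    """Re-derive the pooled binary MSI label for every annotation.

    MSI-H becomes MSI; MSI-L and MSS are pooled into MSS. Unknown raw
    labels raise an error naming the sample.
    """
    pooled = []
    for ann in annotations:
        try:
            pool_msi_label(ann.msi_status_raw)
        except ValueError as exc:
            raise ValueError(f"sample {ann.sample_id!r}: {exc}") from None
        pooled.append(
            SampleAnnotation(
                sample_id=ann.sample_id,
                msi_status_raw=ann.msi_status_raw,
                cohort=ann.cohort,
                batch=ann.batch,
            )
        )
    return pooled


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes.

    For each gene the probe with the highest mean expression is kept — a
    deterministic rule. Probes without a mapping are dropped.
    """
    best: dict[str, tuple[float, int]] = {}
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        mean = float(matrix.values[i, :].mean())
        if gene not in best or mean > best[gene][0]:
            best[gene] = (mean, i)
    if not best:
        raise ValueError("no probe maps to a gene")
    genes = sorted(best)
    idx = [best[g][1] for g in genes]
    return ExpressionMatrix(
        matrix.values[idx, :],
        genes,
        list(matrix.sample_ids),
        matrix.platform,
        matrix.value_kind,
    )


def _require_counts(matrix: ExpressionMatrix, op: str) -> None:
    if matrix.value_kind is not ValueKind.COUNTS:
        raise ValueError(f"{op} expects raw counts, got {matrix.value_kind.value}")
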