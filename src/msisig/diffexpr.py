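"""Negative-binomial differential expression between MSI and MSS.

Each gene is fit with a log-linear negative-binomial model at a single
common dispersion shared across genes: log mean = offset + intercept +
class effect (+ batch indicators when batches are supplied), offset =
ln(TMM-effective library size). Significance comes from a likelihood-ratio
test of the class coefficient (chi-squared, 1 df) with Benjamini-Hochberg
adjustment across genes; the reported log2 fold change is the class
coefficient divided by ln 2 (MSI minus MSS).

This is a deliberate simplification of the full empirical-Bayes machinery
of dedicated count-model packages: one pooled dispersion, no tagwise
shrinkage, no quasi-likelihood — sufficient for the planted-signal regimes
this pipeline is exercised in, and pluggable if a finer test is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .containers import ExpressionMatrix, GeneSignature, SampleAnnotation
from .preprocess import NormalizationFactors, log_cpm

__all__ = [
    "DEResult",
    "estimate_common_dispersion",
    "nb_test_per_gene",
    "benjamini_hochberg",
    "select_degs",
    "nb_glm_fit",
]


@dataclass
class DEResult:
    """Per-gene differential expression table.

    ``log2_fc`` is MSI minus MSS on the log2 scale; ``p_value`` may be NaN
    for genes whose fit did not converge (those are excluded from the
    Benjamini-Hochberg denominator).
    """

    table: pd.DataFrame  # index: gene_id; columns: log2_fc, p_value, adj_p, mean_log_cpm

    def __post_init__(self) -> None:
        required = {"log2_fc", "p_value", "adj_p", "mean_log_cpm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")


def _class_vector(
    matrix: ExpressionMatrix, annotations: list[SampleAnnotation]
) -> np.ndarray:
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in matrix.sample_ids if s not in ann_by_id]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    return np.array(
        [ann_by_id[s].msi_label == "MSI" for s in matrix.sample_ids],
        dtype=float,
    )


def estimate_common_dispersion(
    counts: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    factors: NormalizationFactors | None = None,
) -> float:
    """Method-of-moments pooled NB dispersion.

    Counts are rescaled to a common effective library size; within each
    class, the excess of the sample variance over the mean is pooled
    across genes by regressing (variance - mean) on mean^2 through the
    origin. The estimate is floored at 0.
    """
    is_msi = _class_vector(counts, annotations).astype(bool)
    for label, mask in (("MSI", is_msi), ("MSS", ~is_msi)):
        if mask.sum() < 2:
            raise ValueError(f"class {label} has fewer than 2 samples")
    if factors is None:
        lib = counts.values.sum(axis=0)
    else:
        if list(factors.sample_ids) != list(counts.sample_ids):
            raise ValueError("factors were computed on a different sample set")
        lib = factors.effective_lib_sizes
    scaled = counts.values * (lib.mean() / lib)[None, :]

    num = 0.0
    den = 0.0
    for mask in (is_msi, ~is_msi):
        sub = scaled[:, mask]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mean > 0
        num += np.sum(var[ok] - mean[ok])
        den += np.sum(mean[ok] ** 2)
    if den == 0:
        return 0.0
    return float(max(0.0, num / den))


def nb_glm_fit(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    dispersion: float,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-linear models for many genes against one design matrix.

    Parameters
    ----------
    y
        Counts, shape ``(n_genes, n_samples)``.
    design
        Design matrix, shape ``(n_samples, n_params)``.
    offset
        Per-sample log offset (ln effective library size).
    dispersion
        Common NB dispersion; 0 reduces to Poisson regression.

    Returns
    -------
    beta : ``(n_genes, n_params)`` coefficient matrix
    loglik : per-gene maximized log-likelihood
    converged : per-gene boolean
    """
    y = np.asarray(y, dtype=float)
    n_genes, n_samples = y.shape
    n_params = design.shape[1]

    # start from a regularized log-linear least-squares fit
    init_resp = np.log((y + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(design, init_resp.T, rcond=None)
    beta = beta.T  # (n_genes, n_params)

    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active]
        eta = b @ design.T + offset[None, :]
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        w = mu / (1.0 + dispersion * mu)  # IRLS weight for log link
        z = eta - offset[None, :] + (y[active] - mu) / mu
        # batched weighted normal equations: A_g = X' W_g X, rhs_g = X' W_g z_g
        a = np.einsum("np,gn,nq->gpq", design, w, design)
        rhs = np.einsum("np,gn,gn->gp", design, w, z)
        a += 1e-10 * np.eye(n_params)[None, :, :]
        try:
            new_b = np.linalg.solve(a, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_b = np.stack(
                [np.linalg.lstsq(ai, ri, rcond=None)[0] for ai, ri in zip(a, rhs)]
            )
        step = new_b - b
        beta[active] = new_b
        done = np.max(np.abs(step), axis=1) < tol
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    eta = beta @ design.T + offset[None, :]
    eta = np.clip(eta, -50.0, 50.0)
    mu = np.exp(eta)
    loglik = _nb_loglik(y, mu, dispersion)
    return beta, loglik, converged


def _nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # mu is strictly positive (linear predictor is clipped), so every term
    # below is finite
    if dispersion == 0:
        ll = y * np.log(mu) - mu - gammaln(y + 1.0)
    else:
        r = 1.0 / dispersion
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    return ll.sum(axis=1)


def nb_test_per_gene(
    counts: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    factors: NormalizationFactors | None = None,
    dispersion: float | None = None,
    use_batch: bool = True,
) -> DEResult:
    """Likelihood-ratio test of the MSI class effect for every gene.

    Batch indicator columns are included in both the full and the reduced
    model when the annotations carry more than one batch and ``use_batch``
    is set. Genes whose fit fails to converge get ``p_value = NaN`` and do
    not count toward the Benjamini-Hochberg denominator.
    """
    is_msi = _class_vector(counts, annotations)
    if is_msi.sum() == 0 or is_msi.sum() == is_msi.size:
        raise ValueError("both MSI and MSS samples are required")
    if factors is None:
        lib = counts.values.sum(axis=0)
        factors = NormalizationFactors(
            list(counts.sample_ids), np.ones(counts.n_samples), lib
        )
    offset = np.log(factors.effective_lib_sizes)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, annotations, factors)

    ann_by_id = {a.sample_id: a for a in annotations}
    batches = [ann_by_id[s].batch for s in counts.sample_ids]
    levels = sorted(set(batches))
    cols = [np.ones(counts.n_samples), is_msi]
    if use_batch and len(levels) > 1:
        for level in levels[1:]:
            cols.append(np.array([b == level for b in batches], dtype=float))
    design_full = np.column_stack(cols)
    design_null = np.delete(design_full, 1, axis=1)

    y = counts.values
    beta_f, ll_f, conv_f = nb_glm_fit(y, design_full, offset, dispersion)
    _, ll_n, conv_n = nb_glm_fit(y, design_null, offset, dispersion)

    stat = np.maximum(0.0, 2.0 * (ll_f - ll_n))
    p = chi2.sf(stat, df=1)
    ok = conv_f & conv_n
    if not ok.all():
        n_bad = int((~ok).sum())
        warnings.warn(
            f"{n_bad} gene(s) did not converge; p set to NaN and excluded "
            "from the BH denominator"
        )
        p = np.where(ok, p, np.nan)

    log2_fc = beta_f[:, 1] / np.log(2.0)
    adj = benjamini_hochberg(p)
    mean_lcpm = log_cpm(counts, factors).values.mean(axis=1)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": p,
            "adj_p": adj,
            "mean_log_cpm": mean_lcpm,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )
    return DEResult(table)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up false-discovery-rate adjustment, NaN-aware.

    NaN entries are passed through and do not count toward the number of
    tests m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


def select_degs(
    de: DEResult,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
    name: str = "degs",
) -> GeneSignature:
    """Differentially expressed genes: |log2FC| > cut and adjusted p < alpha.

    Both inequalities are strict. Genes are ordered by ascending adjusted
    p, then descending |log2FC|, then gene ID.
    """
    t = de.table
    keep = (np.abs(t["log2_fc"]) > lfc_cut) & (t["adj_p"] < alpha)
    sub = t[keep.fillna(False)].copy()
    sub["abs_lfc"] = np.abs(sub["log2_fc"])
    sub = sub.sort_values(
        by=["adj_p", "abs_lfc", "gene_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    return GeneSignature(
        list(sub.index),
        name=name,
        provenance={"lfc_cut": lfc_cut, "alpha": alpha, "n_tested": len(t)},
    )
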