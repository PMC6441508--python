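"""ROC/AUC evaluation with DeLong variance, paired AUC tests and
stratified cross-validation of the centroid classifier.

The AUC is the Mann-Whitney statistic (ties count 1/2). DeLong's method
estimates its variance from placement values: for each positive the
fraction of negatives it outscores (V10) and for each negative the
fraction of positives scored below it (V01); the variance of the AUC is
S10/m + S01/n with the sample (co)variances of the placements, which also
yields the covariance of two AUCs computed on the same samples and hence
a paired z-test for equal AUCs.

Cross-validation is stratified by the binary MSI label; centroids,
standardization statistics and the decision threshold are fit on training
folds only and the held-out scores are pooled into a single ROC, from
which one AUC and DeLong confidence interval are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .classifier import fit_centroids, optimize_threshold, score_samples
from .containers import ExpressionMatrix, GeneSignature, SampleAnnotation
from .diffexpr import benjamini_hochberg

__all__ = [
    "RocResult",
    "CvPlan",
    "auc",
    "delong_ci",
    "delong_paired_test",
    "make_cv_plan",
    "cross_validate",
    "compare_signatures",
]


@dataclass
class RocResult:
    """Scores, labels and AUC with DeLong variance and CI."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = MSI
    auc: float
    delong_var: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC")


@dataclass
class CvPlan:
    """Stratified fold assignment: sample_id -> fold index."""

    fold_of: dict[str, int]
    k: int
    seed: int
    folds: list[list[str]] = field(default_factory=list)


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    is_pos = _as_binary(labels)
    if scores.shape != is_pos.shape:
        raise ValueError("scores and labels differ in length")
    pos = scores[is_pos]
    neg = scores[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes are required")
    return pos, neg


def auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative
    (Mann-Whitney normalization, ties 1/2)."""
    pos, neg = _split_scores(scores, labels)
    psi = _placements(pos, neg)
    return float(psi.mean())


def _placements(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Matrix psi[i, j] = 1, 1/2, 0 for pos_i >, =, < neg_j."""
    diff = pos[:, None] - neg[None, :]
    return (diff > 0).astype(float) + 0.5 * (diff == 0)


def delong_ci(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC with DeLong variance and normal-approximation CI.

    Perfect separation gives zero variance; the result is flagged
    ``degenerate`` and the CI collapses onto the AUC.
    """
    pos, neg = _split_scores(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong variance needs >= 2 samples per class")
    psi = _placements(pos, neg)
    v10 = psi.mean(axis=1)  # per-positive placement
    v01 = psi.mean(axis=0)  # per-negative placement
    theta = float(psi.mean())
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = s10 / pos.size + s01 / neg.size
    degenerate = var == 0.0
    if degenerate:
        lo = hi = theta
        warnings.warn("zero DeLong variance (perfect separation); CI collapsed")
    else:
        z = norm.ppf(1.0 - alpha / 2.0)
        half = z * np.sqrt(var)
        lo = max(0.0, theta - half)
        hi = min(1.0, theta + half)
    scores_arr = np.asarray(scores, dtype=float)
    return RocResult(
        scores=scores_arr,
        labels=_as_binary(labels),
        auc=theta,
        delong_var=float(var),
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        degenerate=bool(degenerate),
    )


def delong_paired_test(
    scores_a, scores_b, labels
) -> tuple[float, float, float, float]:
    """DeLong test for equality of two AUCs on the same samples.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.
    Antisymmetric under swapping the two score vectors.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors differ in length")
    is_pos = _as_binary(labels)
    pos_a, neg_a = scores_a[is_pos], scores_a[~is_pos]
    pos_b, neg_b = scores_b[is_pos], scores_b[~is_pos]
    if pos_a.size < 2 or neg_a.size < 2:
        raise ValueError("paired DeLong test needs >= 2 samples per class")

    psi_a = _placements(pos_a, neg_a)
    psi_b = _placements(pos_b, neg_b)
    auc_a = float(psi_a.mean())
    auc_b = float(psi_b.mean())

    v10 = np.stack([psi_a.mean(axis=1), psi_b.mean(axis=1)])  # (2, m)
    v01 = np.stack([psi_a.mean(axis=0), psi_b.mean(axis=0)])  # (2, n)
    s10 = np.cov(v10)  # 2x2
    s01 = np.cov(v01)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / pos_a.size
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / neg_a.size
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return auc_a, auc_b, float(z), p


def make_cv_plan(
    annotations: list[SampleAnnotation], k: int = 10, seed: int = 0
) -> CvPlan:
    """Stratified k-fold assignment over the annotated samples."""
    sample_ids = [a.sample_id for a in annotations]
    y = np.array([a.msi_label == "MSI" for a in annotations], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes are required for stratified folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    folds: list[list[str]] = []
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(y.size), y)):
        members = [sample_ids[i] for i in test_idx]
        folds.append(members)
        for s in members:
            fold_of[s] = fold
    return CvPlan(fold_of=fold_of, k=k, seed=seed, folds=folds)


def cross_validate(
    expr: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    signature: GeneSignature,
    k: int = 10,
    seed: int = 0,
    standardize: str = "zscore",
    plan: CvPlan | None = None,
    alpha: float = 0.05,
) -> tuple[RocResult, CvPlan]:
    """Pooled out-of-fold ROC of the centroid classifier.

    For every fold, centroids (and standardization statistics and the
    decision threshold) are fit on the training split only; held-out
    samples are scored with the training-fold statistics. All out-of-fold
    scores are pooled into one ROC with a DeLong CI.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in expr.sample_ids if s not in ann_by_id]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    anns = [ann_by_id[s] for s in expr.sample_ids]
    if plan is None:
        plan = make_cv_plan(anns, k=k, seed=seed)

    scores = pd.Series(np.nan, index=expr.sample_ids, dtype=float)
    for fold_members in plan.folds:
        test_ids = [s for s in fold_members if s in scores.index]
        train_ids = [s for s in expr.sample_ids if s not in set(fold_members)]
        train_anns = [ann_by_id[s] for s in train_ids]
        train_labels = {a.msi_label for a in train_anns}
        if len(train_labels) < 2:
            raise ValueError(
                "a training split lost a class entirely; use a smaller k"
            )
        model = fit_centroids(
            expr.subset_samples(train_ids),
            train_anns,
            signature,
            standardize=standardize,
        )
        train_scores = score_samples(
            expr.subset_samples(train_ids), model, standardize_with="training"
        )
        try:
            model.threshold = optimize_threshold(
                train_scores.to_numpy(),
                [ann_by_id[s].msi_label for s in train_ids],
            )
        except ValueError:
            model.threshold = 0.0
        fold_scores = score_samples(
            expr.subset_samples(test_ids), model, standardize_with="training"
        )
        scores.loc[fold_scores.index] = fold_scores.to_numpy()

    labels = [ann_by_id[s].msi_label for s in expr.sample_ids]
    roc = delong_ci(scores.to_numpy(), labels, alpha=alpha)
    return roc, plan


def compare_signatures(
    expr: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    signatures: list[GeneSignature],
    k: int = 10,
    seed: int = 0,
    standardize: str = "zscore",
) -> pd.DataFrame:
    """Cross-validated comparison of signatures against the first one.

    All signatures share one fold plan; the reference (first) signature's
    pooled scores are compared to every other signature's by the paired
    DeLong test, with Benjamini-Hochberg adjustment across comparisons.
    Signatures with no gene present in the matrix are reported as failed
    rows rather than aborting the comparison.
    """
    if len(signatures) < 2:
        raise ValueError("need a reference and at least one comparator")
    ann_by_id = {a.sample_id: a for a in annotations}
    anns = [ann_by_id[s] for s in expr.sample_ids]
    plan = make_cv_plan(anns, k=k, seed=seed)
    labels = [ann_by_id[s].msi_label for s in expr.sample_ids]

    rows = []
    pooled: dict[str, np.ndarray] = {}
    for sig in signatures:
        present = [g for g in sig.gene_ids if g in set(expr.gene_ids)]
        if not present:
            rows.append(
                {
                    "signature": sig.name,
                    "n_genes": 0,
                    "auc": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "z_vs_reference": np.nan,
                    "p_vs_reference": np.nan,
                    "status": "failed: no gene present",
                }
            )
            continue
        usable = GeneSignature(present, name=sig.name)
        roc, _ = cross_validate(
            expr,
            annotations,
            usable,
            k=k,
            seed=seed,
            standardize=standardize,
            plan=plan,
        )
        pooled[sig.name] = roc.scores
        rows.append(
            {
                "signature": sig.name,
                "n_genes": len(present),
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "z_vs_reference": np.nan,
                "p_vs_reference": np.nan,
                "status": "ok",
            }
        )

    ref_name = signatures[0].name
    if ref_name not in pooled:
        raise ValueError("reference signature has no usable genes")
    ref_scores = pooled[ref_name]
    for row in rows:
        name = row["signature"]
        if row["status"] != "ok" or name == ref_name:
            continue
        _, _, z, p = delong_paired_test(pooled[name], ref_scores, labels)
        row["z_vs_reference"] = z
        row["p_vs_reference"] = p
    frame = pd.DataFrame(rows).set_index("signature")
    pvals = frame["p_vs_reference"].to_numpy(dtype=float)
    frame["adj_p_vs_reference"] = benjamini_hochberg(pvals)
    frame.loc[ref_name, "adj_p_vs_reference"] = 1.0
    frame.attrs["fold_plan"] = plan
    return frame


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    return np.array([str(v) == "MSI" for v in arr], dtype=bool)
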