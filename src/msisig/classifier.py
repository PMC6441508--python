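"""Cosine nearest-centroid MSI classifier.

Each class is summarized by the arithmetic mean (centroid) of its
training samples over the signature genes. A sample's score is the
difference of cosine distances to the two centroids,

    score = cosdist(x, centroid_MSS) - cosdist(x, centroid_MSI),

so MSI-like samples score high; the score lies in [-2, 2] and is
invariant to positive rescaling of the sample vector. A sample is called
MSI when its score strictly exceeds an optimized threshold (default
criterion: Youden's J on the training scores).

Raw log units of different platforms are not directly comparable, so
per-gene z-scoring is applied before the cosine computation by default.
When a fitted model is moved to a new cohort (typically the other
platform), the new cohort is standardized with its own per-gene statistics
(``standardize_with="cohort"``); within-cohort application — including
held-out folds in cross-validation — uses the statistics stored at
training time (``standardize_with="training"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSignature, SampleAnnotation

__all__ = [
    "CentroidModel",
    "fit_centroids",
    "msi_score",
    "score_samples",
    "optimize_threshold",
    "classify",
]

_SD_FLOOR = 1e-12


@dataclass
class CentroidModel:
    """Fitted nearest-centroid model over signature genes."""

    gene_ids: list[str]
    centroid_msi: np.ndarray
    centroid_mss: np.ndarray
    threshold: float = 0.0
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid_msi = np.asarray(self.centroid_msi, dtype=float)
        self.centroid_mss = np.asarray(self.centroid_mss, dtype=float)
        n = len(self.gene_ids)
        if self.centroid_msi.shape != (n,) or self.centroid_mss.shape != (n,):
            raise ValueError("centroid length must equal the gene count")
        if not (
            np.all(np.isfinite(self.centroid_msi))
            and np.all(np.isfinite(self.centroid_mss))
        ):
            raise ValueError("centroids must be finite")
        if np.linalg.norm(self.centroid_msi) == 0 or (
            np.linalg.norm(self.centroid_mss) == 0
        ):
            raise ValueError("centroids must not be identically zero")

    @property
    def standardize(self) -> str:
        return self.training_meta.get("standardize", "none")

    def restrict_to(self, gene_ids: list[str]) -> "CentroidModel":
        """Model reduced to a subset of its genes (missing-gene fallback)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [index[g] for g in gene_ids]
        meta = dict(self.training_meta)
        for key in ("gene_means", "gene_sds"):
            if key in meta:
                meta[key] = [meta[key][i] for i in idx]
        meta["restricted_from"] = len(self.gene_ids)
        return CentroidModel(
            gene_ids=list(gene_ids),
            centroid_msi=self.centroid_msi[idx],
            centroid_mss=self.centroid_mss[idx],
            threshold=self.threshold,
            training_meta=meta,
        )


def fit_centroids(
    expr: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    signature: GeneSignature,
    standardize: str = "zscore",
) -> CentroidModel:
    """Fit class centroids on log-scale expression over signature genes.

    ``standardize="zscore"`` (default) z-scores each gene across the
    training samples before averaging and stores the per-gene mean/SD in
    ``training_meta``; ``"none"`` averages raw values.
    """
    if standardize not in ("zscore", "none"):
        raise ValueError("standardize must be 'zscore' or 'none'")
    sub = expr.subset_genes(list(signature.gene_ids))
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in sub.sample_ids if s not in ann_by_id]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    is_msi = np.array(
        [ann_by_id[s].msi_label == "MSI" for s in sub.sample_ids], dtype=bool
    )
    if is_msi.sum() == 0 or (~is_msi).sum() == 0:
        raise ValueError("both classes are required to fit centroids")

    values = sub.values
    meta: dict = {
        "standardize": standardize,
        "n_msi": int(is_msi.sum()),
        "n_mss": int((~is_msi).sum()),
        "cohorts": sorted({ann_by_id[s].cohort for s in sub.sample_ids}),
    }
    if standardize == "zscore":
        means = values.mean(axis=1)
        sds = values.std(axis=1, ddof=1)
        sds = np.maximum(sds, _SD_FLOOR)
        values = (values - means[:, None]) / sds[:, None]
        meta["gene_means"] = means.tolist()
        meta["gene_sds"] = sds.tolist()

    centroid_msi = values[:, is_msi].mean(axis=1)
    centroid_mss = values[:, ~is_msi].mean(axis=1)
    return CentroidModel(
        gene_ids=list(signature.gene_ids),
        centroid_msi=centroid_msi,
        centroid_mss=centroid_mss,
        threshold=0.0,
        training_meta=meta,
    )


def msi_score(sample: np.ndarray, model: CentroidModel) -> float:
    """Cosine-distance difference score for one (already standardized)
    expression vector over the model's genes; higher = more MSI-like."""
    x = np.asarray(sample, dtype=float)
    if x.shape != (len(model.gene_ids),):
        raise ValueError(
            f"sample vector length {x.shape} does not match the "
            f"{len(model.gene_ids)}-gene model"
        )
    return float(_cosine_scores(x[:, None], model)[0])


def _cosine_scores(values: np.ndarray, model: CentroidModel) -> np.ndarray:
    norms = np.linalg.norm(values, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm sample vector; cosine score undefined")
    c_msi = model.centroid_msi
    c_mss = model.centroid_mss
    sim_msi = (c_msi @ values) / (np.linalg.norm(c_msi) * norms)
    sim_mss = (c_mss @ values) / (np.linalg.norm(c_mss) * norms)
    # cosdist(x, mss) - cosdist(x, msi) == sim_msi - sim_mss
    return sim_msi - sim_mss


def score_samples(
    expr: ExpressionMatrix,
    model: CentroidModel,
    standardize_with: str = "cohort",
    allow_missing_genes: bool = False,
) -> pd.Series:
    """Score every sample of a matrix against a fitted model.

    ``standardize_with`` selects where the per-gene standardization
    statistics come from when the model was fit with z-scoring: the input
    cohort itself (``"cohort"``, appropriate when transferring across
    platforms), the statistics stored at training time (``"training"``,
    appropriate within-cohort and in cross-validation), or ``"none"``.
    With ``allow_missing_genes`` the model falls back to the subset of its
    genes present in the matrix.
    """
    if standardize_with not in ("cohort", "training", "none"):
        raise ValueError("standardize_with must be cohort, training or none")
    present = set(expr.gene_ids)
    missing = [g for g in model.gene_ids if g not in present]
    if missing:
        if not allow_missing_genes:
            raise KeyError(
                f"{len(missing)} model gene(s) absent from matrix: {missing}"
            )
        kept = [g for g in model.gene_ids if g in present]
        if not kept:
            raise ValueError("no model gene present in the matrix")
        warnings.warn(
            f"scoring on {len(kept)} of {len(model.gene_ids)} signature "
            f"genes; absent: {missing}"
        )
        model = model.restrict_to(kept)
    sub = expr.subset_genes(model.gene_ids)
    values = sub.values

    if model.standardize == "zscore" and standardize_with != "none":
        if standardize_with == "cohort":
            means = values.mean(axis=1)
            sds = np.maximum(values.std(axis=1, ddof=1), _SD_FLOOR)
        else:
            means = np.asarray(model.training_meta["gene_means"], dtype=float)
            sds = np.asarray(model.training_meta["gene_sds"], dtype=float)
        values = (values - means[:, None]) / sds[:, None]

    scores = _cosine_scores(values, model)
    return pd.Series(scores, index=sub.sample_ids, name="msi_score")


def optimize_threshold(
    scores, labels, criterion: str = "youden"
) -> float:
    """Decision threshold maximizing Youden's J (sens + spec - 1).

    Candidates are the midpoints between consecutive sorted unique scores;
    ties are broken toward the larger threshold (higher specificity).
    Classification uses strict exceedance (score > threshold = MSI).
    """
    if criterion != "youden":
        raise ValueError(f"unknown criterion {criterion!r}")
    scores = np.asarray(scores, dtype=float)
    is_msi = _as_binary(labels)
    if is_msi.all() or not is_msi.any():
        raise ValueError("both classes are required to optimize a threshold")
    unique = np.unique(scores)
    if unique.size < 2:
        raise ValueError("all scores identical; threshold is degenerate")
    candidates = (unique[:-1] + unique[1:]) / 2.0
    n_pos = is_msi.sum()
    n_neg = (~is_msi).sum()
    best_t = candidates[0]
    best_j = -np.inf
    for t in candidates:
        pred = scores > t
        sens = np.sum(pred & is_msi) / n_pos
        spec = np.sum(~pred & ~is_msi) / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_t):
            best_t = t
            best_j = j
    return float(best_t)


def classify(
    expr: ExpressionMatrix,
    model: CentroidModel,
    standardize_with: str = "cohort",
    allow_missing_genes: bool = False,
) -> pd.DataFrame:
    """Score and label every sample: MSI iff score > model.threshold."""
    scores = score_samples(
        expr,
        model,
        standardize_with=standardize_with,
        allow_missing_genes=allow_missing_genes,
    )
    labels = np.where(scores.to_numpy() > model.threshold, "MSI", "MSS")
    return pd.DataFrame(
        {"msi_score": scores, "predicted_label": labels}, index=scores.index
    )


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    return np.array([str(v) == "MSI" for v in arr], dtype=bool)
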