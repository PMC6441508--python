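"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text: tab-separated expression matrices
(genes as rows, first column = gene ID, header = sample IDs), a sample
annotation CSV (``sample_id,msi_status,cohort,batch``), GMT gene-set
collections, one-gene-per-line signature files, and a versioned JSON
serialization of fitted centroid models.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import CentroidModel
from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GeneSignature,
    Platform,
    SampleAnnotation,
    ValueKind,
)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "read_model",
    "write_model",
    "bundled_signature",
]

MODEL_FORMAT_VERSION = 1


def read_expression_tsv(
    path: str | Path, platform: Platform | str, value_kind: ValueKind | str
) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix from TSV.

    The first column holds gene IDs, the header row sample IDs. Duplicate
    gene or sample IDs and non-numeric cells are rejected with an error
    naming the offender; rows are never silently dropped.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if frame.index.name is None and frame.shape[1] == 0:
        raise ValueError(f"{path}: malformed header or empty matrix")
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    try:
        values = frame.astype(float).to_numpy()
    except ValueError as exc:
        # locate the first bad cell for the error message
        for gene, row in frame.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at "
                        f"gene {gene!r}, sample {sample!r}"
                    ) from exc
        raise
    return ExpressionMatrix(values, gene_ids, sample_ids, platform, value_kind)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    if matrix.value_kind is ValueKind.COUNTS:
        frame = frame.astype(int)
    frame.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_csv(path: str | Path) -> list[SampleAnnotation]:
    """Read per-sample MSI annotations from CSV.

    Expected columns: ``sample_id``, ``msi_status`` (MSI-H/MSI-L/MSS) and
    optionally ``cohort`` and ``batch``.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "msi_status"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    annotations = []
    for _, row in frame.iterrows():
        annotations.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                msi_status_raw=row["msi_status"],
                cohort=row.get("cohort", ""),
                batch=row.get("batch", ""),
            )
        )
    return annotations


def write_annotation_csv(
    annotations: list[SampleAnnotation], path: str | Path
) -> None:
    frame = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "msi_status": [a.msi_status_raw for a in annotations],
            "cohort": [a.cohort for a in annotations],
            "batch": [a.batch for a in annotations],
        }
    )
    frame.to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (name, description, member genes)."""
    sets = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, description, frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene_set in collection:
            genes = "\t".join(sorted(gene_set.gene_ids))
            handle.write(f"{gene_set.name}\t{gene_set.description}\t{genes}\n")


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a gene signature: one gene ID per line, ``#`` comments allowed."""
    path = Path(path)
    gene_ids = []
    for lineno, line in enumerate(open(path), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene = line.split()[0]
        if gene in gene_ids:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        gene_ids.append(gene)
    if not gene_ids:
        warnings.warn(f"{path}: signature file contains no genes")
    return GeneSignature(
        gene_ids, name=name or path.stem, provenance={"source": str(path)}
    )


def write_signature(signature: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# signature: {signature.name}\n")
        for key, value in signature.provenance.items():
            handle.write(f"# {key}: {value}\n")
        for gene in signature.gene_ids:
            handle.write(f"{gene}\n")


def write_model(model: CentroidModel, path: str | Path) -> None:
    """Serialize a fitted centroid model to versioned, diffable JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "gene_ids": model.gene_ids,
        "centroid_msi": [float(v) for v in model.centroid_msi],
        "centroid_mss": [float(v) for v in model.centroid_mss],
        "threshold": float(model.threshold),
        "training_meta": _jsonable(model.training_meta),
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_model(path: str | Path) -> CentroidModel:
    with open(path) as handle:
        payload = json.load(handle)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    for field in ("gene_ids", "centroid_msi", "centroid_mss", "threshold"):
        if field not in payload:
            raise ValueError(f"{path}: model file missing field {field!r}")
    return CentroidModel(
        gene_ids=[str(g) for g in payload["gene_ids"]],
        centroid_msi=np.asarray(payload["centroid_msi"], dtype=float),
        centroid_mss=np.asarray(payload["centroid_mss"], dtype=float),
        threshold=float(payload["threshold"]),
        training_meta=payload.get("training_meta", {}),
    )


def bundled_signature() -> GeneSignature:
    """The packaged 25-gene cross-platform MSI signature (Entrez IDs)."""
    path = Path(__file__).parent / "data" / "signature_msi25.txt"
    return read_signature(path, name="msi25")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
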