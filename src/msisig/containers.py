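"""Core in-memory containers shared across the pipeline.

Gene identifiers are Entrez IDs stored as strings throughout; gene symbols
are carried only as free-text metadata. Expression matrices are oriented
genes-as-rows, samples-as-columns, and tagged with the measurement platform
and the kind of value they hold so that downstream stages can refuse inputs
they were not designed for (e.g. TMM on log intensities).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "ValueKind",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSignature",
    "GeneSet",
    "GeneSetCollection",
    "pool_msi_label",
]


class Platform(str, enum.Enum):
    """Measurement platform of an expression matrix."""

    RNASEQ = "rnaseq"
    MICROARRAY = "microarray"


class ValueKind(str, enum.Enum):
    """What the numbers in an expression matrix represent."""

    COUNTS = "counts"
    LOG_INTENSITY = "log_intensity"
    LOG_CPM = "log_cpm"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with identity and provenance.

    Parameters
    ----------
    values
        2-D float array of shape ``(n_genes, n_samples)``.
    gene_ids
        Unique gene identifiers (Entrez IDs as strings), one per row.
    sample_ids
        Unique sample identifiers, one per column.
    platform
        Measurement platform.
    value_kind
        Interpretation of the values; ``counts`` requires non-negative
        integers.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    platform: Platform
    value_kind: ValueKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.platform = Platform(self.platform)
        self.value_kind = ValueKind(self.value_kind)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_samples != len(self.sample_ids):
            raise ValueError(
                f"matrix has {n_samples} columns but "
                f"{len(self.sample_ids)} sample ids"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.value_kind is ValueKind.COUNTS:
            if np.any(self.values < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be integers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        """Row indices for ``gene_ids``; raises on any absent gene."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.platform,
            self.value_kind,
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing}")
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.platform,
            self.value_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


_RAW_TO_POOLED = {"MSI-H": "MSI", "MSI-L": "MSS", "MSS": "MSS"}


def pool_msi_label(raw: str) -> str:
    """Pool the three-level MSI grade into the binary analysis label.

    MSI-H is the MSI class; MSI-L tumours share the clinicopathologic
    profile of stable tumours and are pooled with MSS.
    """
    try:
        return _RAW_TO_POOLED[raw]
    except KeyError:
        raise ValueError(
            f"unknown MSI status {raw!r}; expected MSI-H, MSI-L or MSS"
        ) from None


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation.

    ``msi_label`` is the pooled binary label derived from the raw
    three-level grade: MSI-H maps to MSI, MSI-L and MSS map to MSS.
    """

    sample_id: str
    msi_status_raw: str
    cohort: str = ""
    batch: str = ""
    msi_label: str = field(init=False)

    def __post_init__(self) -> None:
        self.msi_label = pool_msi_label(self.msi_status_raw)


@dataclass
class GeneSignature:
    """Ordered list of unique gene identifiers with provenance metadata."""

    gene_ids: list[str]
    name: str = "signature"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene ids in signature: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


@dataclass
class GeneSet:
    name: str
    description: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.gene_ids = frozenset(str(g) for g in self.gene_ids)
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        dup = _duplicates([s.name for s in self.sets])
        if dup:
            raise ValueError(f"duplicate gene-set names: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup
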