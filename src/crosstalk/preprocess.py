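"""Quality control and normalization shared by the cell and spot matrices.

QC applies four per-unit thresholds (a "unit" is a cell or a spot): a
minimum total count, a minimum number of expressed genes, a maximum
mitochondrial percentage, and a minimum log10(genes)/log10(counts) ratio.
The last criterion catches low-complexity units whose reads concentrate in
few genes. Units with counts <= 1 never reach the ratio (log10 undefined or
zero); they are removed by the count threshold first.

Normalization is per-unit library scaling to a fixed total followed by
natural log1p: value = ln(1 + scale_factor * count / unit_total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CellMatrix, SpotMatrix

__all__ = ["QCThresholds", "NormalizedMatrix", "qc_filter", "normalize"]


@dataclass(frozen=True)
class QCThresholds:
    """The four QC thresholds.

    Inequalities follow the stated rules exactly: counts and genes are
    "minimum of" (non-strict), the ratio is "at least" (non-strict), the
    mitochondrial percentage is "less than" (strict).
    """

    min_counts: int = 500
    min_genes: int = 250
    max_mito_pct: float = 20.0
    min_log10_genes_over_log10_counts: float = 0.80
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0 <= self.max_mito_pct <= 100):
            raise ValueError("max_mito_pct must be in [0, 100]")
        for name in ("min_counts", "min_genes", "min_log10_genes_over_log10_counts"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with per-unit metadata.

    ``values[i, j] = ln(1 + scale_factor * counts[i, j] / row_total_i)``.
    ``meta`` carries the unit labels of the source matrix (cell_type /
    condition / sample_id for cells; sample_id / condition / x / y for
    spots), indexed 0..n-1 in unit order.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    unit_ids: list[str]
    meta: pd.DataFrame
    scale_factor: float = 10_000.0

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-unit expression of one gene; KeyError if absent."""
        try:
            j = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(gene) from None
        return np.asarray(self.values[:, j].todense()).ravel()


def _qc_metrics(counts: sp.csr_matrix, gene_ids, mito_prefix: str) -> pd.DataFrame:
    counts = sp.csr_matrix(counts)
    total = np.asarray(counts.sum(axis=1)).ravel()
    genes = counts.getnnz(axis=1)
    mito_mask = np.array([g.startswith(mito_prefix) for g in gene_ids])
    if mito_mask.any():
        mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
        ratio = np.where(
            total > 1, np.log10(np.maximum(genes, 1)) / np.log10(np.maximum(total, 2)), np.nan
        )
    return pd.DataFrame(
        {"counts": total, "genes": genes, "mito_pct": mito_pct, "ratio": ratio}
    )


def qc_filter(matrix, thresholds: QCThresholds = QCThresholds()):
    """Filter cells or spots by the four QC thresholds.

    Returns ``(filtered_matrix, report)`` where ``report`` is a DataFrame
    with one row per input unit: its metrics, whether it was kept, and a
    comma-separated list of failed criteria. A unit failing several criteria
    appears in each criterion's removal count.

    Units with counts <= 1 are removed by ``min_counts`` and never evaluated
    for the log-ratio (which would be undefined).
    """
    if not isinstance(matrix, (CellMatrix, SpotMatrix)):
        raise TypeError("qc_filter expects a CellMatrix or SpotMatrix")
    ids = matrix.cell_ids if isinstance(matrix, CellMatrix) else matrix.spot_ids
    m = _qc_metrics(matrix.counts, matrix.gene_ids, thresholds.mito_gene_prefix)

    fail_counts = m["counts"] < thresholds.min_counts
    fail_genes = m["genes"] < thresholds.min_genes
    fail_mito = ~(m["mito_pct"] < thresholds.max_mito_pct)
    # ratio evaluated only where defined; units with counts<=1 already fail min_counts
    ratio_defined = m["counts"] > 1
    fail_ratio = ratio_defined & ~(
        m["ratio"] >= thresholds.min_log10_genes_over_log10_counts
    )

    keep = ~(fail_counts | fail_genes | fail_mito | fail_ratio)
    reasons = []
    for fc, fg, fm, fr in zip(fail_counts, fail_genes, fail_mito, fail_ratio):
        r = []
        if fc:
            r.append("min_counts")
        if fg:
            r.append("min_genes")
        if fm:
            r.append("max_mito_pct")
        if fr:
            r.append("min_ratio")
        reasons.append(",".join(r))
    report = m.assign(unit_id=list(ids), kept=keep.to_numpy(), reasons=reasons)[
        ["unit_id", "counts", "genes", "mito_pct", "ratio", "kept", "reasons"]
    ]
    return matrix.subset(keep.to_numpy()), report


def normalize(matrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Library-scale and log1p a QC-passed count matrix.

    Every unit must have a positive total (guaranteed after QC); a zero row
    total raises.
    """
    counts = sp.csr_matrix(matrix.counts, dtype=float)
    total = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(total <= 0):
        bad = int(np.sum(total <= 0))
        raise ValueError(f"{bad} units have zero total counts; run QC first")
    scaled = sp.diags(scale_factor / total) @ counts
    scaled.data = np.log1p(scaled.data)
    if isinstance(matrix, CellMatrix):
        ids = list(matrix.cell_ids)
        meta = pd.DataFrame(
            {
                "cell_type": matrix.cell_type,
                "condition": matrix.condition,
                "sample_id": matrix.sample_id,
            }
        )
    elif isinstance(matrix, SpotMatrix):
        ids = list(matrix.spot_ids)
        meta = pd.DataFrame(
            {
                "sample_id": matrix.sample_id,
                "condition": matrix.condition,
                "x": matrix.xy[:, 0],
                "y": matrix.xy[:, 1],
            }
        )
    else:
        raise TypeError("normalize expects a CellMatrix or SpotMatrix")
    return NormalizedMatrix(
        values=sp.csr_matrix(scaled),
        gene_ids=list(matrix.gene_ids),
        unit_ids=ids,
        meta=meta.reset_index(drop=True),
        scale_factor=scale_factor,
    )
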