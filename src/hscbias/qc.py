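"""Per-cell QC on mapping statistics, CPM normalization, variable-gene selection.

QC excludes a cell when ANY criterion is violated: fewer than 500,000 mapped
reads, more than 10% of mapped reads on the mitochondrial chromosome, or
fewer than 3,000 detected genes. The inequalities are strict, so boundary
cells (exactly 500,000 reads, exactly 10% mito, exactly 3,000 genes) pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CellStats, CountsMatrix


@dataclass
class QCThresholds:
    min_mapped_reads: int = 500_000
    max_pct_mito: float = 10.0
    min_genes_detected: int = 3_000

    def __post_init__(self) -> None:
        if min(self.min_mapped_reads, self.max_pct_mito, self.min_genes_detected) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class ExpressionMatrix:
    """Gene x cell real-valued expression, either CPM or log2(CPM+1)."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    scale: str
    cell_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match id lists")
        if self.scale not in ("cpm", "log2cpm1"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    def group_mask(self, group: str) -> np.ndarray:
        if self.cell_groups is None:
            raise ValueError("no group labels attached")
        return np.array([self.cell_groups[c] == group for c in self.cell_ids])

    @property
    def groups(self) -> list[str]:
        if self.cell_groups is None:
            return []
        out: list[str] = []
        for c in self.cell_ids:
            g = self.cell_groups[c]
            if g not in out:
                out.append(g)
        return out


def filter_cells(
    stats: list[CellStats], thresholds: QCThresholds | None = None
) -> dict[str, bool]:
    """Pass/fail decision per cell; fails if any single criterion is violated."""
    thresholds = thresholds or QCThresholds()
    return {
        s.cell_id: (
            s.mapped_reads >= thresholds.min_mapped_reads
            and s.pct_mito <= thresholds.max_pct_mito
            and s.genes_detected >= thresholds.min_genes_detected
        )
        for s in stats
    }


def apply_cell_filter(
    counts: CountsMatrix, stats: list[CellStats], thresholds: QCThresholds | None = None
) -> CountsMatrix:
    """Drop failing cells from a counts matrix; every cell needs a stats row."""
    by_id = {s.cell_id: s for s in stats}
    missing = [c for c in counts.cell_ids if c not in by_id]
    if missing:
        raise ValueError(f"no mapping statistics for cells: {missing[:5]}")
    decisions = filter_cells([by_id[c] for c in counts.cell_ids], thresholds)
    keep = [c for c in counts.cell_ids if decisions[c]]
    return counts.subset_cells(keep)


def cpm_normalize(counts: CountsMatrix) -> ExpressionMatrix:
    """Counts-per-million: value(g, c) = counts(g, c) / total(c) * 1e6."""
    totals = counts.counts.sum(axis=0).astype(float)
    zero = [counts.cell_ids[i] for i in np.flatnonzero(totals == 0)]
    if zero:
        raise ValueError(f"cells with zero total count: {zero[:5]}")
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        values=counts.counts / totals * 1e6,
        scale="cpm",
        cell_groups=dict(counts.cell_groups),
    )


def log_transform(cpm: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1), the scale used for PCA, clustering and level tests."""
    if cpm.scale != "cpm":
        raise ValueError(f"expected cpm input, got {cpm.scale!r}")
    return ExpressionMatrix(
        gene_ids=list(cpm.gene_ids),
        cell_ids=list(cpm.cell_ids),
        values=np.log2(cpm.values + 1.0),
        scale="log2cpm1",
        cell_groups=dict(cpm.cell_groups) if cpm.cell_groups else None,
    )


def select_variable_genes(
    cpm: ExpressionMatrix, cv_min: float = 1.0, mean_cpm_min: float = 1.0
) -> list[str]:
    """Genes with CV >= cv_min and mean CPM > mean_cpm_min, on the CPM scale.

    CV is sd/mean with the sample (n-1) standard deviation. Order of the
    returned list follows the input gene order.
    """
    if cpm.scale != "cpm":
        raise ValueError(f"expected cpm input, got {cpm.scale!r}")
    if len(cpm.cell_ids) < 2:
        raise ValueError("variable-gene selection needs at least 2 cells")
    mean = cpm.values.mean(axis=1)
    sd = cpm.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    keep = (cv >= cv_min) & (mean > mean_cpm_min)
    return [g for g, k in zip(cpm.gene_ids, keep) if k]
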