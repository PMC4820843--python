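"""Shared in-memory containers for the pipeline.

Every reader in :mod:`hscbias.io_formats` validates into one of these types,
so downstream stages never touch raw files. Validation is eager: constructing
an instance with inconsistent fields raises ``ValueError`` immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))[:5]}")


@dataclass
class CountsMatrix:
    """Gene x cell integer read counts with a group label per cell.

    ``counts[i, j]`` is the count for ``gene_ids[i]`` in ``cell_ids[j]``.
    ``cell_groups`` maps every cell id to its group (e.g. ``"young"`` /
    ``"old"``); cells without a label are rejected.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    cell_groups: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.cell_ids if c not in self.cell_groups]
        if missing:
            raise ValueError(f"cells without a group label: {missing[:5]}")

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order over cells."""
        out: list[str] = []
        for c in self.cell_ids:
            g = self.cell_groups[c]
            if g not in out:
                out.append(g)
        return out

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.cell_groups[c] == group for c in self.cell_ids])

    def subset_cells(self, keep: list[str]) -> "CountsMatrix":
        idx = [self.cell_ids.index(c) for c in keep]
        return CountsMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=list(keep),
            counts=self.counts[:, idx],
            cell_groups={c: self.cell_groups[c] for c in keep},
        )


@dataclass
class CellStats:
    """Per-cell mapping statistics driving QC.

    ``genes_detected`` counts genes at >= 1 RPKM as reported by the upstream
    quantification; it is taken as authoritative and never recomputed from
    counts.
    """

    cell_id: str
    input_reads: int
    mapped_reads: int
    pct_mapped: float
    pct_mito: float
    genes_detected: int

    def __post_init__(self) -> None:
        if min(self.input_reads, self.mapped_reads, self.genes_detected) < 0:
            raise ValueError(f"{self.cell_id}: negative count field")
        if self.mapped_reads > self.input_reads:
            raise ValueError(
                f"{self.cell_id}: mapped_reads ({self.mapped_reads}) exceeds "
                f"input_reads ({self.input_reads})"
            )
        for name in ("pct_mapped", "pct_mito"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.cell_id}: {name}={v} outside [0, 100]")


@dataclass
class GeneSet:
    name: str
    members: set[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class CtMatrix:
    """Assay x cell qPCR cycle-threshold values; NaN means not detected.

    ``lod`` is the limit-of-detection cycle; values at or beyond it are
    treated as undetected at read time, so stored Ct values lie in
    ``(0, lod]``.
    """

    assay_ids: list[str]
    cell_ids: list[str]
    ct: np.ndarray
    reference_assay: str = "Kit"
    lod: float = 40.0

    def __post_init__(self) -> None:
        _check_unique(self.assay_ids, "assay")
        _check_unique(self.cell_ids, "cell")
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.assay_ids), len(self.cell_ids)):
            raise ValueError("ct shape does not match assay/cell id lists")
        if self.reference_assay not in self.assay_ids:
            raise ValueError(
                f"reference assay {self.reference_assay!r} not among assays"
            )
        finite = self.ct[np.isfinite(self.ct)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > self.lod)):
            raise ValueError(f"Ct values must lie in (0, {self.lod}]")


LINEAGES = ("platelet", "myeloid", "B", "T")


@dataclass
class CloneRecord:
    """One transplanted clone's peripheral-blood output over time.

    ``contributions`` maps week -> ``{platelet, myeloid, B, T}`` percent
    contribution of the clone to each lineage at that time point.
    """

    clone_id: str
    group: str
    source_population: str
    contributions: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contributions:
            raise ValueError(f"clone {self.clone_id}: no time points")
        for week, lin in self.contributions.items():
            missing = [l for l in LINEAGES if l not in lin]
            if missing:
                raise ValueError(
                    f"clone {self.clone_id} week {week}: missing {missing}"
                )
            for l in LINEAGES:
                if lin[l] < 0:
                    raise ValueError(
                        f"clone {self.clone_id} week {week}: negative {l} "
                        f"contribution {lin[l]}"
                    )

    @property
    def weeks(self) -> list[int]:
        return sorted(self.contributions)
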