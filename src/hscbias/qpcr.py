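"""Single-cell qPCR analytics: ΔCt normalization and group comparisons.

ΔCt is computed relative to a reference assay (Kit by default) in each
cell, with the sign convention reference minus assay so that larger ΔCt
means higher expression. Cells without reference expression are excluded
outright. Frequencies (fraction of retained cells detecting an assay) are
compared by chi-square; levels among expressing cells by a two-tailed
two-sample t-test; co-expression of a gene panel by a two-sample KS test
on the per-cell count of detected panel assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .datatypes import CtMatrix, GeneSet


@dataclass
class DeltaCtMatrix:
    """Assay x cell ΔCt (reference minus assay Ct; NaN = undetected)."""

    assay_ids: list[str]
    cell_ids: list[str]
    delta: np.ndarray
    reference_assay: str
    excluded_cells: dict[str, str] = field(default_factory=dict)
    cell_groups: dict[str, str] | None = None

    def detected(self) -> np.ndarray:
        return np.isfinite(self.delta)

    def group_mask(self, group: str) -> np.ndarray:
        if self.cell_groups is None:
            raise ValueError("no group labels attached")
        return np.array([self.cell_groups[c] == group for c in self.cell_ids])


@dataclass
class AssayComparison:
    assay_id: str
    freq_a: float | None = None
    freq_b: float | None = None
    p_freq: float | None = None
    mean_delta_a: float | None = None
    mean_delta_b: float | None = None
    n_expressing_a: int = 0
    n_expressing_b: int = 0
    p_level: float | None = None
    untestable: bool = False


def delta_ct(ct: CtMatrix, cell_groups: dict[str, str] | None = None) -> DeltaCtMatrix:
    """Normalize each cell to the reference assay; drop reference-negative cells."""
    ref_idx = ct.assay_ids.index(ct.reference_assay)
    ref = ct.ct[ref_idx, :]
    has_ref = np.isfinite(ref)
    excluded = {
        ct.cell_ids[i]: f"no {ct.reference_assay} expression"
        for i in np.flatnonzero(~has_ref)
    }
    keep = np.flatnonzero(has_ref)
    delta = ref[keep][None, :] - ct.ct[:, keep]
    retained = [ct.cell_ids[i] for i in keep]
    return DeltaCtMatrix(
        assay_ids=list(ct.assay_ids),
        cell_ids=retained,
        delta=delta,
        reference_assay=ct.reference_assay,
        excluded_cells=excluded,
        cell_groups=(
            {c: cell_groups[c] for c in retained} if cell_groups is not None else None
        ),
    )


def _two_groups(delta: DeltaCtMatrix, group_a, group_b):
    groups = []
    if delta.cell_groups is not None:
        for c in delta.cell_ids:
            g = delta.cell_groups[c]
            if g not in groups:
                groups.append(g)
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, found {groups}")
        group_a, group_b = groups
    mask_a, mask_b = delta.group_mask(group_a), delta.group_mask(group_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("a group has zero retained cells")
    return mask_a, mask_b


def expression_frequency(
    delta: DeltaCtMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    continuity: bool = False,
) -> list[AssayComparison]:
    """Per-assay detection frequency per group with a 2x2 chi-square p."""
    mask_a, mask_b = _two_groups(delta, group_a, group_b)
    det = delta.detected()
    out = []
    for i, assay in enumerate(delta.assay_ids):
        ka, kb = int(det[i, mask_a].sum()), int(det[i, mask_b].sum())
        na, nb = int(mask_a.sum()), int(mask_b.sum())
        table = np.array([[ka, na - ka], [kb, nb - kb]])
        if table.sum(axis=0).min() == 0:  # all-detected or none-detected
            p = 1.0
        else:
            p = float(scipy.stats.chi2_contingency(table, correction=continuity)[1])
        out.append(
            AssayComparison(
                assay_id=assay,
                freq_a=ka / na,
                freq_b=kb / nb,
                p_freq=p,
                n_expressing_a=ka,
                n_expressing_b=kb,
            )
        )
    return out


def expression_level_test(
    delta: DeltaCtMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
) -> list[AssayComparison]:
    """Per-assay mean ΔCt among expressing cells with a two-tailed t-test p.

    An assay with fewer than 2 expressing cells in either group is flagged
    untestable and carries no p-value.
    """
    mask_a, mask_b = _two_groups(delta, group_a, group_b)
    out = []
    for i, assay in enumerate(delta.assay_ids):
        va = delta.delta[i, mask_a]
        vb = delta.delta[i, mask_b]
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        comp = AssayComparison(
            assay_id=assay,
            n_expressing_a=va.size,
            n_expressing_b=vb.size,
            mean_delta_a=float(va.mean()) if va.size else None,
            mean_delta_b=float(vb.mean()) if vb.size else None,
        )
        if va.size < 2 or vb.size < 2:
            comp.untestable = True
        else:
            if np.ptp(np.concatenate([va, vb])) == 0:
                comp.p_level = 1.0  # identical constant samples
            else:
                comp.p_level = float(scipy.stats.ttest_ind(va, vb).pvalue)
        out.append(comp)
    return out


def coexpression_ks(
    delta: DeltaCtMatrix,
    panel: GeneSet,
    group_a: str | None = None,
    group_b: str | None = None,
) -> tuple[float, float]:
    """KS test on per-cell counts of detected panel assays between groups.

    Returns (D, p). The count distribution summarizes how broadly each cell
    co-expresses the lineage panel.
    """
    present = [a for a in delta.assay_ids if a in panel.members]
    if not present:
        raise ValueError(f"panel {panel.name!r} has no assays in the matrix")
    mask_a, mask_b = _two_groups(delta, group_a, group_b)
    idx = [delta.assay_ids.index(a) for a in present]
    counts = delta.detected()[idx, :].sum(axis=0)
    res = scipy.stats.ks_2samp(counts[mask_a], counts[mask_b])
    return float(res.statistic), float(res.pvalue)
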