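"""Readers and writers for the external formats the pipeline touches.

Counts come in as TSV (genes as rows by convention, ``transpose=True`` for
the other orientation) or MatrixMarket triplets with row/column id sidecars;
gene sets as GMT; Ct matrices as CSV (empty fields or values at/above the
limit of detection mean "not detected", matching Biomark export
conventions); clone tables as long-form CSV. All ids are case-sensitive
exact strings.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import LINEAGES, CellStats, CloneRecord, CountsMatrix, CtMatrix, GeneSet

# ---------------------------------------------------------------------------
# counts


def read_cell_groups(path) -> dict[str, str]:
    """Read a two-column (cell_id, group) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: metadata needs cell_id and group columns")
    cells, groups = df.iloc[:, 0], df.iloc[:, 1]
    if cells.duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids in metadata")
    return dict(zip(cells, groups))


def read_counts(path, metadata_path, transpose: bool = False) -> CountsMatrix:
    """Read a counts TSV (genes as rows) or MatrixMarket triplet.

    For MatrixMarket, ``path`` is the ``.mtx`` file and ``<path>.rows`` /
    ``<path>.cols`` hold gene and cell ids, one per line. ``metadata_path``
    is a cell_id -> group TSV; cells present in the matrix but absent from
    the metadata are an error.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = path.with_suffix(".mtx.rows").read_text().split()
        cell_ids = path.with_suffix(".mtx.cols").read_text().split()
        values = np.asarray(mat)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        values = df.to_numpy()
    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    if not np.issubdtype(np.asarray(values).dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in counts")
    groups = read_cell_groups(metadata_path)
    missing = [c for c in cell_ids if c not in groups]
    if missing:
        raise ValueError(f"{path}: cells missing from metadata: {missing[:5]}")
    return CountsMatrix(gene_ids, cell_ids, values, {c: groups[c] for c in cell_ids})


def write_counts(cm: CountsMatrix, path, metadata_path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {"cell_id": cm.cell_ids, "group": [cm.cell_groups[c] for c in cm.cell_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def write_counts_mtx(cm: CountsMatrix, path) -> None:
    """Write MatrixMarket triplet plus ``.rows`` / ``.cols`` id sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
    path.with_suffix(".mtx.rows").write_text("\n".join(cm.gene_ids) + "\n")
    path.with_suffix(".mtx.cols").write_text("\n".join(cm.cell_ids) + "\n")


# ---------------------------------------------------------------------------
# per-cell mapping statistics

_STATS_COLS = [
    "cell_id",
    "input_reads",
    "mapped_reads",
    "pct_mapped",
    "pct_mito",
    "genes_detected",
]


def read_cell_stats(path) -> list[CellStats]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _STATS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids")
    return [
        CellStats(
            cell_id=str(r.cell_id),
            input_reads=int(r.input_reads),
            mapped_reads=int(r.mapped_reads),
            pct_mapped=float(r.pct_mapped),
            pct_mito=float(r.pct_mito),
            genes_detected=int(r.genes_detected),
        )
        for r in df.itertuples()
    ]


def write_cell_stats(stats: list[CellStats], path) -> None:
    pd.DataFrame([vars(s) for s in stats])[_STATS_COLS].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members…``.

    Member order is discarded and duplicate members collapse into the set.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >=3"
                )
            members = {m for m in fields[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set with no members")
            sets.append(GeneSet(name=fields[0], members=members, description=fields[1]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Ct matrices


def read_ct(path, reference_assay: str = "Kit", lod: float = 40.0) -> CtMatrix:
    """Read an assay x cell Ct CSV.

    Empty fields and values >= ``lod`` both mean "not detected" (Biomark
    exports use both conventions) and are stored as NaN.
    """
    df = pd.read_csv(path, index_col=0)
    ct = df.to_numpy(dtype=float)
    ct = np.where(np.isfinite(ct) & (ct >= lod), np.nan, ct)
    return CtMatrix(
        assay_ids=[str(a) for a in df.index],
        cell_ids=[str(c) for c in df.columns],
        ct=ct,
        reference_assay=reference_assay,
        lod=lod,
    )


def write_ct(ct: CtMatrix, path) -> None:
    df = pd.DataFrame(ct.ct, index=ct.assay_ids, columns=ct.cell_ids)
    df.index.name = "assay_id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# clone tables

_CLONE_COLS = ["clone_id", "group", "source_population", "week", *LINEAGES]


def read_clone_table(path) -> list[CloneRecord]:
    """Read a long-form clone CSV into per-clone records.

    One row per (clone, week); rows for the same clone are folded into one
    record with a per-week contribution map. Duplicate (clone, week) rows
    and negative contributions are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CLONE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.duplicated(subset=["clone_id", "week"]).any():
        dup = df[df.duplicated(subset=["clone_id", "week"])].iloc[0]
        raise ValueError(f"{path}: duplicate row for clone {dup.clone_id} week {dup.week}")
    records = []
    for clone_id, sub in df.groupby("clone_id", sort=False):
        meta = sub.iloc[0]
        contributions = {
            int(r.week): {l: float(getattr(r, l)) for l in LINEAGES}
            for r in sub.itertuples()
        }
        records.append(
            CloneRecord(
                clone_id=str(clone_id),
                group=str(meta.group),
                source_population=str(meta.source_population),
                contributions=contributions,
            )
        )
    return records


def write_clone_table(clones: list[CloneRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CLONE_COLS)
        for c in clones:
            for week in c.weeks:
                lin = c.contributions[week]
                w.writerow(
                    [c.clone_id, c.group, c.source_population, week]
                    + [repr(float(lin[l])) for l in LINEAGES]
                )
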