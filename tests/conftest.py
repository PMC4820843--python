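import numpy as np
import pytest

from hscbias import CellStats, CountsMatrix


@pytest.fixture
def tiny_counts() -> CountsMatrix:
    """3 genes x 4 cells, two groups of two."""
    return CountsMatrix(
        gene_ids=["Vwf", "Itgb3", "Actb"],
        cell_ids=["y1", "y2", "o1", "o2"],
        counts=np.array([[0, 1, 5, 9], [2, 0, 4, 4], [10, 9, 1, 7]]),
        cell_groups={"y1": "young", "y2": "young", "o1": "old", "o2": "old"},
    )


@pytest.fixture
def stats_row():
    def make(cell_id="c1", mapped=600_000, mito=5.0, genes=3_500):
        return CellStats(
            cell_id=cell_id,
            input_reads=max(mapped, 1_000_000),
            mapped_reads=mapped,
            pct_mapped=80.0,
            pct_mito=mito,
            genes_detected=genes,
        )

    return make
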