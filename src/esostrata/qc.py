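"""Gene/cell quality filters and per-condition equalized downsampling.

Filtering conventions: a gene is kept when it has nonzero counts in at least
``min_expressing_cells`` cells (default 4, i.e. genes seen in 3 or fewer cells
are dropped); a cell is kept when its unique-gene count lies in [250, 3500]
and its total UMI count in [100, 9500], both bounds inclusive ("under X /
over Y" read strictly).  Doublets and debris are handled by these bounds
alone.  The pipeline order is gene filter -> cell filter -> downsample ->
final gene re-filter, the last pass removing genes stranded by cell removal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["QCReport", "filter_genes", "filter_cells", "downsample_equalize", "run_qc"]


@dataclass
class QCReport:
    genes_removed: int = 0
    cells_removed_by_rule: dict = field(default_factory=dict)
    cells_retained_per_condition: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("genes_removed", "", self.genes_removed)]
        rows += [("cells_removed", rule, n) for rule, n in self.cells_removed_by_rule.items()]
        rows += [("cells_retained", cond, n) for cond, n in self.cells_retained_per_condition.items()]
        return pd.DataFrame(rows, columns=["metric", "key", "value"])


def filter_genes(cm: CountMatrix, min_expressing_cells: int = 4) -> CountMatrix:
    """Keep genes with nonzero counts in >= ``min_expressing_cells`` cells."""
    n_expressing = np.asarray((cm.counts > 0).sum(axis=0)).ravel()
    return cm.subset_genes(n_expressing >= min_expressing_cells)


def filter_cells(
    cm: CountMatrix,
    gene_bounds: tuple[int, int] = (250, 3500),
    total_bounds: tuple[int, int] = (100, 9500),
) -> tuple[CountMatrix, QCReport]:
    """Keep cells inside the unique-gene and total-UMI bounds (inclusive).

    A cell failing both rules is tallied under the gene-count rule.
    """
    genes_per_cell = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    total_per_cell = np.asarray(cm.counts.sum(axis=1)).ravel()
    ok_genes = (genes_per_cell >= gene_bounds[0]) & (genes_per_cell <= gene_bounds[1])
    ok_total = (total_per_cell >= total_bounds[0]) & (total_per_cell <= total_bounds[1])
    keep = ok_genes & ok_total
    report = QCReport(
        cells_removed_by_rule={
            "gene_count": int((~ok_genes).sum()),
            "total_count": int((ok_genes & ~ok_total).sum()),
        }
    )
    out = cm.subset_cells(keep)
    if "condition" in out.cell_meta.columns:
        report.cells_retained_per_condition = (
            out.cell_meta["condition"].value_counts().to_dict()
        )
    return out, report


class ConditionSizeError(ValueError):
    """A condition holds fewer cells than the downsampling cap."""


def downsample_equalize(
    cm: CountMatrix,
    per_condition_cap: int = 1500,
    seed: int = 0,
    cap_to_min: bool = False,
) -> CountMatrix:
    """Uniformly subsample, without replacement, to the cap in each condition.

    Retained cells keep their count vectors untouched.  A condition smaller
    than the cap raises :class:`ConditionSizeError` unless ``cap_to_min`` is
    set, in which case the smallest condition's size becomes the cap.
    """
    if "condition" not in cm.cell_meta.columns:
        raise ValueError("downsampling needs a 'condition' column in cell_meta")
    cond = cm.cell_meta["condition"].to_numpy()
    sizes = pd.Series(cond).value_counts()
    cap = per_condition_cap
    if cap_to_min:
        cap = min(cap, int(sizes.min()))
    else:
        small = sizes[sizes < cap]
        if len(small):
            raise ConditionSizeError(
                f"condition {small.index[0]!r} has {small.iloc[0]} cells, "
                f"below the cap of {cap}; pass cap_to_min to use the minimum"
            )
    rng = np.random.default_rng(seed)
    keep = np.zeros(cm.n_cells, dtype=bool)
    for c in sizes.index:
        idx = np.flatnonzero(cond == c)
        keep[rng.choice(idx, size=cap, replace=False)] = True
    return cm.subset_cells(keep)


def run_qc(
    cm: CountMatrix,
    min_cells_per_gene: int = 4,
    gene_bounds: tuple[int, int] = (250, 3500),
    total_bounds: tuple[int, int] = (100, 9500),
    per_condition_cap: int = 1500,
    seed: int = 0,
    cap_to_min: bool = False,
) -> tuple[CountMatrix, QCReport]:
    """Full QC stage: gene filter, cell filter, downsample, gene re-filter."""
    n_genes_in = cm.n_genes
    out = filter_genes(cm, min_cells_per_gene)
    out, report = filter_cells(out, gene_bounds, total_bounds)
    out = downsample_equalize(out, per_condition_cap, seed=seed, cap_to_min=cap_to_min)
    out = filter_genes(out, min_cells_per_gene)
    report.genes_removed = n_genes_in - out.n_genes
    if "condition" in out.cell_meta.columns:
        report.cells_retained_per_condition = (
            out.cell_meta["condition"].value_counts().to_dict()
        )
    return out, report
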