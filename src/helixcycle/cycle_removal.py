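"""Cell-cycle effect removal by discarding stage-explained genes.

For every gene, the fraction of expression variance explained by the
inferred stages (one-way SS_between / SS_total over the G1/S/G2M groups) is
computed on the log2 scale; genes above a threshold are treated as
cell-cycle-related and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix
from .staging import StageAssignment

logger = logging.getLogger("helixcycle")


@dataclass
class VarianceExplainedTable:
    gene_ids: list[str]
    r2: np.ndarray          # in [0, 1], one entry per gene


def variance_explained(X: ExpressionMatrix, stages: StageAssignment
                       ) -> VarianceExplainedTable:
    """Per-gene fraction of variance explained by the stage grouping.

    r² = SS_between / SS_total of the one-way decomposition over stage
    groups; empty stages are ignored and constant genes get r² = 0 by
    convention. Under random labels its expectation is (K−1)/(N−1).
    """
    labels = np.asarray(stages.labels)
    if labels.size != X.n_cells:
        raise ValueError("stage assignment does not cover the matrix's cells")
    groups = [np.flatnonzero(labels == s) for s in sorted(set(labels.tolist()))]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("all cells are in one stage; no variance to decompose")
    vals = X.values
    grand = vals.mean(axis=1)
    ss_total = ((vals - grand[:, None]) ** 2).sum(axis=1)
    ss_between = np.zeros_like(ss_total)
    for g in groups:
        gm = vals[:, g].mean(axis=1)
        ss_between += g.size * (gm - grand) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return VarianceExplainedTable(gene_ids=list(X.gene_ids),
                                  r2=np.clip(r2, 0.0, 1.0))


def remove_cycle_genes(X: ExpressionMatrix, table: VarianceExplainedTable,
                       threshold: float = 0.05
                       ) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose stage-explained variance reaches `threshold`.

    Returns the reduced matrix and the list of removed genes. Values of the
    surviving genes and the cell set are untouched.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    r2 = dict(zip(table.gene_ids, table.r2))
    keep = [i for i, g in enumerate(X.gene_ids) if r2.get(g, 0.0) < threshold]
    removed = [g for g in X.gene_ids if r2.get(g, 0.0) >= threshold]
    if not keep:
        raise ValueError("threshold removed every gene; raise the threshold")
    if removed:
        logger.info("removed %d cell-cycle-related gene(s)", len(removed))
    reduced = ExpressionMatrix(
        X.values[keep], [X.gene_ids[i] for i in keep], list(X.cell_ids), X.scale
    )
    return reduced, removed
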