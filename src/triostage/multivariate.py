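"""Sample-level PCA and the loading-magnitude gene ranking.

PCA runs on log2(FPKM+1) of the expressed genes (optionally protein-coding
only), gene-centred but not unit-scaled, so highly variable genes keep
their weight. Genes are ranked by the mean absolute loading across a
chosen set of PCs — the PCs that visually separate the tissue groups in a
biplot — and the top fraction is flagged as the most group-informative
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, UsageError
from .expression import ExpressionMatrix
from .staging import StagePartition

logger = logging.getLogger("triostage")

DEFAULT_TOP_FRACTION = 0.05


@dataclass
class PCAResult:
    loadings: pd.DataFrame        # genes x PCs (rotation matrix)
    scores: pd.DataFrame          # samples x PCs
    explained_variance: pd.Series  # per PC
    gene_subset: str


@dataclass
class GeneRanking:
    table: pd.DataFrame  # index gene; loadings, rank_metric, rank, top flag
    pcs: list[int]
    top_fraction: float

    @property
    def top_genes(self) -> pd.Index:
        return self.table.index[self.table["top"]]


def pca_samples(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation | None = None,
    gene_subset: str = "all",
    n_pcs: int = 10,
) -> PCAResult:
    """PCA of samples over expressed genes on centred log2(FPKM+1).

    ``gene_subset``: 'all' expressed genes or 'protein_coding' only (needs
    the annotation). PCs are ordered by decreasing explained variance with
    a deterministic sign convention: the largest-magnitude loading of each
    PC is made positive.
    """
    genes = expr.expressed_genes
    if gene_subset == "protein_coding":
        if annotation is None:
            raise UsageError("protein_coding subset requires an annotation")
        coding = annotation.df.index[annotation.df["biotype"] == "protein_coding"]
        genes = genes.intersection(coding)
    elif gene_subset != "all":
        raise UsageError(f"unknown gene subset {gene_subset!r}")
    if len(expr.samples) < 3:
        raise UsageError("PCA needs at least 3 samples")
    x = np.log2(expr.fpkm.loc[genes].to_numpy().T + 1.0)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x != 0):
        raise UsageError("expression matrix is constant; no variance to decompose")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic signs: flip each PC so its largest |loading| is positive
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    cols = [f"PC{i}" for i in range(1, k + 1)]
    loadings = pd.DataFrame(vt.T, index=genes, columns=cols)
    scores = pd.DataFrame(u * s, index=expr.samples, columns=cols)
    expl = pd.Series(s**2 / (x.shape[0] - 1), index=cols, name="explained_variance")
    return PCAResult(loadings, scores, expl, gene_subset)


def separating_pcs(pca: PCAResult, sheet, n: int = 2) -> list[int]:
    """The ``n`` PCs whose scores best separate the tissue groups.

    Stands in for the by-eye biplot inspection that picks which PCs to
    rank on: PCs are ordered by the one-way ANOVA F statistic of their
    sample scores grouped by tissue.
    """
    from scipy import stats

    tissues = sheet.df.loc[pca.scores.index, "tissue"]
    f_stats = {}
    for col in pca.scores.columns:
        groups = [pca.scores.loc[tissues == t, col] for t in tissues.unique()]
        groups = [g for g in groups if len(g) > 1]
        if len(groups) < 2:
            continue
        f_stats[col] = stats.f_oneway(*groups).statistic
    best = sorted(f_stats, key=f_stats.get, reverse=True)[:n]
    return sorted(int(c[2:]) for c in best)


def rank_genes(
    pca: PCAResult,
    pcs: list[int] = (2, 3),
    top_fraction: float = DEFAULT_TOP_FRACTION,
    partition: StagePartition | None = None,
) -> GeneRanking:
    """Rank genes by mean |loading| across the chosen PCs; flag the top slice.

    The cutoff keeps the first ceil(top_fraction x n_genes) genes of the
    descending ranking; ties break by gene id so output is reproducible.
    A stage partition, when given, joins each gene's Venn membership.
    """
    pcs = list(pcs)
    if not pcs:
        raise UsageError("at least one PC index is required")
    cols = [f"PC{i}" for i in pcs]
    missing = [c for c in cols if c not in pca.loadings.columns]
    if missing:
        raise UsageError(f"requested PCs not computed: {missing}")
    metric = pca.loadings[cols].abs().mean(axis=1)
    table = pca.loadings[cols].copy()
    table["rank_metric"] = metric
    # deterministic tie-break: descending metric, ascending gene id
    idname = pca.loadings.index.name or "gene_id"
    table = (
        table.rename_axis(idname)
        .reset_index()
        .sort_values(["rank_metric", idname], ascending=[False, True], kind="stable")
        .set_index(idname)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    n_top = int(np.ceil(top_fraction * len(table)))
    table["top"] = table["rank"] <= n_top
    if partition is not None:
        table = table.join(partition.table[["membership", "stage"]], how="left")
    return GeneRanking(table=table, pcs=pcs, top_fraction=top_fraction)
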