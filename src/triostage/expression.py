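"""Fragment counts to FPKM and the expressed-gene filter.

FPKM here is computed from the count table itself: the per-sample "million
mapped fragments" denominator is that sample's column total, and the
per-gene kilobase denominator is the annotated exonic length. A gene is
"expressed" when its mean FPKM is at least 0.1 (inclusive) across the
samples of at least one tissue type; the union over N, D and T gives a
single expressed background shared by every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_io import GeneAnnotation, SampleSheet, TISSUES, FormatError

logger = logging.getLogger("triostage")

DEFAULT_FPKM_THRESHOLD = 0.1


@dataclass
class ExpressionMatrix:
    """Raw fragment counts and FPKM for the same genes x samples grid.

    ``expressed`` is a boolean per-gene flag, filled in by
    :func:`filter_expressed`; until then every gene is considered expressed.
    """

    counts: pd.DataFrame
    fpkm: pd.DataFrame
    expressed: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.expressed is None:
            self.expressed = pd.Series(True, index=self.counts.index)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def expressed_genes(self) -> pd.Index:
        return self.counts.index[self.expressed]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts.loc[genes], self.fpkm.loc[genes], self.expressed.loc[genes]
        )


def compute_fpkm(counts: pd.DataFrame, annotation: GeneAnnotation) -> ExpressionMatrix:
    """FPKM[g, s] = count[g, s] / (exonic_kb[g] * column_total[s] / 1e6).

    Raises on genes missing from the annotation and on all-zero samples
    (which would make the denominator zero).
    """
    missing = counts.index.difference(annotation.df.index)
    if len(missing):
        raise FormatError(f"genes missing from annotation: {missing.tolist()}")
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise FormatError(f"all-zero samples (no mapped fragments): {zero}")
    kb = annotation.lengths_kb().reindex(counts.index)
    fpkm = counts.div(kb, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(counts=counts, fpkm=fpkm)


def tissue_mean_fpkm(expr: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Mean FPKM per gene within each tissue type (columns N, D, T)."""
    out = {}
    for tissue in TISSUES:
        cols = [s for s in sheet.samples_of_tissue(tissue) if s in expr.samples]
        if not cols:
            logger.warning("tissue %s has no samples; skipped in filter", tissue)
            continue
        out[tissue] = expr.fpkm[cols].mean(axis=1)
    if not out:
        raise FormatError("no tissue has any samples")
    return pd.DataFrame(out)


def filter_expressed(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    threshold: float = DEFAULT_FPKM_THRESHOLD,
    mode: str = "any",
) -> pd.Index:
    """Flag genes expressed at mean FPKM >= threshold within a tissue type.

    ``mode='any'`` (default) keeps a gene expressed in at least one tissue —
    the single union background; ``mode='all'`` requires every tissue.
    Sets ``expr.expressed`` in place and returns the expressed gene index.
    """
    means = tissue_mean_fpkm(expr, sheet)
    hits = means >= threshold  # inclusive boundary
    flags = hits.any(axis=1) if mode == "any" else hits.all(axis=1)
    expr.expressed = flags
    logger.info(
        "expressed filter (mean FPKM >= %g, mode=%s): %d / %d genes",
        threshold, mode, int(flags.sum()), len(flags),
    )
    return expr.expressed_genes
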