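"""Immune-infiltration read-outs from bulk expression.

Three complementary views of the immune compartment per sample:

* an ESTIMATE-style **immune score** — a single-sample rank-enrichment
  (ssGSEA-type) statistic over an immune signature, correlated per tissue
  against the pathologist's visual immune-cell percentage;
* the **immunome** — per immune-cell-type marker sets (Bindea-style)
  tested for over-representation among up-regulated genes of a contrast,
  separating e.g. cytotoxic-effector infiltration at the dysplasia stage
  from inflammatory infiltration at the tumour stage;
* the **CYT cytolytic score** — log2 of the mean FPKM of the two
  cytolytic effectors granzyme A (GZMA) and perforin (PRF1), with
  per-patient stage-to-stage deltas that the matched design permits.

On CYT: the operational definition used here by default,
``log2((FPKM_GZMA + FPKM_PRF1) / 2)``, is the log2 of the *arithmetic*
mean. The score is often described as a geometric mean; the true
geometric-mean variant ``(log2 GZMA + log2 PRF1) / 2`` is available via
``mode='true_geometric'`` (with a 0.01 FPKM floor to keep it finite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneAnnotation, GeneSet, GeneSetCollection, SampleSheet, TISSUES, UsageError
from .differential import ContrastResult
from .expression import ExpressionMatrix
from .staging import hypergeom_enrichment_p

logger = logging.getLogger("triostage")

MIN_SIGNATURE_GENES = 10
SSGSEA_ALPHA = 0.25
CYT_FPKM_FLOOR = 0.01


# ---------------------------------------------------------------------------
# single-sample rank-enrichment immune score
# ---------------------------------------------------------------------------

def _ssgsea_score(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Single-sample enrichment score of one signature in one sample.

    Genes are ordered by decreasing expression (ties broken by position,
    which callers make deterministic); the score is the normalised sum of
    the gap between the rank-weighted ECDF of signature genes and the
    plain ECDF of the rest, weight = rank^alpha.
    """
    n = len(values)
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # top gene gets rank n
    sig = in_set[order]
    w = ranks[order] ** alpha
    w_sig = np.where(sig, w, 0.0)
    denom_sig = w_sig.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w_sig) / denom_sig
    p_out = np.cumsum(np.where(sig, 0.0, 1.0)) / n_out
    raw = float(np.sum(p_in - p_out) / n)
    # centre on the random-signature expectation (rank^alpha weighting alone
    # pulls the weighted ECDF above the uniform one), so null scores sit at 0
    baseline = float(np.sum(np.cumsum(w) / w.sum() - np.arange(1, n + 1) / n) / n)
    return raw - baseline


@dataclass
class ImmuneScoreTable:
    scores: pd.Series                      # per sample
    correlations: pd.DataFrame | None      # per tissue: r, p, n
    signature_size: int


def immune_score(
    expr: ExpressionMatrix,
    signature: GeneSet,
    sheet: SampleSheet | None = None,
    alpha: float = SSGSEA_ALPHA,
) -> ImmuneScoreTable:
    """ESTIMATE-style immune score per sample, optionally vs pathologist %.

    Scores are computed over the expressed genes only. When a sample sheet
    with ``immune_pct`` is given, Pearson r and its two-sided t-test p are
    reported per tissue; samples without a percentage are omitted from the
    correlation but still scored.
    """
    genes = expr.expressed_genes
    in_set = np.asarray(genes.isin(pd.Index(signature.members)))
    n_matched = int(in_set.sum())
    if n_matched < MIN_SIGNATURE_GENES:
        raise UsageError(
            f"signature {signature.name!r}: only {n_matched} genes matched "
            f"(need >= {MIN_SIGNATURE_GENES})"
        )
    # sort genes by id once so that expression ties resolve deterministically
    order = np.argsort(genes)
    fpkm = expr.fpkm.loc[genes].to_numpy()[order]
    in_set = in_set[order]
    scores = pd.Series(
        [_ssgsea_score(fpkm[:, j], in_set, alpha) for j in range(fpkm.shape[1])],
        index=expr.samples,
        name="immune_score",
    )
    corr = None
    if sheet is not None and sheet.df["immune_pct"].notna().any():
        rows = {}
        for tissue in TISSUES:
            ids = [s for s in sheet.samples_of_tissue(tissue) if s in scores.index]
            pct = sheet.df.loc[ids, "immune_pct"]
            ids = [s for s in ids if pd.notna(pct[s])]
            if len(ids) < 3:
                continue
            r, p = stats.pearsonr(sheet.df.loc[ids, "immune_pct"], scores[ids])
            rows[tissue] = {"r": r, "p": p, "n": len(ids)}
        corr = pd.DataFrame(rows).T if rows else None
    return ImmuneScoreTable(scores=scores, correlations=corr, signature_size=n_matched)


# ---------------------------------------------------------------------------
# immunome: per-cell-type enrichment among up-regulated genes
# ---------------------------------------------------------------------------

@dataclass
class ImmunomeResult:
    """Per cell type: up-regulated members and their over-representation."""

    contrast: str
    table: pd.DataFrame  # index cell type; k, set_size, n_up, background, p, significant,
                         # mean_pct_change, members

    @property
    def significant_sets(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def _immunome_table(
    up_genes: pd.Index,
    universe: pd.Index,
    cell_sets: GeneSetCollection,
    log2fc: pd.Series,
    p_fisher: float,
) -> pd.DataFrame:
    rows = []
    for gs in cell_sets:
        members = universe.intersection(pd.Index(gs.members))
        if len(members) == 0:
            logger.warning("cell set %r has no expressed members; skipped", gs.name)
            continue
        hits = up_genes.intersection(members)
        p = hypergeom_enrichment_p(len(hits), len(members), len(up_genes), len(universe))
        pct = (
            float(((2.0 ** log2fc.reindex(hits) - 1.0) * 100.0).mean())
            if len(hits)
            else np.nan
        )
        rows.append(
            {
                "cell_type": gs.name,
                "k": len(hits),
                "set_size": len(members),
                "n_up": len(up_genes),
                "background": len(universe),
                "p": p,
                "significant": p <= p_fisher,
                "mean_pct_change": pct,
                "members": ",".join(sorted(hits)),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type") if rows else pd.DataFrame(
        columns=["k", "set_size", "n_up", "background", "p", "significant",
                 "mean_pct_change", "members"]
    )


def immunome_enrichment(
    result: ContrastResult,
    cell_sets: GeneSetCollection,
    p_up: float = 0.01,
    p_fisher: float = 0.05,
) -> ImmunomeResult:
    """Which immune cell types are over-represented among up-regulated genes.

    "Up-regulated" is log2FC > 0 at unadjusted p <= ``p_up`` (a deliberately
    permissive per-gene screen, distinct from the FDR used for the main DE
    calls); each cell-type set is then Fisher-tested against the total
    up-regulated count over the expressed background at ``p_fisher``.
    """
    tab = result.table
    up = tab.index[(tab["log2FC"] > 0) & (tab["p"] <= p_up)]
    table = _immunome_table(up, tab.index, cell_sets, tab["log2FC"], p_fisher)
    return ImmunomeResult(contrast=result.contrast, table=table)


def compare_external_de(
    de_table: pd.DataFrame,
    cell_sets: GeneSetCollection,
    annotation: GeneAnnotation | None = None,
    p_threshold: float = 0.05,
    contrast: str = "external",
) -> ImmunomeResult:
    """Apply the immunome machinery to an externally produced DE table.

    ``de_table`` needs columns ``gene``, ``log2FC`` and ``p_adj``; its gene
    universe is the background. Gene names are mapped through ``annotation``
    when given (case-insensitive symbol fallback); unmappable names are
    dropped with a warning. DE = p_adj <= threshold (either direction);
    ``mean_pct_change`` = mean over DE set members of (2^log2FC - 1) x 100.
    """
    required = {"gene", "log2FC", "p_adj"}
    missing = required - set(de_table.columns)
    if missing:
        raise UsageError(f"external DE table missing columns: {sorted(missing)}")
    tab = de_table.copy()
    if annotation is not None:
        mapping = annotation.resolve_names(tab["gene"])
        n_before = len(tab)
        tab = tab[tab["gene"].isin(mapping)]
        tab = tab.assign(gene=[mapping[g] for g in tab["gene"]])
        if len(tab) < n_before:
            logger.warning("dropped %d unmappable gene names", n_before - len(tab))
    tab = tab.drop_duplicates(subset="gene").set_index("gene")
    universe = tab.index
    de = universe[tab["p_adj"] <= p_threshold]
    table = _immunome_table(de, universe, cell_sets, tab["log2FC"], p_threshold)
    return ImmunomeResult(contrast=contrast, table=table)


# ---------------------------------------------------------------------------
# CYT cytolytic score
# ---------------------------------------------------------------------------

@dataclass
class CYTTable:
    scores: pd.Series         # per sample
    deltas: pd.DataFrame      # per patient: dCYT_NtoD, dCYT_NtoT (NaN when a sample is missing)
    summary: pd.DataFrame     # per delta: mean, sem, n
    mode: str


def cyt_score(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    annotation: GeneAnnotation | None = None,
    mode: str = "as_stated",
    genes: tuple[str, str] = ("GZMA", "PRF1"),
) -> CYTTable:
    """Cytolytic activity per sample and its change along disease stages.

    ``as_stated`` (default): CYT = log2((FPKM_GZMA + FPKM_PRF1) / 2).
    ``true_geometric``: CYT = (log2 FPKM_GZMA + log2 FPKM_PRF1) / 2, with a
    0.01 FPKM floor. Deltas are within-patient: D minus N and T minus N,
    only for patients holding both samples; the cohort summary is
    mean +- s.e.m. (s.d. / sqrt(n)).
    """
    if mode not in ("as_stated", "true_geometric"):
        raise UsageError(f"unknown CYT mode {mode!r}")
    ids = []
    for name in genes:
        if annotation is not None:
            resolved = annotation.resolve_names([name])
            if name not in resolved:
                raise UsageError(f"CYT gene {name!r} not found in annotation")
            gid = resolved[name]
        else:
            gid = name
        if gid not in expr.fpkm.index:
            raise UsageError(f"CYT gene {name!r} not present in the expression matrix")
        ids.append(gid)
    a = expr.fpkm.loc[ids[0]]
    b = expr.fpkm.loc[ids[1]]
    if mode == "as_stated":
        scores = np.log2((a + b) / 2.0)
    else:
        scores = (
            np.log2(np.maximum(a, CYT_FPKM_FLOOR)) + np.log2(np.maximum(b, CYT_FPKM_FLOOR))
        ) / 2.0
    scores = pd.Series(scores, index=expr.samples, name="CYT")

    wide = (
        sheet.df.reset_index()
        .pivot(index="patient_id", columns="tissue", values="sample_id")
        .reindex(columns=list(TISSUES))
    )
    def _delta(frm: str, to: str) -> pd.Series:
        have = wide[[frm, to]].dropna()
        return pd.Series(
            scores[have[to]].to_numpy() - scores[have[frm]].to_numpy(),
            index=have.index,
        )
    deltas = pd.DataFrame({"dCYT_NtoD": _delta("N", "D"), "dCYT_NtoT": _delta("N", "T")})
    summary_rows = {}
    for col in deltas:
        vals = deltas[col].dropna()
        n = len(vals)
        summary_rows[col] = {
            "mean": float(vals.mean()) if n else np.nan,
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "n": n,
        }
    return CYTTable(
        scores=scores, deltas=deltas, summary=pd.DataFrame(summary_rows).T, mode=mode
    )
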