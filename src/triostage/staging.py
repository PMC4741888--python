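"""Venn staging of DE genes across the three contrasts, plus enrichment.

A gene's (de_NvD, de_DvT, de_NvT) triple places it in one of eight
disjoint classes. The biological reading, under the progression model
N -> D -> T:

* early      — DE NvD but not DvT: altered during dysplasia formation;
* late       — DE DvT but not NvD: altered during malignant transformation;
* consistent — DE in all three contrasts;
* transient  — DE NvD and DvT but not NvT: dysregulated one way then the
  other (e.g. up in dysplasia, back down in tumour).

Gene-set enrichment is the one-sided hypergeometric upper tail (equivalent
to a one-sided Fisher exact test on the 2x2 table), always restricted to
the expressed background. The cis-window control asks whether genes
flanking a clustered gene family (within +-2 Mb by default) show the same
coordinated regulation — if they do, copy-number change rather than
regulation is the likelier cause.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core_io import GeneAnnotation, GeneSet, GeneSetCollection, UsageError
from .differential import ContrastResult

logger = logging.getLogger("triostage")

MEMBERSHIP_CLASSES = (
    "none", "NvD-only", "DvT-only", "NvT-only",
    "NvD&DvT", "NvD&NvT", "DvT&NvT", "all-three",
)

_MEMBERSHIP_BY_TRIPLE = {
    (False, False, False): "none",
    (True, False, False): "NvD-only",
    (False, True, False): "DvT-only",
    (False, False, True): "NvT-only",
    (True, True, False): "NvD&DvT",
    (True, False, True): "NvD&NvT",
    (False, True, True): "DvT&NvT",
    (True, True, True): "all-three",
}

_STAGE_BY_MEMBERSHIP = {
    "none": "none",
    "NvD-only": "early",
    "NvD&NvT": "early",
    "DvT-only": "late",
    "DvT&NvT": "late",
    "all-three": "consistent",
    "NvD&DvT": "transient",
    "NvT-only": "other",
}


@dataclass
class StagePartition:
    """Assignment of every expressed gene to a Venn class and stage label."""

    table: pd.DataFrame  # index gene_id; columns de_NvD, de_DvT, de_NvT, membership, stage

    @property
    def counts(self) -> pd.Series:
        return self.table["membership"].value_counts().reindex(
            MEMBERSHIP_CLASSES, fill_value=0
        )

    def genes_in(self, membership: str) -> pd.Index:
        return self.table.index[self.table["membership"] == membership]

    def stage_genes(self, stage: str) -> pd.Index:
        return self.table.index[self.table["stage"] == stage]


def venn_partition(results: dict[str, ContrastResult]) -> StagePartition:
    """Partition the expressed universe by DE flags of the three contrasts."""
    needed = {"NvD", "DvT", "NvT"}
    if set(results) != needed:
        raise UsageError(f"need exactly contrasts {sorted(needed)}, got {sorted(results)}")
    universes = [tuple(r.table.index) for r in results.values()]
    if len(set(universes)) > 1:
        raise UsageError("contrasts were run on different gene universes")
    idx = results["NvD"].table.index
    flags = pd.DataFrame(
        {f"de_{c}": results[c].table["de"].to_numpy() for c in ("NvD", "DvT", "NvT")},
        index=idx,
    )
    membership = [
        _MEMBERSHIP_BY_TRIPLE[triple]
        for triple in zip(flags["de_NvD"], flags["de_DvT"], flags["de_NvT"])
    ]
    table = flags.assign(
        membership=membership,
        stage=[_STAGE_BY_MEMBERSHIP[m] for m in membership],
    )
    part = StagePartition(table)
    logger.info("Venn partition counts: %s", part.counts.to_dict())
    return part


def transient_genes(
    partition: StagePartition, results: dict[str, ContrastResult]
) -> pd.DataFrame:
    """NvD & DvT (not NvT) genes with per-contrast fold-change signs.

    ``opposite`` flags genes dysregulated one way then reversed (the
    IL36G-like pattern: up in dysplasia, down again in tumour).
    """
    genes = partition.genes_in("NvD&DvT")
    lfc1 = results["NvD"].table.loc[genes, "log2FC"]
    lfc2 = results["DvT"].table.loc[genes, "log2FC"]
    out = pd.DataFrame(
        {
            "log2FC_NvD": lfc1,
            "log2FC_DvT": lfc2,
            "sign_NvD": np.sign(lfc1).astype(int),
            "sign_DvT": np.sign(lfc2).astype(int),
        },
        index=genes,
    )
    out["opposite"] = (out["sign_NvD"] * out["sign_DvT"]) < 0
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    k: int          # DE-list members of the set
    set_size: int   # set size within the background
    list_size: int  # DE-list size
    background: int
    p: float
    frac_up: float | None = None
    members: list[str] = field(default_factory=list)
    evaluable: bool = True
    p_adj: float | None = None


def hypergeom_enrichment_p(k: int, set_size: int, list_size: int, background: int) -> float:
    """One-sided over-representation p: P[X >= k], X ~ Hypergeom(N, K, n).

    Computed as one log-gamma evaluation at the modal tail term plus the
    exact pmf ratio recurrence, which keeps the relative error near machine
    precision even for very small p — tighter than summing independently
    log-gamma'd terms (and than generic distribution ``sf`` routines, whose
    tail error grows with |log p|). Equals the one-sided Fisher exact p.
    """
    K, n, N = set_size, list_size, background
    support_lo = max(0, n - (N - K))
    hi = min(K, n)
    if k > hi:
        return 0.0
    if k <= support_lo:
        return 1.0  # the tail covers the whole support
    lo = k
    mode = int((n + 1) * (K + 1) / (N + 2))
    i0 = min(max(lo, mode), hi)
    logp0 = (
        gammaln(K + 1) - gammaln(i0 + 1) - gammaln(K - i0 + 1)
        + gammaln(N - K + 1) - gammaln(n - i0 + 1) - gammaln(N - K - n + i0 + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    s = 1.0
    term = 1.0
    for i in range(i0, hi):  # upward from the modal term
        term *= (K - i) * (n - i) / ((i + 1.0) * (N - K - n + i + 1.0))
        s += term
        if term < 1e-17 * s:
            break
    term = 1.0
    for i in range(i0, lo, -1):  # downward to k; terms decay below the mode
        term *= i * (N - K - n + i) / ((K - i + 1.0) * (n - i + 1.0))
        s += term
        if term < 1e-17 * s:
            break
    return float(min(np.exp(logp0) * s, 1.0))


def set_enrichment(
    gene_list,
    gene_set: GeneSet,
    background,
    log2fc: pd.Series | None = None,
) -> EnrichmentResult:
    """Over-representation of one gene set in a gene list.

    The set is restricted to the background universe before testing; an
    empty restricted set is an error. ``log2fc`` (optional) supplies the
    direction summary (fraction of hit members with positive fold change).
    """
    bg = pd.Index(background)
    members = bg.intersection(pd.Index(gene_set.members))
    if len(members) == 0:
        raise UsageError(
            f"gene set {gene_set.name!r} has no members in the background"
        )
    lst = bg.intersection(pd.Index(gene_list))
    hits = lst.intersection(members)
    p = hypergeom_enrichment_p(len(hits), len(members), len(lst), len(bg))
    frac_up = None
    if log2fc is not None and len(hits):
        frac_up = float((log2fc.reindex(hits) > 0).mean())
    return EnrichmentResult(
        set_name=gene_set.name,
        k=len(hits),
        set_size=len(members),
        list_size=len(lst),
        background=len(bg),
        p=p,
        frac_up=frac_up,
        members=sorted(hits),
    )


def enrich_collection(
    gene_list,
    collection: GeneSetCollection,
    background,
    log2fc: pd.Series | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Run :func:`set_enrichment` over a collection; optional BH across sets.

    Sets with no member in the background are skipped with a warning.
    """
    rows = []
    for gs in collection:
        try:
            res = set_enrichment(gene_list, gs, background, log2fc=log2fc)
        except UsageError:
            logger.warning("set %r empty after background restriction; skipped", gs.name)
            continue
        rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["k", "set_size", "list_size", "background", "p", "p_adj", "frac_up"]
        )
    df = pd.DataFrame(
        {
            "k": [r.k for r in rows],
            "set_size": [r.set_size for r in rows],
            "list_size": [r.list_size for r in rows],
            "background": [r.background for r in rows],
            "p": [r.p for r in rows],
            "frac_up": [r.frac_up for r in rows],
            "members": [",".join(r.members) for r in rows],
        },
        index=[r.set_name for r in rows],
    )
    if adjust and len(df) > 1:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p"]
    return df


# ---------------------------------------------------------------------------
# cis-window (copy-number) control
# ---------------------------------------------------------------------------

@dataclass
class CisWindowResult:
    contrast: str
    chrom: str
    window_start: int
    window_end: int
    n_window_genes: int
    n_de: int
    n_de_up: int
    p_enrichment: float | None
    p_sign: float | None
    evaluable: bool


def cis_window_control(
    chrom: str,
    family_start: int,
    family_end: int,
    annotation: GeneAnnotation,
    results: dict[str, ContrastResult],
    family_genes,
    window: int = 2_000_000,
) -> dict[str, CisWindowResult]:
    """Test the +-`window` bp flanks of a gene-family locus, per contrast.

    Window = [family_start - window, family_end + window], inclusive at both
    ends; a gene overlapping it by >= 1 bp is in. Family members are
    excluded. Two read-outs per contrast: hypergeometric enrichment of DE
    genes among window genes, and a binomial sign test for coordinated
    up-regulation among the DE window genes. With no window genes the
    result is flagged not evaluable.
    """
    ann = annotation.df
    if chrom not in set(ann["chrom"]):
        raise UsageError(f"unknown chromosome {chrom!r}")
    lo = family_start - window
    hi = family_end + window
    on_chrom = ann[ann["chrom"] == chrom]
    overlap = (on_chrom["end"] >= lo) & (on_chrom["start"] <= hi)
    window_genes = on_chrom.index[overlap].difference(pd.Index(family_genes))
    out: dict[str, CisWindowResult] = {}
    for contrast, res in results.items():
        universe = res.table.index
        wg = window_genes.intersection(universe)
        if len(wg) == 0:
            out[contrast] = CisWindowResult(
                contrast, chrom, lo, hi, 0, 0, 0, None, None, evaluable=False
            )
            continue
        sub = res.table.loc[wg]
        de = sub[sub["de"]]
        n_de_total = int(res.table["de"].sum())
        p_enr = hypergeom_enrichment_p(len(de), len(wg), n_de_total, len(universe))
        if len(de):
            n_up = int((de["log2FC"] > 0).sum())
            p_sign = float(stats.binomtest(n_up, len(de), 0.5, alternative="greater").pvalue)
        else:
            n_up, p_sign = 0, 1.0
        out[contrast] = CisWindowResult(
            contrast, chrom, lo, hi, len(wg), len(de), n_up, p_enr, p_sign, True
        )
    return out
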