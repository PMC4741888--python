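"""Co-expression network: sampled-quantile thresholds, graph, subclusters.

All-pairs correlation of tens of thousands of genes is dominated by its
own extreme tails, so the significance thresholds are estimated from a
random sample of gene pairs: draw a fixed fraction of the C(G,2) unordered
pairs without replacement, correlate them, and take the empirical
quantiles that demarcate the top and bottom tail fraction. Edges whose
correlation is equal to or outside those thresholds are retained.
Positively correlated subclusters (connected components above a high
correlation floor) are the unit of 'guilt by association' annotation for
non-coding genes, including antisense genes paired with the sense gene
they overlap.

Correlations are Pearson (default) or Spearman on log2(FPKM+1) across all
samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneAnnotation, UsageError
from .expression import ExpressionMatrix
from .staging import StagePartition

logger = logging.getLogger("triostage")

DEFAULT_SAMPLE_FRACTION = 0.01
DEFAULT_TAIL_FRACTION = 0.0005 / 100  # "top and bottom 0.0005%"
DEFAULT_MIN_R = 0.95
_PAIR_CHUNK = 200_000
_BLOCK = 2_000


@dataclass
class ThresholdPair:
    lower: float
    upper: float
    sample_size: int
    sample_fraction: float
    tail_fraction: float


def planned_sample_size(n_genes: int, sample_fraction: float = DEFAULT_SAMPLE_FRACTION) -> int:
    """round(fraction x C(G, 2)) — the number of pair correlations sampled."""
    total = n_genes * (n_genes - 1) // 2
    return int(round(sample_fraction * total))


def _standardise(expr: ExpressionMatrix, method: str) -> tuple[np.ndarray, pd.Index]:
    """Rows standardised so that Z_i . Z_j / (S-1) is the correlation."""
    genes = expr.expressed_genes
    x = np.log2(expr.fpkm.loc[genes].to_numpy() + 1.0)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    elif method != "pearson":
        raise UsageError(f"unknown correlation method {method!r}")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    if constant.any():
        logger.warning(
            "%d constant genes: their correlations are treated as 0", int(constant.sum())
        )
        sd[constant] = np.inf  # zero rows -> correlation 0 with everything
    z = (x - mean) / sd / math.sqrt(x.shape[1] - 1)
    return z, genes


def _decode_pairs(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat indices in [0, C(n,2)) to (i, j) with i < j, row-major."""
    # idx = i*n - i*(i+1)/2 + (j - i - 1); invert the triangular part for i
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    first_of_row = i * n - i * (i + 1) // 2
    # guard against float rounding at row boundaries
    over = first_of_row > idx
    i[over] -= 1
    first_of_row = i * n - i * (i + 1) // 2
    under = idx - first_of_row >= (n - 1 - i)
    i[under] += 1
    first_of_row = i * n - i * (i + 1) // 2
    j = idx - first_of_row + i + 1
    return i, j


def _sample_pair_indices(total: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct uniform draws from [0, total) without materialising range."""
    if k >= total:
        return np.arange(total, dtype=np.int64)
    chosen: set[int] = set()
    out = np.empty(k, dtype=np.int64)
    filled = 0
    while filled < k:
        need = k - filled
        draw = rng.integers(0, total, size=int(need * 1.1) + 16, dtype=np.int64)
        for v in draw:
            v = int(v)
            if v not in chosen:
                chosen.add(v)
                out[filled] = v
                filled += 1
                if filled == k:
                    break
    return out


def correlation_thresholds(
    expr: ExpressionMatrix,
    sample_fraction: float = DEFAULT_SAMPLE_FRACTION,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    seed: int = 0,
    method: str = "pearson",
) -> ThresholdPair:
    """Estimate retention thresholds from a random sample of gene pairs.

    Draws ``round(sample_fraction x C(G,2))`` distinct unordered pairs,
    correlates them, and returns the nearest-rank empirical quantiles at
    ``tail_fraction`` and ``1 - tail_fraction``.
    """
    z, genes = _standardise(expr, method)
    n = len(genes)
    if n < 2:
        raise UsageError("need at least 2 expressed genes")
    total = n * (n - 1) // 2
    k = int(round(sample_fraction * total))
    if k < 1:
        logger.warning("sample size < 1; raised to 1")
        k = 1
    rng = np.random.default_rng(seed)
    flat = _sample_pair_indices(total, k, rng)
    corrs = np.empty(k)
    for lo in range(0, k, _PAIR_CHUNK):
        hi = min(lo + _PAIR_CHUNK, k)
        i, j = _decode_pairs(flat[lo:hi], n)
        corrs[lo:hi] = np.einsum("ks,ks->k", z[i], z[j])
    corrs.sort()
    # nearest-rank quantiles: smallest value with >= q*k values at or below it
    lo_idx = max(int(math.ceil(tail_fraction * k)), 1) - 1
    hi_idx = max(int(math.ceil((1.0 - tail_fraction) * k)), 1) - 1
    pair = ThresholdPair(
        lower=float(corrs[lo_idx]),
        upper=float(corrs[hi_idx]),
        sample_size=k,
        sample_fraction=sample_fraction,
        tail_fraction=tail_fraction,
    )
    logger.info(
        "thresholds from %d sampled pairs (of %d): [%.4f, %.4f]",
        k, total, pair.lower, pair.upper,
    )
    return pair


def build_network(
    expr: ExpressionMatrix,
    thresholds: ThresholdPair,
    partition: StagePartition | None = None,
    annotation: GeneAnnotation | None = None,
    method: str = "pearson",
    block_size: int = _BLOCK,
) -> nx.Graph:
    """All-pairs correlation graph keeping |extreme| edges (inclusive).

    An edge (i, j) is retained iff r >= upper or r <= lower. Correlation is
    computed blockwise so memory stays bounded for large gene sets. Nodes
    carry biotype and the Venn membership / stage labels used to colour
    Cytoscape plots.
    """
    z, genes = _standardise(expr, method)
    n = len(genes)
    g = nx.Graph()
    for idx, gene in enumerate(genes):
        attrs = {}
        if annotation is not None and gene in annotation.df.index:
            attrs["biotype"] = annotation.df.at[gene, "biotype"]
        if partition is not None and gene in partition.table.index:
            attrs["membership"] = partition.table.at[gene, "membership"]
            attrs["stage"] = partition.table.at[gene, "stage"]
        g.add_node(gene, **attrs)
    lower, upper = thresholds.lower, thresholds.upper
    for a0 in range(0, n, block_size):
        a1 = min(a0 + block_size, n)
        for b0 in range(a0, n, block_size):
            b1 = min(b0 + block_size, n)
            r = z[a0:a1] @ z[b0:b1].T
            keep = (r >= upper) | (r <= lower)
            if a0 == b0:
                keep = np.triu(keep, k=1)  # no self-loops or duplicates
            ii, jj = np.nonzero(keep)
            for i, j in zip(ii, jj):
                g.add_edge(genes[a0 + i], genes[b0 + j], r=float(r[i, j]))
    logger.info("network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


@dataclass
class Subcluster:
    genes: list[str]
    size: int
    de_classes: dict[str, int]
    biotypes: dict[str, int]


def extract_subclusters(
    graph: nx.Graph, min_r: float = DEFAULT_MIN_R, min_size: int = 2
) -> list[Subcluster]:
    """Connected components of the r > min_r positive-edge subgraph.

    Returned largest-first; each carries its DE-class and biotype
    composition for 'guilt by association' reading.
    """
    strong = nx.Graph()
    strong.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        if data.get("r", 0.0) > min_r:
            strong.add_edge(u, v)
    clusters = []
    for comp in nx.connected_components(strong):
        if len(comp) < min_size:
            continue
        members = sorted(comp)
        de_hist: dict[str, int] = {}
        bio_hist: dict[str, int] = {}
        for m in members:
            data = graph.nodes[m]
            mem = data.get("membership", "unknown")
            de_hist[mem] = de_hist.get(mem, 0) + 1
            bt = data.get("biotype", "unknown")
            bio_hist[bt] = bio_hist.get(bt, 0) + 1
        clusters.append(Subcluster(members, len(members), de_hist, bio_hist))
    clusters.sort(key=lambda c: (-c.size, c.genes))
    return clusters


def antisense_pairs(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    subclusters: list[Subcluster] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of each expressed antisense gene with its sense partner.

    Pairs whose partner is not expressed are excluded. ``co_member`` says
    whether the two genes share a positively correlated subcluster.
    """
    z, genes = _standardise(expr, method)
    pos = {g: i for i, g in enumerate(genes)}
    member_of: dict[str, int] = {}
    for ci, cl in enumerate(subclusters or []):
        for gene in cl.genes:
            member_of[gene] = ci
    rows = []
    ann = annotation.df
    linked = ann[ann["antisense_partner"].notna()]
    for gid, row in linked.iterrows():
        partner = row["antisense_partner"]
        if gid not in pos or partner not in pos:
            continue
        r = float(z[pos[gid]] @ z[pos[partner]])
        co = (
            gid in member_of
            and partner in member_of
            and member_of[gid] == member_of[partner]
        )
        rows.append(
            {"antisense_gene": gid, "sense_partner": partner, "r": r, "co_member": co}
        )
    return pd.DataFrame(rows, columns=["antisense_gene", "sense_partner", "r", "co_member"])
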