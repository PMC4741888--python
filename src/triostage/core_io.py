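"""Readers and writers for the tabular and graph formats the pipeline touches.

Conventions
-----------
* Counts: TSV, first column gene ids, header row of sample ids, integer cells.
* Annotation: TSV with 1-based inclusive coordinates (GTF convention);
  internal arithmetic that needs intervals converts at the boundary.
* Sample sheet: CSV with ``sample_id, patient_id, tissue, immune_pct,
  tumour_pct``; tissue is one of N (normal), D (dysplasia), T (tumour).
* Gene sets: standard GMT (name TAB description TAB member...).
* Graphs: GraphML (attributes embedded) or SIF plus a sidecar
  node-attribute TSV, the pair Cytoscape expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("triostage")

TISSUES = ("N", "D", "T")

#: the three pairwise contrasts, mapped to (earlier stage, later stage)
CONTRASTS: Mapping[str, tuple[str, str]] = {
    "NvD": ("N", "D"),
    "DvT": ("D", "T"),
    "NvT": ("N", "T"),
}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ValueError):
    """An invalid configuration value."""


class UsageError(ValueError):
    """An invalid argument combination at the API/CLI boundary."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample metadata: which patient and tissue each library comes from.

    ``df`` is indexed by sample id with columns ``patient_id``, ``tissue``
    and the pathologist's visual estimates ``immune_pct`` / ``tumour_pct``
    (percentages in [0, 100], NaN when not scored).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        bad = set(df["tissue"]) - set(TISSUES)
        if bad:
            raise FormatError(f"unknown tissue codes: {sorted(bad)}")
        per = df.groupby(["patient_id", "tissue"]).size()
        if (per > 1).any():
            clash = per[per > 1].index.tolist()
            raise FormatError(f"patient has >1 sample of a tissue: {clash}")
        for col in ("immune_pct", "tumour_pct"):
            if col in df and df[col].notna().any():
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise FormatError(f"{col} outside [0, 100]")

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
        required = {"sample_id", "patient_id", "tissue"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        for col in ("immune_pct", "tumour_pct"):
            if col not in df:
                df[col] = float("nan")
        return cls(df.set_index("sample_id"))

    def write_csv(self, path: str | Path) -> None:
        self.df.reset_index().to_csv(path, index=False)

    @property
    def samples(self) -> pd.Index:
        return self.df.index

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return self.df.index[self.df["tissue"] == tissue].tolist()

    def complete_trios(self) -> list[str]:
        """Patients with all three tissues sampled."""
        got = self.df.groupby("patient_id")["tissue"].agg(set)
        return sorted(got.index[got.apply(lambda s: set(TISSUES) <= s)])

    def pairs(self, contrast: str) -> pd.DataFrame:
        """Per-patient (earlier, later) sample-id pairs for a contrast.

        Patients missing either tissue are dropped with a warning.
        """
        if contrast not in CONTRASTS:
            raise UsageError(f"unknown contrast {contrast!r}")
        a, b = CONTRASTS[contrast]
        wide = (
            self.df.reset_index()
            .pivot(index="patient_id", columns="tissue", values="sample_id")
            .reindex(columns=list(TISSUES))
        )
        have = wide[[a, b]].dropna()
        dropped = sorted(set(wide.index) - set(have.index))
        if dropped:
            logger.warning(
                "contrast %s: dropping unpaired patients %s", contrast, dropped
            )
        return have.rename(columns={a: "first", b: "second"}).sort_index()


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

BIOTYPES = ("protein_coding", "antisense", "lincRNA", "other")

_ANN_COLS = [
    "gene_name", "biotype", "chrom", "start", "end",
    "strand", "exonic_length", "antisense_partner",
]


@dataclass
class GeneAnnotation:
    """Gene-level annotation indexed by gene id.

    Coordinates are stored 1-based inclusive as read; ``exonic_length`` is
    the summed exon length in bp used for FPKM. ``antisense_partner`` links
    an antisense gene to the sense gene it overlaps, when known.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids in annotation: {dups}")
        if (df["start"] > df["end"]).any():
            bad = df.index[df["start"] > df["end"]].tolist()
            raise FormatError(f"start > end for genes: {bad}")
        if (df["exonic_length"] <= 0).any():
            bad = df.index[df["exonic_length"] <= 0].tolist()
            raise FormatError(f"non-positive exonic_length for genes: {bad}")
        span = df["end"] - df["start"] + 1
        if (df["exonic_length"] > span).any():
            bad = df.index[df["exonic_length"] > span].tolist()
            raise FormatError(f"exonic_length exceeds gene span: {bad}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        missing = ({"gene_id"} | set(_ANN_COLS) - {"antisense_partner"}) - set(df.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if "antisense_partner" not in df:
            df["antisense_partner"] = pd.NA
        return cls(df.set_index("gene_id")[_ANN_COLS])

    def write_tsv(self, path: str | Path) -> None:
        self.df.reset_index().rename(columns={"index": "gene_id"}).to_csv(
            path, sep="\t", index=False
        )

    def lengths_kb(self) -> pd.Series:
        return self.df["exonic_length"] / 1e3

    def resolve_names(self, names: Iterable[str]) -> dict[str, str]:
        """Map gene symbols to gene ids, case-insensitively.

        Ids are matched first; unmatched names fall back to ``gene_name``.
        Ambiguous symbols are skipped with a warning.
        """
        by_name: dict[str, list[str]] = {}
        for gid, nm in self.df["gene_name"].items():
            by_name.setdefault(str(nm).casefold(), []).append(gid)
        out: dict[str, str] = {}
        for raw in names:
            if raw in self.df.index:
                out[raw] = raw
                continue
            hits = by_name.get(raw.casefold(), [])
            if len(hits) == 1:
                out[raw] = hits[0]
            elif len(hits) > 1:
                logger.warning("ambiguous gene symbol %r -> %s; skipped", raw, hits)
        return out


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets with GMT semantics."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gene_set: GeneSet) -> None:
        if not gene_set.members:
            raise FormatError(f"empty gene set {gene_set.name!r} rejected")
        self.sets[gene_set.name] = gene_set


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of non-negative integer fragment counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in counts: {dups}")
    try:
        numeric = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in counts table: {exc}") from exc
    if numeric.isna().any().any() or (numeric < 0).any().any():
        raise FormatError("counts table contains negative or missing values")
    if ((numeric % 1) != 0).any().any():
        raise FormatError("counts table contains non-integer values")
    out = numeric.astype(int)
    out.index.name = "gene_id"
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = parts
            members = [m for m in members if m]
            coll.add(GeneSet(name, desc, members))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def write_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Write a co-expression graph as GraphML or SIF (+ node-attribute TSV).

    SIF emits ``geneA corr geneB`` triples; node attributes go to a sidecar
    ``<path>.nodes.tsv`` so Cytoscape can colour nodes by DE class and
    biotype.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for n, data in graph.nodes(data=True):
            g.add_node(n, **{k: ("" if v is None else v) for k, v in data.items()})
        for u, v, data in graph.edges(data=True):
            g.add_edge(u, v, **{k: d for k, d in data.items() if d is not None})
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\tcorr\t{v}\n")
        rows = []
        for n, data in sorted(graph.nodes(data=True)):
            rows.append({"gene_id": n, **data})
        pd.DataFrame(rows).to_csv(
            path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False
        )
    else:
        raise UsageError(f"unknown graph format {fmt!r}; use 'graphml' or 'sif'")


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


# ---------------------------------------------------------------------------
# config & logging
# ---------------------------------------------------------------------------

DEFAULT_SEED = 2015019  # fixed default; every randomised step logs it


def load_config(path: str | Path | None, overrides: Mapping | None = None) -> dict:
    """Load a flat YAML config and apply explicit overrides on top."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        cfg.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            cfg[key] = val
    logger.info("effective config: %s", cfg)
    return cfg


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
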