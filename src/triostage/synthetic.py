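"""Synthetic matched normal/dysplasia/tumour trios with planted truth.

The generator emulates the design of a matched-trio bulk RNA-seq study:
19 patients, three tissues each, negative-binomial fragment counts with a
shared multiplicative patient effect (what pairing removes), planted
disease-stage effects, immune-cell infiltration driving marker-gene
signal, and antisense genes tracking their sense partners.

Effect classes and their expected Venn placements after paired DE:

======================  ==========================  ==============
class                   tissue means (x baseline)   expected stage
======================  ==========================  ==============
early_up / early_down   N=1, D=2^(+-e), T=2^(+-e)   early
late_up / late_down     N=1, D=1,      T=2^(+-e)    late
consistent_up / _down   N=1, D=2^e,    T=2^(2e)     consistent
transient_up_down       N=1, D=2^e,    T=1          transient
======================  ==========================  ==============

Immune-marker genes carry **no** intrinsic stage effect; their mean scales
linearly with the sample's infiltration fraction for that cell type, so
any DE signal they show is infiltration-driven — exactly the confounder
the immunome analysis is designed to read out. The early_up genes form a
clustered family (HOX-like) on a dedicated chromosome, with null
neighbour genes placed inside the +-2 Mb flanks so the cis-window control
has genuine material to test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ConfigError,
    DEFAULT_SEED,
    GeneAnnotation,
    GeneSet,
    GeneSetCollection,
    SampleSheet,
    TISSUES,
)

logger = logging.getLogger("triostage")

EFFECT_CLASSES = (
    "null", "early_up", "early_down", "late_up", "late_down",
    "consistent_up", "consistent_down", "transient_up_down",
    "immune_marker", "antisense_pair",
)

#: per-tissue mean infiltration fraction per simulated cell type; the
#: cytotoxic wave peaks at dysplasia, the inflammatory cells at tumour
DEFAULT_INFILTRATION: dict[str, dict[str, float]] = {
    "cytotoxic": {"N": 0.03, "D": 0.25, "T": 0.08},
    "t_cells": {"N": 0.03, "D": 0.15, "T": 0.08},
    "b_cells": {"N": 0.02, "D": 0.10, "T": 0.05},
    "macrophage": {"N": 0.03, "D": 0.05, "T": 0.25},
    "neutrophil": {"N": 0.02, "D": 0.03, "T": 0.15},
}

DEFAULT_EFFECT_FRACTIONS: dict[str, float] = {
    "early_up": 0.020,
    "early_down": 0.010,
    "late_up": 0.010,
    "late_down": 0.020,
    "consistent_up": 0.010,
    "consistent_down": 0.010,
    "transient_up_down": 0.004,
}


@dataclass
class SimulationConfig:
    """Knobs of the trio simulator; defaults mirror the emulated study."""

    n_patients: int = 19
    n_genes: int = 5000
    effect_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_FRACTIONS)
    )
    effect_size: float = 2.0                 # |log2FC| of planted effects
    dispersion_range: tuple[float, float] = (0.05, 0.2)
    patient_sd: float = 0.5                  # s.d. of the shared log-normal patient effect
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    infiltration: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INFILTRATION.items()}
    )
    infiltration_jitter_sd: float = 0.04     # per patient/tissue/cell-type, truncated >= 0
    markers_per_cell_type: int = 15
    marker_base: float = 0.1                 # marker mean multiplier at zero infiltration
    marker_response: float = 5.0             # slope of multiplier vs infiltration fraction
    n_antisense: int = 15
    antisense_corr: float = 0.98             # target log-scale correlation with partner
    antisense_scale: float = 1.0             # antisense mean as fraction of partner count
    immune_pct_noise_sd: float = 5.0         # pathologist-estimate noise, percentage points
    noncoding_effect_fraction: float = 0.2   # slice of late/consistent effects typed lincRNA
    frac_unexpressed: float = 0.02           # genes below the FPKM filter by construction
    n_cis_neighbours: int = 40               # null genes inside the cluster's +-2 Mb flanks
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        bad = set(self.effect_fractions) - set(DEFAULT_EFFECT_FRACTIONS)
        if bad:
            raise ConfigError(f"unknown effect classes: {sorted(bad)}")
        if any(f < 0 for f in self.effect_fractions.values()):
            raise ConfigError("effect fractions must be non-negative")
        if sum(self.effect_fractions.values()) > 1:
            raise ConfigError("effect fractions sum to > 1")
        for ct, per_tissue in self.infiltration.items():
            for t, f in per_tissue.items():
                if not 0 <= f <= 1:
                    raise ConfigError(f"infiltration[{ct}][{t}]={f} outside [0, 1]")
        for t in TISSUES:
            tot = sum(per.get(t, 0.0) for per in self.infiltration.values())
            if tot > 1:
                raise ConfigError(f"total infiltration in tissue {t} exceeds 1")


@dataclass
class TruthTable:
    """Planted per-gene ground truth for parameter-recovery testing.

    ``df`` is indexed by gene id: ``effect_class``, planted log2 effects
    ``lfc_NvD`` (D over N) and ``lfc_DvT`` (T over D), NB ``dispersion``,
    ``cell_type`` for immune markers, ``antisense_partner`` for antisense
    genes, and ``in_cluster`` for the HOX-like family.
    """

    df: pd.DataFrame
    infiltration: pd.DataFrame  # (patient, tissue) x cell type true fractions

    def genes_of_class(self, effect_class: str) -> pd.Index:
        return self.df.index[self.df["effect_class"] == effect_class]

    def markers_of(self, cell_type: str) -> pd.Index:
        sel = (self.df["effect_class"] == "immune_marker") & (
            self.df["cell_type"] == cell_type
        )
        return self.df.index[sel]

    @property
    def family_genes(self) -> pd.Index:
        return self.df.index[self.df["in_cluster"]]

    def write_tsv(self, path) -> None:
        self.df.reset_index().to_csv(path, sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean m, dispersion phi) with variance m + phi m^2; phi=0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        m, f = mean[~pois], phi[~pois]
        n = 1.0 / f
        p = 1.0 / (1.0 + f * m)
        out[~pois] = rng.negative_binomial(n, p)
    return out


def simulate_trios(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, SampleSheet, GeneAnnotation, TruthTable]:
    """Generate one synthetic cohort: counts, sample sheet, annotation, truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_pat, n_genes = cfg.n_patients, cfg.n_genes
    cell_types = list(cfg.infiltration)

    # ---- gene roster ------------------------------------------------------
    n_per_class = {k: int(round(f * n_genes)) for k, f in cfg.effect_fractions.items()}
    n_markers = cfg.markers_per_cell_type * len(cell_types)
    n_antisense = cfg.n_antisense if n_per_class.get("early_up", 0) > 0 else 0
    n_antisense = min(n_antisense, n_per_class.get("early_up", 0))
    n_unexpr = int(round(cfg.frac_unexpressed * n_genes))
    n_special = sum(n_per_class.values()) + n_markers + n_antisense + n_unexpr
    if n_special + cfg.n_cis_neighbours > n_genes:
        raise ConfigError("n_genes too small for the requested planted classes")

    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    classes = np.array(["null"] * n_genes, dtype=object)
    cell_of = np.array([None] * n_genes, dtype=object)
    partner_of = np.array([None] * n_genes, dtype=object)
    names = list(gene_ids)

    cursor = 0
    spans: dict[str, slice] = {}
    for cls in ("early_up", "early_down", "late_up", "late_down",
                "consistent_up", "consistent_down", "transient_up_down"):
        n_c = n_per_class.get(cls, 0)
        spans[cls] = slice(cursor, cursor + n_c)
        classes[spans[cls]] = cls
        cursor += n_c
    spans["cis_null"] = slice(cursor, cursor + cfg.n_cis_neighbours)
    cursor += cfg.n_cis_neighbours  # null genes placed next to the cluster
    marker_ix: dict[str, slice] = {}
    for ct in cell_types:
        marker_ix[ct] = slice(cursor, cursor + cfg.markers_per_cell_type)
        classes[marker_ix[ct]] = "immune_marker"
        cell_of[marker_ix[ct]] = ct
        for j, gi in enumerate(range(cursor, cursor + cfg.markers_per_cell_type)):
            names[gi] = f"{ct.upper()}_M{j + 1:02d}"
        cursor += cfg.markers_per_cell_type
    if "cytotoxic" in marker_ix and cfg.markers_per_cell_type >= 2:
        # the two cytolytic effectors the CYT score reads
        names[marker_ix["cytotoxic"].start] = "GZMA"
        names[marker_ix["cytotoxic"].start + 1] = "PRF1"
    for j, gi in enumerate(range(*spans["early_up"].indices(n_genes))):
        names[gi] = f"HOXL{j + 1:02d}"
    spans["antisense"] = slice(cursor, cursor + n_antisense)
    classes[spans["antisense"]] = "antisense_pair"
    family_idx = np.arange(spans["early_up"].start, spans["early_up"].stop)
    for j, gi in enumerate(range(cursor, cursor + n_antisense)):
        p = family_idx[j]
        partner_of[gi] = gene_ids[p]
        names[gi] = f"{names[p]}-AS"
    cursor += n_antisense
    spans["unexpressed"] = slice(cursor, cursor + n_unexpr)
    cursor += n_unexpr

    # ---- planted effects --------------------------------------------------
    e = cfg.effect_size
    lfc1 = np.zeros(n_genes)  # D over N
    lfc2 = np.zeros(n_genes)  # T over D
    lfc1[spans["early_up"]] = e
    lfc1[spans["early_down"]] = -e
    lfc2[spans["late_up"]] = e
    lfc2[spans["late_down"]] = -e
    lfc1[spans["consistent_up"]] = e
    lfc2[spans["consistent_up"]] = e
    lfc1[spans["consistent_down"]] = -e
    lfc2[spans["consistent_down"]] = -e
    lfc1[spans["transient_up_down"]] = e
    lfc2[spans["transient_up_down"]] = -e

    lo, hi = cfg.dispersion_range
    phi = rng.uniform(lo, hi, size=n_genes)

    # ---- annotation -------------------------------------------------------
    exonic = rng.integers(500, 5001, size=n_genes)
    span_len = (exonic * rng.uniform(1.0, 3.0, size=n_genes)).astype(int)
    chrom = np.array(["chr1"] * n_genes, dtype=object)
    start = np.zeros(n_genes, dtype=int)
    strand = np.array(["+"] * n_genes, dtype=object)
    biotype = np.array(["protein_coding"] * n_genes, dtype=object)
    # a slice of the later-stage effects is non-coding, so coding-only and
    # all-gene PCA genuinely differ in how well they separate the tissues
    for cls in ("late_up", "late_down", "consistent_up", "consistent_down"):
        ixs = np.arange(*spans[cls].indices(n_genes))
        n_nc = int(round(cfg.noncoding_effect_fraction * len(ixs)))
        biotype[ixs[:n_nc]] = "lincRNA"

    # HOX-like family packed at the centre of its own chromosome, null
    # neighbours strewn through the +-2 Mb flanks, everything else on chr1
    fam = np.arange(*spans["early_up"].indices(n_genes))
    pos = 3_000_000
    for gi in fam:
        chrom[gi] = "chrC1"
        start[gi] = pos
        pos += span_len[gi] + 2_000
    fam_start, fam_end = (3_000_000, pos) if len(fam) else (3_000_000, 3_000_000)
    cis = np.arange(*spans["cis_null"].indices(n_genes))
    if len(cis):
        offsets = np.linspace(-1_900_000, 1_900_000 + (fam_end - fam_start), len(cis))
        for gi, off in zip(cis, offsets.astype(int)):
            chrom[gi] = "chrC1"
            start[gi] = max(fam_start + off, 1)
    bg = np.setdiff1d(np.arange(n_genes), np.concatenate([fam, cis]))
    start[bg] = 1 + np.arange(len(bg)) * 60_000
    for gi in range(*spans["antisense"].indices(n_genes)):
        p = gene_ids.index(partner_of[gi])
        chrom[gi] = chrom[p]
        start[gi] = start[p]
        span_len[gi] = span_len[p]
        exonic[gi] = min(exonic[gi], span_len[p])
        strand[gi] = "-"
        biotype[gi] = "antisense"
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_name": names,
                "biotype": biotype,
                "chrom": chrom,
                "start": start,
                "end": start + span_len - 1,
                "strand": strand,
                "exonic_length": exonic,
                "antisense_partner": partner_of,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )

    # ---- infiltration fractions ------------------------------------------
    pat_ids = [f"P{i:02d}" for i in range(1, n_pat + 1)]
    idx = pd.MultiIndex.from_product(
        [pat_ids, list(TISSUES)], names=["patient_id", "tissue"]
    )
    infiltration = pd.DataFrame(0.0, index=idx, columns=cell_types)
    for pat in pat_ids:
        for t in TISSUES:
            fr = {}
            for ct in cell_types:
                base = cfg.infiltration[ct].get(t, 0.0)
                fr[ct] = float(
                    np.clip(base + rng.normal(0.0, cfg.infiltration_jitter_sd), 0.0, 1.0)
                )
            tot = sum(fr.values())
            if tot > 1.0:
                fr = {ct: v / tot for ct, v in fr.items()}
            for ct, v in fr.items():
                infiltration.loc[(pat, t), ct] = v

    # ---- means and counts -------------------------------------------------
    baseline = np.exp(rng.normal(np.log(150.0), 1.2, size=n_genes))
    baseline[spans["early_up"]] = np.exp(rng.normal(np.log(300.0), 0.6, size=len(fam)))
    baseline[spans["unexpressed"]] = 0.02
    # gene-specific patient effects, shared across a patient's three samples:
    # the within-patient correlation the paired design exists to exploit
    patient_eff = np.exp(rng.normal(0.0, cfg.patient_sd, size=(n_genes, n_pat)))
    lib_lo, lib_hi = cfg.library_size_range

    tissue_mult = {
        "N": np.ones(n_genes),
        "D": 2.0 ** lfc1,
        "T": 2.0 ** (lfc1 + lfc2),
    }
    marker_mask = classes == "immune_marker"

    sample_ids, col_meta = [], []
    counts_cols = {}
    antis = np.arange(*spans["antisense"].indices(n_genes))
    for pi, pat in enumerate(pat_ids):
        for t in TISSUES:
            sid = f"{pat}_{t}"
            lib = rng.uniform(lib_lo, lib_hi)
            mean = baseline * patient_eff[:, pi] * tissue_mult[t] * (lib / 1e6)
            if marker_mask.any():
                fr = infiltration.loc[(pat, t)]
                mult = np.ones(n_genes)
                for ct in cell_types:
                    ix = marker_ix[ct]
                    mult[ix] = cfg.marker_base + cfg.marker_response * fr[ct]
                mean = np.where(
                    marker_mask,
                    baseline * patient_eff[:, pi] * mult * (lib / 1e6),
                    mean,
                )
            y = _nb_draw(rng, mean, phi)
            counts_cols[sid] = y
            sample_ids.append(sid)
            col_meta.append((pat, t))

    counts = pd.DataFrame(counts_cols, index=pd.Index(gene_ids, name="gene_id"))

    # antisense genes rewritten as noisy scalings of their partner's counts
    if len(antis):
        y_all = counts.to_numpy().astype(float)
        # noise budget set on the library-normalised scale the analysis
        # correlates on, so the target correlation survives normalisation
        tot = y_all.sum(axis=0)
        rel_tot = tot / tot.mean()
        for gi in antis:
            p = gene_ids.index(partner_of[gi])
            v = np.log((y_all[p] + 1.0) / rel_tot)
            rho = cfg.antisense_corr
            if rho <= 0:
                continue  # left as the independent NB draw above
            var_v = float(np.var(v))
            mean_a = cfg.antisense_scale * (y_all[p] + 1.0)
            pois_var = float(np.mean(1.0 / np.maximum(mean_a, 1e-6)))
            sigma2 = max(var_v * (1.0 / rho**2 - 1.0) - pois_var, 0.0)
            eps = rng.normal(0.0, np.sqrt(sigma2), size=y_all.shape[1])
            counts.iloc[gi] = rng.poisson(mean_a * np.exp(eps))

    # ---- sample sheet -----------------------------------------------------
    total_frac = infiltration.sum(axis=1)
    rows = []
    for sid, (pat, t) in zip(sample_ids, col_meta):
        pct = 100.0 * total_frac.loc[(pat, t)]
        pct = float(np.clip(pct + rng.normal(0.0, cfg.immune_pct_noise_sd), 0.0, 100.0))
        tumour_pct = {"N": 0.0, "D": 30.0, "T": 70.0}[t]
        rows.append(
            {
                "sample_id": sid,
                "patient_id": pat,
                "tissue": t,
                "immune_pct": pct,
                "tumour_pct": tumour_pct,
            }
        )
    sheet = SampleSheet(pd.DataFrame(rows).set_index("sample_id"))

    truth = TruthTable(
        df=pd.DataFrame(
            {
                "effect_class": classes,
                "lfc_NvD": lfc1,
                "lfc_DvT": lfc2,
                "dispersion": phi,
                "cell_type": cell_of,
                "antisense_partner": partner_of,
                "in_cluster": [i in set(fam) for i in range(n_genes)],
                "gene_name": names,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        infiltration=infiltration,
    )
    logger.info(
        "simulated %d patients x 3 tissues, %d genes (%d planted, %d markers)",
        n_pat, n_genes, sum(n_per_class.values()), n_markers,
    )
    return counts, sheet, annotation, truth


def default_gene_sets(truth: TruthTable) -> GeneSetCollection:
    """GMT-style sets from the planted truth: one per cell type, one family.

    Mirrors the role of published immune-cell signatures and of the HOX
    family: one set of marker gene ids per simulated cell type, a combined
    immune signature, and the clustered early-up family.
    """
    coll = GeneSetCollection()
    markers = truth.df[truth.df["effect_class"] == "immune_marker"]
    for ct in dict.fromkeys(markers["cell_type"]):
        ids = markers.index[markers["cell_type"] == ct].tolist()
        coll.add(GeneSet(str(ct).upper(), f"simulated {ct} markers", ids))
    if len(markers):
        coll.add(
            GeneSet("IMMUNE_SIGNATURE", "all simulated immune markers",
                    markers.index.tolist())
        )
    fam = truth.family_genes
    if len(fam):
        coll.add(GeneSet("HOX_LIKE_FAMILY", "clustered early-up family", fam.tolist()))
    return coll
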