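import numpy as np
import pandas as pd
import pytest

import triostage as ts


@pytest.fixture(scope="session")
def cohort():
    """One default-conditions synthetic cohort shared across tests."""
    cfg = ts.SimulationConfig(seed=42, n_genes=2500)
    counts, sheet, ann, truth = ts.simulate_trios(cfg)
    return counts, sheet, ann, truth


@pytest.fixture(scope="session")
def expr(cohort):
    counts, sheet, ann, _ = cohort
    e = ts.compute_fpkm(counts, ann)
    ts.filter_expressed(e, sheet)
    return e


@pytest.fixture(scope="session")
def de_results(expr, cohort):
    _, sheet, _, _ = cohort
    return {c: ts.paired_de(expr, sheet, c) for c in ("NvD", "DvT", "NvT")}


@pytest.fixture(scope="session")
def gene_sets(cohort):
    return ts.default_gene_sets(cohort[3])


def make_expression(fpkm: pd.DataFrame, counts: pd.DataFrame | None = None):
    """Build an ExpressionMatrix directly from an FPKM table (for unit tests)."""
    if counts is None:
        counts = (fpkm * 10).round().astype(int)
    return ts.ExpressionMatrix(counts=counts, fpkm=fpkm)


def fake_contrast(contrast: str, de_flags: pd.Series, log2fc: pd.Series | None = None):
    """A ContrastResult with prescribed DE flags (for partition-level tests)."""
    idx = de_flags.index
    if log2fc is None:
        log2fc = pd.Series(0.0, index=idx)
    p = pd.Series(np.where(de_flags, 1e-6, 0.5), index=idx)
    table = pd.DataFrame(
        {"log2FC": log2fc, "p": p, "p_adj": p, "de": de_flags.astype(bool),
         "de_secondary": de_flags.astype(bool)}
    )
    return ts.ContrastResult(contrast=contrast, table=table, fdr=0.01, n_pairs=19)
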