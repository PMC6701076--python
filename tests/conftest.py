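import numpy as np
import pandas as pd
import pytest

from crcyt.io import ExpressionMatrix
from crcyt.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded synthetic cohort small enough for fast unit tests."""
    return simulate_cohort(SimulationConfig(n_tumor=60, n_normal=6, n_genes=100, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the reference study conditions (200 tumors)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def toy_expression():
    """3 genes x 2 tumor samples with easy hand-checkable counts."""
    counts = pd.DataFrame(
        {"S1": [10, 20, 30], "S2": [5, 0, 15]},
        index=pd.Index(["GZMA", "PRF1", "OTHER"], name="gene"),
    )
    lengths = pd.Series([1000, 2000, 3000], index=counts.index)
    meta = pd.DataFrame(
        {"tissue": ["tumor", "tumor"], "dataset": ["COAD", "COAD"]},
        index=pd.Index(["S1", "S2"], name="sample_id"),
    )
    return ExpressionMatrix(counts=counts, lengths=lengths, sample_meta=meta)


def make_maf(rows):
    """Build a canonical mutation table from (sample, gene, classification,
    ref, alt, t_ref, t_alt) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "variant_classification", "ref_allele", "alt_allele",
                 "t_ref_count", "t_alt_count"],
    )
    df["t_ref_count"] = pd.array(df["t_ref_count"], dtype="Int64")
    df["t_alt_count"] = pd.array(df["t_alt_count"], dtype="Int64")
    df["chromosome"] = "1"
    df["position"] = pd.array(np.arange(1, len(df) + 1), dtype="Int64")
    df["known_classification"] = True
    return df
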