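"""Low-expression filtering, two-group differential expression, and
immune-checkpoint association with the cytolytic index and MSI status.

Differential expression is a deliberately simple two-group procedure:
Welch's t-test per gene on log2 counts normalized by median-of-ratios
size factors (0.5-count stabilizer), BH-adjusted, with genes called
differentially expressed at q below the configured FDR (default 0.1).
This trades the precision weights and empirical-Bayes moderation of
dedicated RNA-seq DE frameworks for a transparent test whose operating
characteristics are verified by planted-effect simulation.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cyt import TpmMatrix, bh_adjust
from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("crcyt")

__all__ = [
    "filter_low_expression",
    "differential_expression",
    "checkpoint_correlation",
    "checkpoint_by_msi",
]


def filter_low_expression(
    expr: ExpressionMatrix,
    cpm_threshold: float = 1.0,
    sample_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Drop genes not reaching ``cpm_threshold`` CPM in at least
    ``sample_fraction`` of the samples.

    CPM is counts scaled by library size times 1e6.  A gene at the
    boundary (expressed in exactly the required fraction) is kept.
    """
    libsize = expr.counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValidationError(f"sample with zero library size: {libsize.index[libsize <= 0][0]!r}")
    cpm = expr.counts.div(libsize, axis=1) * 1e6
    keep = (cpm >= cpm_threshold).mean(axis=1) >= sample_fraction
    removed = expr.genes[~keep]
    if len(removed):
        logger.info("filter_low_expression: removed %d genes (first: %s)", len(removed), list(removed[:5]))
    return ExpressionMatrix(
        counts=expr.counts.loc[keep],
        lengths=expr.lengths.loc[keep],
        sample_meta=expr.sample_meta,
    )


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes positive in every sample).

    Plain library-size scaling is biased when a few very highly expressed
    genes differ between groups: their share of the library deflates every
    other gene's relative abundance.  The median ratio to the per-gene
    geometric mean is robust to such composition shifts.  Falls back to
    library size when too few genes are positive everywhere.
    """
    ok = counts.gt(0).all(axis=1)
    if ok.sum() < 10:
        lib = counts.sum(axis=0).astype(float)
        return lib / np.exp(np.log(lib).mean())
    logc = np.log(counts[ok])
    sf = np.exp((logc.sub(logc.mean(axis=1), axis=0)).median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def _log2_norm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 of size-factor-normalized counts with a 0.5 stabilizer."""
    return np.log2(counts.div(_size_factors(counts), axis=1) + 0.5)


def differential_expression(
    expr: ExpressionMatrix,
    strata: pd.Series,
    de_fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-gene Welch t-test on normalized log2 counts, CYT-high vs CYT-low.

    Returns a DataFrame indexed by gene with ``log2fc`` (mean high minus
    mean low), ``p``, BH ``q`` and ``called`` (q < ``de_fdr``), sorted by q.
    Each stratum must contribute at least 3 samples.
    """
    strata = strata.reindex(expr.samples).dropna()
    high = strata.index[strata == "CYT-high"]
    low = strata.index[strata == "CYT-low"]
    if len(high) < 3 or len(low) < 3:
        raise ValidationError(f"need >=3 samples per stratum, got {len(high)} high / {len(low)} low")
    logcpm = _log2_norm(expr.counts)
    a = logcpm[high].to_numpy()
    b = logcpm[low].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    out = pd.DataFrame({"log2fc": log2fc, "p": p}, index=expr.genes)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["called"] = out["q"] < de_fdr
    return out.sort_values("q", kind="stable")


def checkpoint_correlation(
    tpm: TpmMatrix,
    cyt_index: pd.Series,
    checkpoint_genes: Sequence[str],
) -> pd.DataFrame:
    """Pearson correlation of each checkpoint gene's log2 TPM with the
    cytolytic index; zero-variance genes reported NaN."""
    missing = [g for g in checkpoint_genes if g not in tpm.genes]
    if missing:
        raise ValidationError(f"checkpoint genes absent from matrix: {missing}")
    shared = tpm.samples.intersection(cyt_index.index)
    y = cyt_index.loc[shared].to_numpy(dtype=float)
    logtpm = np.log2(tpm.tpm.loc[list(checkpoint_genes), shared])
    rows = {}
    for g in checkpoint_genes:
        x = logtpm.loc[g].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[g] = {"pearson_r": np.nan, "p": np.nan}
        else:
            r, p = stats.pearsonr(x, y)
            rows[g] = {"pearson_r": float(r), "p": float(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


def checkpoint_by_msi(
    tpm: TpmMatrix,
    msi_status: pd.Series,
    checkpoint_genes: Sequence[str],
) -> pd.DataFrame:
    """Mann-Whitney per checkpoint gene on log2 TPM, MSI vs MSS.

    Returns U, p, BH q over the panel, and ``direction`` — the group with
    the higher median expression.
    """
    missing = [g for g in checkpoint_genes if g not in tpm.genes]
    if missing:
        raise ValidationError(f"checkpoint genes absent from matrix: {missing}")
    shared = tpm.samples.intersection(msi_status.index)
    labels = msi_status.loc[shared]
    msi = shared[labels == "MSI"]
    mss = shared[labels == "MSS"]
    if len(msi) == 0 or len(mss) == 0:
        raise ValidationError("both MSI and MSS groups must be non-empty")
    logtpm = np.log2(tpm.tpm.loc[list(checkpoint_genes)])
    rows = {}
    for g in checkpoint_genes:
        a = logtpm.loc[g, msi].to_numpy(dtype=float)
        b = logtpm.loc[g, mss].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = 0.5 * len(a) * len(b), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        med_a, med_b = np.median(a), np.median(b)
        direction = "MSI" if med_a > med_b else ("MSS" if med_b > med_a else "none")
        rows[g] = {"U": u, "p": p, "direction": direction}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.index.name = "gene"
    return out[["U", "p", "q", "direction"]]
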