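"""Cytolytic-activity index: TPM normalization, CYT computation, quartile
stratification of the cohort, and nonparametric group comparisons.

The cytolytic index (CYT) is a transcriptional proxy for cytotoxic T / NK
activity: the geometric mean of the TPM of *GZMA* and *PRF1*.  Tumors in the
top quartile of CYT form the CYT-high stratum and those in the bottom
quartile the CYT-low stratum; the two strata drive every downstream
association in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "TpmMatrix",
    "compute_tpm",
    "compute_cyt",
    "stratify_cyt",
    "compare_groups",
    "compare_cyt_groups",
    "bh_adjust",
]


@dataclass
class TpmMatrix:
    """Transcripts-per-million expression with an optional additive offset.

    Before the offset each sample column sums to 1e6; after adding
    ``offset`` every entry is at least ``offset`` (zero counts included), so
    logarithms and geometric means are always defined.
    """

    tpm: pd.DataFrame
    offset: float

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns


def compute_tpm(expr: ExpressionMatrix, offset: float = 0.01) -> TpmMatrix:
    """Length-normalize raw counts to TPM, then add ``offset`` to every entry.

    Each gene's counts are divided by its maximum transcript length to give
    a coverage-depth estimate, and coverages are scaled so each sample sums
    to 1e6.  The offset (default 0.01) removes exact zeros ahead of log and
    geometric-mean computations.
    """
    coverage = expr.counts.div(expr.lengths, axis=0)
    totals = coverage.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValidationError(f"all-zero count column for sample {totals.index[zero][0]!r}")
    tpm = coverage.div(totals, axis=1) * 1e6 + offset
    return TpmMatrix(tpm=tpm, offset=offset)


def compute_cyt(tpm: TpmMatrix, cyt_genes: Sequence[str] = ("GZMA", "PRF1")) -> pd.DataFrame:
    """Per-sample cytolytic index from offset-adjusted TPM.

    Returns a DataFrame indexed by sample with ``cyt_raw`` (geometric mean
    of the configured genes' TPM) and ``cyt_index`` (log2(cyt_raw + 1)).
    """
    missing = [g for g in cyt_genes if g not in tpm.genes]
    if missing:
        raise ValidationError(f"cytolytic genes absent from expression matrix: {missing}")
    sub = tpm.tpm.loc[list(cyt_genes)]
    if (sub.to_numpy() <= 0).any():
        raise ValidationError("TPM entries must be positive (apply the offset first)")
    cyt_raw = np.exp(np.log(sub).mean(axis=0))
    return pd.DataFrame({"cyt_raw": cyt_raw, "cyt_index": np.log2(cyt_raw + 1.0)})


def stratify_cyt(cyt: pd.Series | pd.DataFrame, fraction: float = 0.25) -> pd.DataFrame:
    """Assign CYT-high / CYT-low / middle strata by ranked cytolytic index.

    Samples are ranked by ``cyt_raw`` descending, ties broken by sample ID
    (lexicographic, stable) for determinism.  The top ``floor(fraction*n)``
    samples become CYT-high, the bottom ``floor(fraction*n)`` CYT-low, the
    rest middle.
    """
    if isinstance(cyt, pd.DataFrame):
        values = cyt["cyt_raw"]
    else:
        values = cyt
    n = len(values)
    if n < int(np.ceil(2.0 / fraction)):
        raise ValidationError(f"need at least {int(np.ceil(2 / fraction))} samples to stratify, got {n}")
    k = int(np.floor(fraction * n))
    order = pd.DataFrame(
        {"cyt_raw": values.to_numpy(), "sid": values.index.astype(str)}, index=values.index
    ).sort_values(["cyt_raw", "sid"], ascending=[False, True], kind="stable")
    stratum = pd.Series("middle", index=values.index, name="stratum", dtype=object)
    stratum.loc[order.index[:k]] = "CYT-high"
    stratum.loc[order.index[n - k:]] = "CYT-low"
    out = pd.DataFrame({"cyt_raw": values, "stratum": stratum})
    if isinstance(cyt, pd.DataFrame) and "cyt_index" in cyt.columns:
        out.insert(1, "cyt_index", cyt["cyt_index"])
    return out


def compare_groups(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray) -> tuple[float, float]:
    """Nonparametric comparison of a statistic across groups.

    Two groups -> two-sided Mann-Whitney U; more -> Kruskal-Wallis.  Every
    group must have at least 2 observations.  Returns (statistic, p); when
    all observations are identical across two groups the tie-corrected
    asymptotic p is 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    parts = [values[groups == g] for g in labels]
    for g, part in zip(labels, parts):
        if len(part) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    if len(parts) == 2:
        if np.ptp(values) == 0:
            return 0.5 * len(parts[0]) * len(parts[1]), 1.0  # all tied
        res = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*parts)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def compare_cyt_groups(
    comparisons: Mapping[str, tuple[pd.Series | np.ndarray, pd.Series | np.ndarray]],
) -> pd.DataFrame:
    """Run a batch of group comparisons and FDR-adjust them together.

    ``comparisons`` maps a comparison name to (values, group labels).
    Returns a DataFrame with statistic, p and BH q per comparison.
    """
    rows = {}
    for name, (values, groups) in comparisons.items():
        stat, p = compare_groups(values, groups)
        rows[name] = {"statistic": stat, "p": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
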