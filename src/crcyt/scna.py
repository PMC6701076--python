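"""Somatic copy-number event burden from segment means.

A segment is an amplification event when its log2-ratio segment mean is at
or above the amplification cutoff (default 0.6) and a deletion event when
at or below the deletion cutoff (default -0.4); both boundaries inclusive.
No segment-length weighting is applied.  Alongside the event counts the
literal sums of qualifying segment means are reported.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = ["count_scna_events", "compare_scna_burden"]


def count_scna_events(
    segments: pd.DataFrame,
    amp_cutoff: float = 0.6,
    del_cutoff: float = -0.4,
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count copy-number events per sample from a SEG table.

    Returns a DataFrame indexed by sample with ``amp_count``, ``del_count``,
    ``total_count`` and, as auxiliary columns, ``amp_sum`` / ``del_sum`` —
    the sums of the qualifying segment means themselves.
    """
    if not (del_cutoff < 0 < amp_cutoff):
        raise ValidationError("cutoffs must satisfy del_cutoff < 0 < amp_cutoff")
    sm = segments["segment_mean"]
    amp = sm >= amp_cutoff
    dele = sm <= del_cutoff
    by = segments["sample_id"]
    out = pd.DataFrame(
        {
            "amp_count": amp.groupby(by).sum(),
            "del_count": dele.groupby(by).sum(),
            "amp_sum": sm.where(amp, 0.0).groupby(by).sum(),
            "del_sum": sm.where(dele, 0.0).groupby(by).sum(),
        }
    )
    if samples is not None:
        out = out.reindex(pd.Index(samples), fill_value=0)
    out[["amp_count", "del_count"]] = out[["amp_count", "del_count"]].astype(np.int64)
    out["total_count"] = out["amp_count"] + out["del_count"]
    out.index.name = "sample_id"
    return out[["amp_count", "del_count", "total_count", "amp_sum", "del_sum"]]


def compare_scna_burden(summaries: pd.DataFrame, strata: pd.Series) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on total SCNA count, CYT-high vs CYT-low.

    Returns (U, p).  Raises if either stratum is empty.
    """
    strata = strata.reindex(summaries.index)
    high = summaries.loc[strata == "CYT-high", "total_count"].to_numpy()
    low = summaries.loc[strata == "CYT-low", "total_count"].to_numpy()
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("both CYT strata must be non-empty")
    if np.ptp(np.concatenate([high, low])) == 0:
        return 0.5 * len(high) * len(low), 1.0
    res = stats.mannwhitneyu(high, low, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
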