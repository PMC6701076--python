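"""CDN / ADN / priority neoepitope classification and per-sample loads.

Candidate mutant peptides arrive with predicted mutant and wild-type IC50
(nM) per MHC class.  A peptide is a classically defined neoepitope (CDN)
when the mutant binds MHC with high affinity (IC50 strictly below 50 nM);
an alternatively defined neoepitope (ADN) when the differential
agretopicity index DAI = wt_ic50 / mut_ic50 strictly exceeds 10 for MHC-I
or 4 for MHC-II; and a priority neoepitope when it meets both criteria or
is a CDN derived from a frameshift mutation.  All inequalities are strict.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import PipelineConfig, ValidationError

__all__ = ["compute_dai", "classify_neoepitopes", "neoepitope_load", "correlate_load_cyt"]

LOAD_COLUMNS = ["cdn_I", "cdn_II", "adn_I", "adn_II", "priority"]


def compute_dai(wt_ic50: float | np.ndarray, mut_ic50: float | np.ndarray) -> float | np.ndarray:
    """Differential agretopicity index: wild-type / mutant IC50.

    Larger DAI means the mutant peptide binds MHC more strongly than its
    wild-type counterpart (IC50 is a dissociation measure, lower = tighter).
    """
    wt = np.asarray(wt_ic50, dtype=float)
    mut = np.asarray(mut_ic50, dtype=float)
    if (wt <= 0).any() or (mut <= 0).any():
        raise ValidationError("IC50 values must be strictly positive")
    out = wt / mut
    return float(out) if out.ndim == 0 else out


def classify_neoepitopes(affinities: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Flag each affinity record as CDN / ADN / priority.

    Returns the input columns plus ``dai``, ``log2_dai`` (informational,
    not used for calls), ``is_cdn``, ``is_adn`` and ``is_priority``.
    """
    config = config or PipelineConfig()
    bad = ~affinities["mhc_class"].isin(["I", "II"])
    if bad.any():
        raise ValidationError(f"unknown mhc_class {affinities.loc[bad, 'mhc_class'].iloc[0]!r}")
    out = affinities.copy()
    out["dai"] = compute_dai(out["wt_ic50"].to_numpy(), out["mut_ic50"].to_numpy())
    out["log2_dai"] = np.log2(out["dai"])
    out["is_cdn"] = out["mut_ic50"] < config.cdn_ic50_cutoff
    dai_cut = np.where(out["mhc_class"] == "I", config.dai_cutoff_mhc1, config.dai_cutoff_mhc2)
    out["is_adn"] = out["dai"] > dai_cut
    out["is_priority"] = (out["is_cdn"] & out["is_adn"]) | (
        out["is_cdn"] & (out["variant_type"] == "frameshift")
    )
    return out


def neoepitope_load(calls: pd.DataFrame, samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Aggregate classified calls into per-sample neoepitope counts.

    Columns: cdn_I, cdn_II, adn_I, adn_II, priority.  Samples listed in
    ``samples`` with no records get zero counts.
    """
    is_I = calls["mhc_class"] == "I"
    out = pd.DataFrame(
        {
            "cdn_I": (calls["is_cdn"] & is_I).groupby(calls["sample_id"]).sum(),
            "cdn_II": (calls["is_cdn"] & ~is_I).groupby(calls["sample_id"]).sum(),
            "adn_I": (calls["is_adn"] & is_I).groupby(calls["sample_id"]).sum(),
            "adn_II": (calls["is_adn"] & ~is_I).groupby(calls["sample_id"]).sum(),
            "priority": calls["is_priority"].groupby(calls["sample_id"]).sum(),
        }
    )
    if samples is not None:
        out = out.reindex(pd.Index(samples), fill_value=0)
    out = out.fillna(0).astype(np.int64)
    out.index.name = "sample_id"
    return out[LOAD_COLUMNS]


def correlate_load_cyt(loads: pd.DataFrame, cyt_index: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each neoepitope load type with the cytolytic
    index over shared samples; zero-variance inputs yield NaN."""
    shared = loads.index.intersection(cyt_index.index)
    if len(shared) < 3:
        raise ValidationError("need at least 3 paired observations")
    rows = {}
    y = cyt_index.loc[shared].to_numpy(dtype=float)
    for col in loads.columns:
        x = loads.loc[shared, col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[col] = {"pearson_r": np.nan, "p": np.nan}
            continue
        r, p = stats.pearsonr(x, y)
        rows[col] = {"pearson_r": float(r), "p": float(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "load_type"
    return out
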