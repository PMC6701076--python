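"""Kaplan-Meier estimation, log-rank testing, and two-gene synergy survival.

Estimation and testing are delegated to ``lifelines`` (product-limit
estimator, Mantel-Cox log-rank).  The synergy operation dichotomizes each
of two genes at its cohort median (ties to "low" for determinism) and
compares the both-low and both-high groups against all other patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ValidationError

__all__ = ["SurvivalCurve", "km_estimate", "logrank_test", "synergy_groups", "synergy_survival"]


@dataclass
class SurvivalCurve:
    """Product-limit survival curve: event times with at-risk counts,
    event counts, and the survival probability after each time."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step-function value at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(clinical: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier estimate from a clinical table (os_time, os_event).

    Censored subjects leave the risk set without an event step.
    """
    if len(clinical) == 0:
        raise ValidationError("need at least one subject")
    if (clinical["os_time"] < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(clinical["os_time"], clinical["os_event"])
    table = kmf.event_table
    times = table.index.to_numpy(dtype=float)
    sf = kmf.survival_function_.iloc[:, 0].reindex(table.index).to_numpy(dtype=float)
    keep = ~((times == 0) & (table["observed"].to_numpy() == 0) & (table["censored"].to_numpy() == 0))
    return SurvivalCurve(
        event_times=times[keep],
        at_risk=table["at_risk"].to_numpy(dtype=np.int64)[keep],
        events=table["observed"].to_numpy(dtype=np.int64)[keep],
        survival=sf[keep],
    )


def logrank_test(clinical: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two groups.

    ``groups`` is aligned to ``clinical['sample_id']``; returns (chi2, p)
    on 1 degree of freedom.
    """
    labels = groups.reindex(clinical["sample_id"]).to_numpy()
    if pd.isna(labels).any():
        raise ValidationError("every subject needs a group label")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(uniq)}")
    a = clinical[labels == uniq[0]]
    b = clinical[labels == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("a group has no subjects")
    res = _ll_logrank(a["os_time"], b["os_time"], a["os_event"], b["os_event"])
    return float(res.test_statistic), float(res.p_value)


def synergy_groups(expr_two_genes: pd.DataFrame, rule: str = "median") -> pd.Series:
    """Partition samples by joint median dichotomization of two genes.

    ``expr_two_genes`` is sample x 2 expression values.  Each gene is split
    at its cohort median, values equal to the median going to "low";
    returns per-sample labels in {both_high, both_low, other}.
    """
    if rule != "median":
        raise ValidationError(f"unknown synergy rule {rule!r}")
    if expr_two_genes.shape[1] != 2:
        raise ValidationError("exactly two genes required")
    if len(expr_two_genes) < 8:
        raise ValidationError("need at least 8 samples for synergy grouping")
    highs = []
    for col in expr_two_genes.columns:
        v = expr_two_genes[col]
        if v.nunique() < 2:
            raise ValidationError(f"gene {col!r} is constant; cannot dichotomize")
        highs.append(v > v.median())
    both_high = highs[0] & highs[1]
    both_low = ~highs[0] & ~highs[1]
    out = pd.Series("other", index=expr_two_genes.index, name="synergy_group", dtype=object)
    out[both_high] = "both_high"
    out[both_low] = "both_low"
    return out


def synergy_survival(clinical: pd.DataFrame, grouping: pd.Series) -> dict:
    """Log-rank tests of both_low-vs-rest and both_high-vs-rest plus the
    three-group KM curves.

    Returns a dict with keys ``both_low_vs_rest`` and ``both_high_vs_rest``
    mapping to (chi2, p) (or None when the comparison group is empty,
    noted in the log), and ``curves`` mapping each group label to its
    :class:`SurvivalCurve`.
    """
    labels = grouping.reindex(clinical["sample_id"])
    results: dict = {"curves": {}}
    for label in ("both_low", "both_high", "other"):
        sub = clinical[(labels == label).to_numpy()]
        if len(sub):
            results["curves"][label] = km_estimate(sub)
    for key, target in (("both_low_vs_rest", "both_low"), ("both_high_vs_rest", "both_high")):
        mask = (labels == target).to_numpy()
        if mask.sum() == 0 or (~mask).sum() == 0:
            results[key] = None
            continue
        binary = pd.Series(np.where(mask, target, "rest"), index=clinical["sample_id"])
        results[key] = logrank_test(clinical, binary)
    return results
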