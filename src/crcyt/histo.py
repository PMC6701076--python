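"""Histology and validation-cohort scoring rules.

Ordinal scorers for H&E and IHC readouts — TIL counts per 10 high-power
fields (0-3 scale), peritumoral lymphocyte aggregates (0-2), stain
intensity (0-2+ operationalized on percent positivity), MMR protein status
with the dMMR call, the Bethesda five-marker microsatellite panel, and the
TIL/TAN median dichotomization — plus efficiency-corrected Pfaffl RT-qPCR
quantification.

Bin boundaries the source scales leave open are resolved to the
conservative (lower) bin: a TIL count of exactly 215 scores 2, exactly 5
aggregates scores 1, and values equal to the TIL/TAN median go to "low".
"""

from __future__ import annotations

from .io import ValidationError

__all__ = [
    "til_score",
    "aggregate_score",
    "stain_score",
    "mmr_status",
    "msi_panel",
    "til_tan_groups",
    "pfaffl_ratio",
]

BETHESDA_MARKERS = ("D2S123", "D5S346", "D17S250", "BAT25", "BAT26")


def til_score(count: float) -> int:
    """TIL ordinal score from a count per 10 high-power fields.

    0: fewer than 1 TIL; 1: 1-15; 2: more than 15 up to 215; 3: more than
    215.
    """
    if count < 0:
        raise ValidationError("TIL count must be non-negative")
    if count < 1:
        return 0
    if count <= 15:
        return 1
    if count <= 215:
        return 2
    return 3


def aggregate_score(n_aggregates: float) -> int:
    """Peritumoral lymphocyte aggregate score: 0 none, 1 up to 5, 2 more
    than 5."""
    if n_aggregates < 0:
        raise ValidationError("aggregate count must be non-negative")
    if n_aggregates == 0:
        return 0
    if n_aggregates <= 5:
        return 1
    return 2


def stain_score(pct_positive: float, low_cut: float = 10.0) -> int:
    """Stain intensity on the 0-2+ scale from percent positive cells.

    0 for no staining, 1+ for faint (below ``low_cut`` percent), 2+ for
    moderate or strong staining.
    """
    if not (0 <= pct_positive <= 100):
        raise ValidationError(f"percent positive must be in [0, 100], got {pct_positive}")
    if pct_positive == 0:
        return 0
    if pct_positive < low_cut:
        return 1
    return 2


def mmr_status(pct_positive: dict[str, float], threshold: float = 10.0) -> tuple[dict[str, str], str]:
    """Per-protein MMR IHC status and the sample-level pMMR/dMMR call.

    A protein is ``positive`` when at least ``threshold`` percent of cells
    stain (boundary inclusive), else ``lost``; the sample is dMMR when any
    protein is lost.
    """
    if not pct_positive:
        raise ValidationError("at least one MMR protein must be measured")
    per_protein = {
        name: ("positive" if pct >= threshold else "lost") for name, pct in pct_positive.items()
    }
    sample = "dMMR" if any(v == "lost" for v in per_protein.values()) else "pMMR"
    return per_protein, sample


def msi_panel(marker_unstable: dict[str, bool]) -> str:
    """Bethesda five-marker MSI call.

    Markers D2S123, D5S346, D17S250 (dinucleotide) and BAT25, BAT26
    (mononucleotide).  MSI-H with 2+ unstable markers, MSI-L with exactly
    one, MSS with none.
    """
    missing = [m for m in BETHESDA_MARKERS if m not in marker_unstable]
    if missing:
        raise ValidationError(f"missing Bethesda markers: {missing}")
    n = sum(bool(marker_unstable[m]) for m in BETHESDA_MARKERS)
    if n >= 2:
        return "MSI-H"
    if n == 1:
        return "MSI-L"
    return "MSS"


def til_tan_groups(
    til_pct: float,
    tan_pct: float,
    til_median: float = 5.0,
    tan_median: float = 2.0,
) -> dict[str, str]:
    """Dichotomize TIL and CD66b+ TAN percentages at the cohort medians
    (defaults 5% TIL, 2% TAN); values equal to the median go to low."""
    for name, v in (("til_pct", til_pct), ("tan_pct", tan_pct)):
        if not (0 <= v <= 100):
            raise ValidationError(f"{name} must be in [0, 100], got {v}")
    return {
        "TIL": "high" if til_pct > til_median else "low",
        "TAN": "high" if tan_pct > tan_median else "low",
    }


def pfaffl_ratio(
    target_efficiency: float,
    delta_ct_target: float,
    reference_efficiency: float,
    delta_ct_reference: float,
) -> float:
    """Efficiency-corrected relative expression (Pfaffl).

    ratio = E_target ** dCt_target / E_reference ** dCt_reference, with
    dCt = Ct(control) - Ct(sample) and amplification efficiencies in
    (1, 2.2].
    """
    for name, e in (("target", target_efficiency), ("reference", reference_efficiency)):
        if not (1.0 < e <= 2.2):
            raise ValidationError(f"{name} efficiency must be in (1, 2.2], got {e}")
    return float(target_efficiency**delta_ct_target / reference_efficiency**delta_ct_reference)
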