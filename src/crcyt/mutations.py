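"""Mutation-landscape summaries from MAF tables.

Covers MSI/MSS calling from mismatch-repair gene missense mutations,
per-sample nonsynonymous burden, the 6-class pyrimidine-reference
substitution spectrum, variant allele frequencies and the MATH intratumor
heterogeneity score, pairwise Fisher co-occurrence / mutual exclusivity,
and per-gene association with the cytolytic strata.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cyt import bh_adjust
from .io import NONSYNONYMOUS_CLASSES, ValidationError

logger = logging.getLogger("crcyt")

__all__ = [
    "classify_msi_from_maf",
    "nonsyn_burden",
    "mutation_spectrum",
    "compute_vaf",
    "math_score",
    "sample_math_scores",
    "pairwise_fisher",
    "gene_stratum_association",
    "SPECTRUM_CLASSES",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_msi_from_maf(
    maf: pd.DataFrame,
    mmr_genes: Sequence[str],
    samples: Iterable[str] | None = None,
) -> pd.Series:
    """Call MSI/MSS per sample from mismatch-repair gene missense mutations.

    A sample is MSI iff it carries at least one ``Missense_Mutation`` record
    in any of ``mmr_genes`` (the rule is literally missense-only: a nonsense
    MMR mutation does not trigger MSI).  Samples listed in ``samples`` but
    absent from the MAF are called MSS with a logged warning.
    """
    if not len(tuple(mmr_genes)):
        raise ValidationError("mmr_genes must be non-empty")
    hit = maf[
        maf["gene"].isin(mmr_genes) & (maf["variant_classification"] == "Missense_Mutation")
    ]["sample_id"].unique()
    if samples is None:
        samples = maf["sample_id"].unique()
    samples = pd.Index(samples)
    absent = samples.difference(maf["sample_id"].unique())
    if len(absent):
        logger.warning("%d samples absent from MAF called MSS: %s", len(absent), list(absent[:5]))
    return pd.Series(
        np.where(samples.isin(hit), "MSI", "MSS"), index=samples, name="msi_status"
    )


def nonsyn_burden(
    maf: pd.DataFrame,
    samples: Iterable[str] | None = None,
    nonsyn_classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
) -> pd.Series:
    """Count non-silent coding mutations per sample.

    Missense, nonsense, nonstop, splice-site, translation-start-site,
    frameshift and in-frame indel records count; Silent/UTR/Intron/RNA and
    unknown classifications do not.
    """
    counted = maf[maf["variant_classification"].isin(nonsyn_classes)]
    burden = counted.groupby("sample_id").size()
    if samples is None:
        samples = maf["sample_id"].unique()
    return burden.reindex(pd.Index(samples), fill_value=0).astype(np.int64).rename("nonsyn_burden")


def _snv_mask(maf: pd.DataFrame) -> pd.Series:
    ref = maf["ref_allele"].astype("string")
    alt = maf["alt_allele"].astype("string")
    bases = list("ACGT")
    return ref.isin(bases).fillna(False) & alt.isin(bases).fillna(False) & (ref != alt).fillna(False)


def mutation_spectrum(maf: pd.DataFrame, samples: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-sample fractions of the six pyrimidine-reference SNV classes.

    Purine-reference substitutions are strand-complemented into the
    pyrimidine frame (G>A becomes C>T, etc.); non-SNV records are skipped.
    Rows sum to 1 for samples with at least one SNV and are all-NaN
    otherwise.
    """
    snv = maf[_snv_mask(maf)].copy()
    ref = snv["ref_allele"].astype(str)
    alt = snv["alt_allele"].astype(str)
    purine = ref.isin(["A", "G"])
    ref = ref.where(~purine, ref.map(_COMPLEMENT))
    alt = alt.where(~purine, alt.map(_COMPLEMENT))
    snv["sub_class"] = ref + ">" + alt
    counts = (
        snv.groupby(["sample_id", "sub_class"]).size().unstack(fill_value=0)
        .reindex(columns=SPECTRUM_CLASSES, fill_value=0)
    )
    frac = counts.div(counts.sum(axis=1), axis=0)
    if samples is not None:
        frac = frac.reindex(pd.Index(samples))
    frac.columns.name = None
    frac.index.name = "sample_id"
    return frac


def compute_vaf(maf: pd.DataFrame) -> pd.Series:
    """Variant allele frequency alt/(alt+ref) per record; NaN when counts
    are missing or total depth is zero."""
    alt = maf["t_alt_count"].astype("Float64")
    ref = maf["t_ref_count"].astype("Float64")
    depth = alt + ref
    vaf = (alt / depth.where(depth > 0)).astype(float)
    return pd.Series(vaf, index=maf.index, name="vaf")


def math_score(vafs: Sequence[float], min_vafs: int = 5) -> float:
    """Mutant-allele tumor heterogeneity score of a VAF distribution.

    MATH = 100 * (1.4826 * MAD) / median, the ratio of the width of the
    VAF distribution (scaled median absolute deviation) to its center.
    Returns NaN when fewer than ``min_vafs`` VAFs are available or the
    median is zero.
    """
    v = np.asarray([x for x in vafs if np.isfinite(x)], dtype=float)
    if len(v) < min_vafs:
        return float("nan")
    med = float(np.median(v))
    if med == 0:
        return float("nan")
    mad = float(np.median(np.abs(v - med)))
    return 100.0 * 1.4826 * mad / med


def sample_math_scores(maf: pd.DataFrame, min_vafs: int = 5) -> pd.Series:
    """MATH score per sample from the VAFs of its mutations."""
    vaf = compute_vaf(maf)
    df = pd.DataFrame({"sample_id": maf["sample_id"], "vaf": vaf}).dropna()
    return (
        df.groupby("sample_id")["vaf"]
        .apply(lambda v: math_score(v.to_numpy(), min_vafs=min_vafs))
        .rename("math_score")
    )


def _presence_matrix(maf: pd.DataFrame, genes: Sequence[str], samples: pd.Index) -> pd.DataFrame:
    sub = maf[maf["gene"].isin(genes)]
    present = (
        sub.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
        .reindex(index=samples, columns=list(genes), fill_value=0)
        > 0
    )
    return present


def pairwise_fisher(
    maf: pd.DataFrame,
    genes: Sequence[str],
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Fisher exact tests for gene mutation co-occurrence.

    For each gene pair a 2x2 table of samples (both / only A / only B /
    neither) is tested two-sided; the direction is ``co-occurring`` when
    the odds ratio exceeds 1 and ``exclusive`` when it is below 1.  Genes
    mutated in no or all samples are skipped with a note.  q is BH over all
    tested pairs.
    """
    if len(genes) < 2:
        raise ValidationError("need at least two genes")
    if samples is None:
        samples = pd.Index(maf["sample_id"].unique())
    else:
        samples = pd.Index(samples)
    present = _presence_matrix(maf, genes, samples)
    usable = [g for g in genes if 0 < present[g].sum() < len(samples)]
    skipped = sorted(set(genes) - set(usable))
    if skipped:
        logger.info("pairwise_fisher: skipping genes mutated in 0 or all samples: %s", skipped)
    rows = []
    for a, b in itertools.combinations(usable, 2):
        pa, pb = present[a].to_numpy(), present[b].to_numpy()
        table = [
            [int((pa & pb).sum()), int((pa & ~pb).sum())],
            [int((~pa & pb).sum()), int((~pa & ~pb).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        direction = "co-occurring" if odds > 1 else ("exclusive" if odds < 1 else "none")
        rows.append({"gene_a": a, "gene_b": b, "odds_direction": direction, "p": float(p)})
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "odds_direction", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out


def gene_stratum_association(
    maf: pd.DataFrame,
    strata: pd.Series,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Fisher exact test of mutation against CYT-high vs CYT-low.

    ``strata`` maps sample_id to stratum labels; only CYT-high and CYT-low
    samples enter the 2x2 table.  The enriched stratum is the one with the
    higher mutated fraction.  q is BH over the gene list.
    """
    strata = strata[strata.isin(["CYT-high", "CYT-low"])]
    samples = strata.index
    present = _presence_matrix(maf, genes, pd.Index(samples))
    high = (strata == "CYT-high").to_numpy()
    rows = []
    for g in genes:
        mut = present[g].to_numpy()
        table = [
            [int((mut & high).sum()), int((mut & ~high).sum())],
            [int((~mut & high).sum()), int((~mut & ~high).sum())],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        n_high, n_low = int(high.sum()), int((~high).sum())
        frac_high = table[0][0] / n_high if n_high else np.nan
        frac_low = table[0][1] / n_low if n_low else np.nan
        if np.isnan(frac_high) or np.isnan(frac_low) or frac_high == frac_low:
            enriched = "none"
        else:
            enriched = "CYT-high" if frac_high > frac_low else "CYT-low"
        rows.append({"gene": g, "p": float(p), "enriched_stratum": enriched})
    out = pd.DataFrame(rows, columns=["gene", "p", "enriched_stratum"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out[["gene", "p", "q", "enriched_stratum"]]
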