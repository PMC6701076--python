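"""End-to-end orchestration: run every stage on real or synthetic inputs
and emit the per-sample cohort table, the association-test table, and a
run manifest.

Stages are isolated: each consumes only its declared inputs, and a run
with a missing input table simply skips the stages that need it (noted in
the manifest).  Benjamini-Hochberg adjustment is applied within each
analysis family (DE genes, checkpoint panel, gene-stratum associations,
Fisher pairs), never pooled across families.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cyt import compute_cyt, compute_tpm, stratify_cyt
from .expression import checkpoint_by_msi, checkpoint_correlation, differential_expression, filter_low_expression
from .io import ExpressionMatrix, PipelineConfig, ValidationError
from .mutations import classify_msi_from_maf, mutation_spectrum, nonsyn_burden, sample_math_scores
from .neoepitope import classify_neoepitopes, neoepitope_load
from .scna import compare_scna_burden, count_scna_events
from .survival import logrank_test, synergy_groups, synergy_survival

logger = logging.getLogger("crcyt")

__all__ = ["run_pipeline", "write_results"]


def _check_sample_consistency(expr: ExpressionMatrix, tables: dict[str, pd.DataFrame]) -> None:
    known = set(expr.samples)
    for name, table in tables.items():
        if table is None or not len(table):
            continue
        ids = set(table["sample_id"]) if "sample_id" in table.columns else set(table.index)
        stray = ids - known
        if stray:
            raise ValidationError(f"{name}: sample IDs absent from expression matrix: {sorted(stray)[:5]}")


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix,
    maf: pd.DataFrame | None = None,
    segments: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    affinities: pd.DataFrame | None = None,
) -> dict:
    """Run all stages whose inputs are present.

    Returns a dict with ``cohort`` (per-tumor-sample result table),
    ``tests`` (cohort-level association results), ``de`` (per-gene
    differential expression, when computable) and ``manifest``.
    """
    _check_sample_consistency(
        expression,
        {"maf": maf, "segments": segments, "clinical": clinical, "affinities": affinities},
    )
    tumors = expression.tumor_samples()
    manifest: dict = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages_run": [],
        "stages_skipped": [],
        "n_tumor": int(len(tumors)),
    }
    tests_rows: list[dict] = []

    # --- cytolytic index and strata (always runs) ---
    tpm = compute_tpm(expression, offset=config.tpm_offset)
    cyt = compute_cyt(tpm, config.cyt_genes).loc[tumors]
    strat = stratify_cyt(cyt, fraction=config.quartile_fraction)
    cohort = strat.copy()
    manifest["stages_run"].append("cytolytic_index")

    strata = strat["stratum"]

    # --- mutation landscape ---
    if maf is not None:
        msi = classify_msi_from_maf(maf, config.mmr_genes, samples=tumors)
        burden = nonsyn_burden(maf, samples=tumors)
        math = sample_math_scores(maf, min_vafs=config.math_min_vafs).reindex(tumors)
        spectrum = mutation_spectrum(maf, samples=tumors)
        cohort["msi_status"] = msi
        cohort["nonsyn_burden"] = burden
        cohort["math_score"] = math
        from .cyt import compare_groups

        u, p = compare_groups(burden.to_numpy(), np.where(msi == "MSI", "MSI", "MSS"))
        tests_rows.append({"family": "burden", "test": "burden_msi_vs_mss", "statistic": u, "p": p})
        hl = strata.isin(["CYT-high", "CYT-low"])
        u, p = compare_groups(burden[hl].to_numpy(), strata[hl].to_numpy())
        tests_rows.append({"family": "burden", "test": "burden_cythigh_vs_cytlow", "statistic": u, "p": p})
        manifest["stages_run"].append("mutation_landscape")
        manifest["spectrum_classes"] = list(spectrum.columns)
        manifest["math_mad_constant"] = 1.4826
    else:
        manifest["stages_skipped"].append("mutation_landscape")
        msi = None

    # --- SCNA burden ---
    if segments is not None:
        scna = count_scna_events(
            segments, config.scna_amp_cutoff, config.scna_del_cutoff, samples=tumors
        )
        cohort["scna_total"] = scna["total_count"]
        cohort["scna_amp"] = scna["amp_count"]
        cohort["scna_del"] = scna["del_count"]
        u, p = compare_scna_burden(scna, strata)
        tests_rows.append({"family": "scna", "test": "scna_cythigh_vs_cytlow", "statistic": u, "p": p})
        manifest["stages_run"].append("scna_burden")
    else:
        manifest["stages_skipped"].append("scna_burden")

    # --- neoepitopes ---
    if affinities is not None and len(affinities):
        calls = classify_neoepitopes(affinities, config)
        loads = neoepitope_load(calls, samples=tumors)
        for col in loads.columns:
            cohort[f"neo_{col}"] = loads[col]
        from .neoepitope import correlate_load_cyt

        corr = correlate_load_cyt(loads, cyt["cyt_index"])
        for load_type, row in corr.iterrows():
            tests_rows.append(
                {
                    "family": "neoepitope_correlation",
                    "test": f"{load_type}_vs_cyt",
                    "statistic": row["pearson_r"],
                    "p": row["p"],
                }
            )
        manifest["stages_run"].append("neoepitope_classify")
    else:
        manifest["stages_skipped"].append("neoepitope_classify")

    # --- immune expression ---
    de = None
    filtered = filter_low_expression(
        expression, config.cpm_filter_threshold, config.cpm_filter_sample_fraction
    )
    n_high = int((strata == "CYT-high").sum())
    n_low = int((strata == "CYT-low").sum())
    if n_high >= 3 and n_low >= 3:
        de = differential_expression(filtered, strata, de_fdr=config.de_fdr)
        manifest["stages_run"].append("differential_expression")
        manifest["n_genes_after_filter"] = int(len(filtered.genes))
    else:
        manifest["stages_skipped"].append("differential_expression")
    present_cp = [g for g in config.checkpoint_genes if g in tpm.genes]
    if present_cp:
        cc = checkpoint_correlation(tpm, cyt["cyt_index"], present_cp)
        for gene, row in cc.iterrows():
            tests_rows.append(
                {
                    "family": "checkpoint_cyt_correlation",
                    "test": f"{gene}_vs_cyt",
                    "statistic": row["pearson_r"],
                    "p": row["p"],
                }
            )
        if msi is not None and (msi == "MSI").any() and (msi == "MSS").any():
            cbm = checkpoint_by_msi(_subset_tpm(tpm, tumors), msi, present_cp)
            for gene, row in cbm.iterrows():
                tests_rows.append(
                    {
                        "family": "checkpoint_msi",
                        "test": f"{gene}_msi_vs_mss",
                        "statistic": row["U"],
                        "p": row["p"],
                        "direction": row["direction"],
                    }
                )
        manifest["stages_run"].append("immune_expression")
    else:
        manifest["stages_skipped"].append("immune_expression")

    # --- survival ---
    if clinical is not None:
        clin_t = clinical[clinical["sample_id"].isin(tumors)].reset_index(drop=True)
        hl = strata[strata.isin(["CYT-high", "CYT-low"])]
        clin_hl = clin_t[clin_t["sample_id"].isin(hl.index)].reset_index(drop=True)
        if len(clin_hl) and hl.nunique() == 2:
            chi2, p = logrank_test(clin_hl, hl)
            tests_rows.append(
                {"family": "survival", "test": "logrank_cythigh_vs_cytlow", "statistic": chi2, "p": p}
            )
        gene_tpm = tpm.tpm.loc[list(config.cyt_genes), tumors].T
        grouping = synergy_groups(gene_tpm)
        cohort["synergy_group"] = grouping
        syn = synergy_survival(clin_t, grouping)
        for key in ("both_low_vs_rest", "both_high_vs_rest"):
            if syn[key] is not None:
                chi2, p = syn[key]
                tests_rows.append(
                    {"family": "survival", "test": f"synergy_{key}", "statistic": chi2, "p": p}
                )
        cohort = cohort.join(clin_t.set_index("sample_id")[["os_time", "os_event"]])
        manifest["stages_run"].append("survival_synergy")
    else:
        manifest["stages_skipped"].append("survival_synergy")

    tests = pd.DataFrame(tests_rows)
    if len(tests):
        from .cyt import bh_adjust

        tests["q"] = np.nan
        for fam in tests["family"].unique():
            m = tests["family"] == fam
            tests.loc[m, "q"] = bh_adjust(tests.loc[m, "p"].to_numpy())
    cohort.index.name = "sample_id"
    return {"cohort": cohort, "tests": tests, "de": de, "manifest": manifest}


def _subset_tpm(tpm, samples):
    from .cyt import TpmMatrix

    return TpmMatrix(tpm=tpm.tpm[list(samples)], offset=tpm.offset)


def write_results(results: dict, out_dir: str | Path) -> None:
    """Write cohort_result.tsv, tests.tsv, de.tsv, manifest.json and a
    plain-text summary under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["cohort"].reset_index().to_csv(out / "cohort_result.tsv", sep="\t", index=False)
    results["tests"].to_csv(out / "tests.tsv", sep="\t", index=False)
    if results.get("de") is not None:
        results["de"].reset_index().rename(columns={"index": "gene"}).to_csv(
            out / "de.tsv", sep="\t", index=False
        )
    (out / "manifest.json").write_text(json.dumps(results["manifest"], indent=2, default=str))
    lines = [
        f"crcyt run: {results['manifest']['n_tumor']} tumor samples",
        f"stages run: {', '.join(results['manifest']['stages_run'])}",
        f"stages skipped: {', '.join(results['manifest']['stages_skipped']) or 'none'}",
    ]
    if len(results["tests"]):
        lines.append("association tests:")
        for _, row in results["tests"].iterrows():
            lines.append(f"  {row['test']}: p={row['p']:.3g} q={row['q']:.3g}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
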