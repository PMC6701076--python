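# crcyt

Immune cytolytic-activity analysis of colorectal tumor cohorts.

Colorectal cancers differ sharply in how visible they are to the immune
system: hypermutated, microsatellite-unstable (MSI) tumors present many
mutant peptides (neoepitopes) and attract cytotoxic T and NK cells, while
chromosomally unstable tumors tend to be immunologically cold.  `crcyt`
quantifies this axis from standard tumor-profiling tables and associates
it with the genomic and clinical features of the cohort.  It is written
for computational biologists working with TCGA-style colorectal data
(gene-level RNA-seq counts, MAF mutation calls, SEG copy-number segments,
clinical follow-up, predicted peptide–MHC affinities) and for anyone who
needs the same scoring rules on an in-house validation cohort.

## The statistic at its core

The cytolytic index of a tumor is the geometric mean of the
transcript-per-million expression of granzyme A and perforin:

    CYT = sqrt(TPM_GZMA × TPM_PRF1),      cyt_index = log2(CYT + 1)

with TPM computed by dividing each gene's raw counts by its maximum
transcript length, scaling every sample to 10^6, and adding a 0.01 offset
so logs are defined.  Tumors in the top quartile of CYT form the
**CYT-high** stratum, those in the bottom quartile **CYT-low**.  Around
this stratification the package implements:

* **MSI calling** from missense mutations in the nine mismatch-repair
  genes (MLH1, MLH3, MSH2, MSH3, MSH4, MSH5, MSH6, PMS1, PMS2);
* **nonsynonymous mutation burden**, the six-class substitution spectrum,
  and the MATH heterogeneity score
  `100 × 1.4826 × MAD(VAF) / median(VAF)`;
* **SCNA event counts**: segments with segment mean ≥ 0.6 (amplification)
  or ≤ −0.4 (deletion);
* **neoepitope classification**: CDN if mutant IC50 < 50 nM; ADN if the
  differential agretopicity index DAI = IC50_wt / IC50_mut exceeds 10
  (MHC-I) or 4 (MHC-II); priority if CDN∧ADN or a frameshift-derived CDN;
* **checkpoint expression** (12-gene panel: CD274/PD-L1, CTLA4, PDCD1,
  LAG3, TIGIT, IDO1, HAVCR2, VISTA, VTCN1, IDO2, ADORA2A, PDCD1LG2)
  correlated with CYT and compared MSI vs MSS;
* **differential expression** (CPM filter, Welch t on normalized log2
  counts, BH FDR < 0.1);
* **survival**: Kaplan–Meier curves, Mantel–Cox log-rank between strata,
  and two-gene synergy (both-high / both-low / other at per-gene medians);
* **histology scoring rules** for a validation cohort: TIL 0–3 bins,
  peritumoral aggregate 0–2 bins, stain 0–2+ scale, MMR IHC pMMR/dMMR,
  the Bethesda five-marker MSI panel, TIL/TAN median splits, and Pfaffl
  RT-qPCR quantification.

A synthetic cohort generator (`crcyt.simulate`) produces a TCGA-like
dataset with planted, recoverable effects so the full pipeline is testable
without any downloads; see `docs/methods.md` for the generative model.

## Worked example

Simulate a 60-tumor cohort and run every stage:

```sh
crcyt --out-dir demo/sim --seed 11 simulate --n-tumor 60 --n-normal 6 --n-genes 200
crcyt --out-dir demo/res run \
    --expression demo/sim/expression.tsv --sample-meta demo/sim/sample_meta.tsv \
    --maf demo/sim/mutations.maf --segments demo/sim/segments.seg \
    --clinical demo/sim/clinical.tsv --affinities demo/sim/affinities.tsv
```

which prints (abridged):

```
crcyt run: 60 tumor samples
stages run: cytolytic_index, mutation_landscape, scna_burden, neoepitope_classify,
            differential_expression, immune_expression, survival_synergy
association tests:
  burden_msi_vs_mss: p=7.38e-07 q=1.48e-06
  burden_cythigh_vs_cytlow: p=2.72e-05 q=2.72e-05
  scna_cythigh_vs_cytlow: p=4.39e-06 q=4.39e-06
  cdn_I_vs_cyt: p=0.00159 q=0.00222
  CD274_msi_vs_mss: p=5.9e-05 q=8.85e-05
  logrank_cythigh_vs_cytlow: p=0.979 q=0.979
  synergy_both_low_vs_rest: p=0.173 q=0.26
```

Reading the output: the planted MSI subgroup carries a significantly
higher nonsynonymous burden (`burden_msi_vs_mss`), the mutation load and
neoepitope counts rise with the cytolytic index, copy-number events are
enriched in CYT-low tumors (`scna_cythigh_vs_cytlow`, Mann–Whitney), and
checkpoint genes are up-regulated in MSI tumors.  At 60 tumors the
survival contrasts are underpowered (p ≈ 0.17–0.98); at the default 200
tumors the planted both-low hazard effect is detected in essentially
every replicate (see the acceptance tests).  Per-sample values land in
`demo/res/cohort_result.tsv`, one row per tumor:

```
sample_id  cyt_raw   cyt_index  stratum  msi_status  nonsyn_burden  math_score  scna_total ...
T0000      11055.28  13.43      middle   MSS         45             37.82       16
T0001      11729.15  13.52      middle   MSS         53             41.90       18
```

The same analyses are available as library functions (`compute_tpm`,
`compute_cyt`, `stratify_cyt`, `classify_msi_from_maf`, `math_score`,
`count_scna_events`, `classify_neoepitopes`, `km_estimate`,
`logrank_test`, `til_score`, …); `run_pipeline` orchestrates them on
in-memory tables.

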