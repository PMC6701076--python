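# Methods

## Cytolytic index and stratification

Raw gene counts are converted to TPM in two steps: counts are divided by
each gene's maximum transcript length (a coverage-depth estimate) and the
coverages are scaled so every sample sums to 10^6.  A 0.01 offset is then
added to every entry.  The offset is applied *after* scaling — the column
sums become 10^6 + 0.01·G — because its sole purpose is to remove exact
zeros ahead of logarithms and geometric means; rank-based stratification
is unaffected by the choice.

The cytolytic index is the geometric mean of the GZMA and PRF1 TPM
(`cyt_raw`) and its log form `cyt_index = log2(cyt_raw + 1)`.  Tumors are
ranked by `cyt_raw` descending with ties broken lexicographically by
sample ID (a deterministic convention; the stratification rule itself
does not specify tie handling).  The top `floor(0.25·n)` samples are
CYT-high and the bottom `floor(0.25·n)` CYT-low.  Group comparisons of a
statistic across strata use the Mann–Whitney U test for two groups and
Kruskal–Wallis for more, with Benjamini–Hochberg adjustment across the
batch of comparisons requested together.

## Mutation landscape

* **MSI calling** is deliberately literal: a sample is MSI iff it carries
  at least one *missense* mutation in any of the nine configured
  mismatch-repair genes.  A nonsense or frameshift MMR mutation does not
  trigger the call; the classification set is configurable for users who
  prefer any-non-silent.
* **Nonsynonymous burden** counts Missense, Nonsense, Nonstop,
  Splice_Site, Translation_Start_Site, Frame_Shift_Ins/Del and
  In_Frame_Ins/Del records.  Unknown classifications are retained in the
  table but excluded from the count, so MAF-dialect drift degrades
  gracefully instead of aborting a run.
* **Substitution spectra** collapse SNVs into the six pyrimidine-reference
  classes (purine-reference records are strand-complemented, G>A → C>T).
* **MATH** is `100 × 1.4826 × median(|v − median(v)|) / median(v)` over a
  sample's variant allele fractions `v = alt/(alt+ref)`.  The 1.4826
  constant makes the MAD a consistent spread estimate under normality and
  is recorded in the run manifest.  At least 5 VAFs are required (an
  explicit package convention; the score is reported unavailable below
  that, or when the median VAF is zero).
* **Co-occurrence / exclusivity** and **gene-vs-stratum association**
  both use two-sided Fisher exact tests on 2×2 sample tables with BH
  adjustment per family.  The stratum association is a documented
  simplification of a regression-based approach whose details are not
  reproducible from the available description.

## SCNA burden

"Copy-number event" means a segment whose log2-ratio segment mean is
≥ 0.6 (amplification) or ≤ −0.4 (deletion), boundaries inclusive, with no
segment-length weighting and no re-centering of the provided means.  We
read the counting rule as a count of qualifying segments; the literal
sums of qualifying segment means are also written (`amp_sum`, `del_sum`)
for users who want the alternative reading.  Strata are compared on the
total event count with a two-sided Mann–Whitney test.

## Neoepitopes

The differential agretopicity index is `DAI = IC50_wt / IC50_mut`, the
binding-improvement factor of the mutant peptide (IC50 is a dissociation
measure, so lower is tighter; DAI > 1 means the mutation improved
binding).  A log2 variant is emitted as an informational column but never
used for calls.  All classification inequalities are strict: CDN iff
`mut_ic50 < 50 nM`; ADN iff `DAI > 10` (MHC-I) or `DAI > 4` (MHC-II);
priority iff (CDN ∧ ADN) or (CDN ∧ frameshift-derived).  No minimum
absolute mutant affinity is imposed on ADNs.  Loads are integer counts
per sample and class, correlated with the cytolytic index by Pearson.

## Differential expression and checkpoints

Genes are pre-filtered on library-size CPM: a gene is kept iff it reaches
1 CPM in at least 50% of samples (boundary inclusive — the published
phrasing of the exclusion rule is ambiguous in polarity; we keep genes
expressed in at least half the cohort and expose both knobs).

The two-group test is Welch's t per gene on log2 counts with a 0.5
stabilizer, normalized by **median-of-ratios size factors** (the median,
over genes positive in every sample, of the count divided by the gene's
geometric mean).  Plain library-size CPM is not used for testing: when a
few very highly expressed genes genuinely differ between the groups —
exactly the situation the cytolytic strata create, since GZMA/PRF1 are
many-fold higher in CYT-high tumors — their library share deflates every
other gene's CPM and biases all null log2 fold-changes away from zero.
In simulation this inflated the null rejection rate from 5% to 6.6% and
the empirical FDR of the q < 0.1 call set to ~0.16; the robust size
factors restore both to nominal.  Precision weights, empirical-Bayes
moderation and quantile normalization of full RNA-seq DE frameworks are
intentionally omitted: the procedure is validated by its operating
characteristics on planted effects (power ≥ 80% at a 1.5 log2fc with 50
samples per stratum, empirical FDR ≤ 0.1), not by matching any specific
tool's gene lists.

Checkpoint analyses run on log2 TPM: Pearson correlation of each panel
gene with `cyt_index`, and a per-gene Mann–Whitney MSI-vs-MSS comparison
with BH adjustment across the 12-gene panel and the direction defined by
the higher median.

## Survival

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
`lifelines`; the package re-exposes them as a `SurvivalCurve` (event
times, risk sets, event counts, step values) and a `(chi2, p)` pair, and
the log-rank statistic is verified against a hand-computed
risk-set-summation oracle to 1e-10 on all-event toy data.  Two-gene
synergy dichotomizes each gene at its cohort median with ties assigned to
"low" (deterministic), partitions samples into both-high / both-low /
other, and reports both pairwise log-rank tests (both-low vs rest,
both-high vs rest) together with the three-group curves — the grouping
convention of the original web-based synergy analysis is not public, so
the median rule is our documented substitute.

## Histology scoring

Every ordinal scorer has an explicit boundary convention, each resolved
to the conservative (lower) bin where the published scale is open:
TIL counts per 10 high-power fields map to 0 (< 1), 1 (1–15), 2
(> 15 and ≤ 215), 3 (> 215), with exactly 215 → 2; peritumoral aggregates
to 0 (none), 1 (1–5), 2 (> 5), with exactly 5 → 1; stain percent-positive
to 0 (0%), 1+ (< 10%), 2+ (≥ 10%) — the percent cutpoint is our
operationalization of a qualitative faint/moderate scale; MMR proteins
are positive at ≥ 10% cells and a sample is dMMR if any protein is lost;
the five-marker MSI panel (D2S123, D5S346, D17S250, BAT25, BAT26) calls
MSI-H at ≥ 2 unstable markers, MSI-L at exactly 1, MSS at 0; TIL/TAN
groups split at 5%/2% medians with values equal to the median going to
"low".  Pfaffl relative quantification is
`E_target^ΔCt_target / E_ref^ΔCt_ref` with efficiencies required in
(1, 2.2].

## Synthetic cohort generator

The generator's defaults define the reference study conditions: 200
tumors, 20 normals, 2,000 genes, and one seeded RNG stream per output
table (identical configs reproduce byte-identical tables).

* **Expression**: gamma-Poisson (negative-binomial) counts with log-normal
  per-gene baseline means and log-normal per-gene dispersions (the data
  the generator emulates carry no published noise model, so a standard
  RNA-seq prior is used).  Library-size factors span exactly a 2.3-fold
  range.  GZMA/PRF1 are shifted ±3 log2 units in the planted top/bottom
  quartile tiers (CYT tiers), normals sit above the tumor mid level, and
  the 12 checkpoint genes are shifted +1.5 log2 units in samples that are
  MSI or CYT-high-tier.  One all-zero gene is planted so the CPM filter
  always has work to do.
* **Mutations**: per-sample nonsynonymous burdens are Poisson with mean
  300 (MSI) or 60 (MSS), doubled in the high-CYT tier; MSI samples carry
  1 + Poisson(1) planted MMR missense mutations (MSS samples none — the
  background gene pool excludes MMR genes); the substitution spectrum is
  C>T-dominant; VAFs are Beta(5, 5) thinned binomially at depth 100.
* **Segments**: Poisson-many events beyond the ±cutoffs (rate 40 in the
  low-CYT tier vs 20 otherwise) over a fixed background of segments kept
  strictly inside the cutoffs, so the true event count is exact.
* **Affinities**: Poisson(2 × missense count) candidate peptides per
  sample; mutant IC50 log-normal with ~10% of draws below 50 nM;
  independent log-normal wild-type IC50; 10% frameshift-derived.
* **Survival**: exponential with uniform administrative censoring on
  [0, 150].  The hazard ratio (1.8) attaches to the *realized* both-low
  group — the samples whose generated GZMA and PRF1 TPM both fall at or
  below the cohort medians.  This is the group the median-split synergy
  analysis recovers, so the planted effect and the tested contrast
  coincide; planting it on the narrower low tier alone dilutes the
  tested contrast with unaffected mid-tier samples and roughly halves
  detection power.
* MSI is planted as the common cause of the burden and checkpoint shifts,
  mirroring the observed correlations without asserting mechanism.

What the generator does *not* emulate — GC/length biases, batch effects,
subclonal copy-number structure, correlated gene modules, non-proportional
hazards, panel-dependent affinity distributions — bounds what passing
tests show: they demonstrate that the implemented rules recover planted
parameters under a faithful-but-idealized noise model, not that the
pipeline's power generalizes to any real cohort.

## Problem sizes and numerical conventions

Unit fixtures use 60-tumor cohorts; planted-effect recovery runs 100
replicates at the default 200-tumor scale; null-calibration runs 200
replicates at 60 tumors and checks each family's p-values against
uniformity by Kolmogorov–Smirnov at α = 0.01.  A full default cohort
simulates in under a second and the complete pipeline runs in well under
a minute.  Other conventions: TPM column sums hold to 1e-9 relative
tolerance before the offset; Mann–Whitney on fully tied data returns
p = 1 by convention (the tie-corrected asymptotic variance degenerates);
zero-variance genes get p = 1 in the DE test and an unavailable (NaN)
correlation elsewhere; BH q-values are computed within each analysis
family, never pooled across families.
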