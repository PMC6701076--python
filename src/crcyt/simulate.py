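"""Synthetic TCGA-like colorectal cohort with planted, recoverable effects.

The generator emulates the input side of the pipeline — negative-binomial
expression counts, MAF-style somatic mutations, SEG copy-number segments,
peptide IC50 affinities and exponential survival — with effect structure
planted so that every downstream association is testable:

* an MSI subgroup (default 15% of tumors) carries planted missense
  mutations in mismatch-repair genes, a five-fold higher nonsynonymous
  burden, and up-regulated immune-checkpoint genes;
* a designated top quartile of tumors has elevated GZMA/PRF1 expression
  (the CYT-high tier), doubled mutation burden, and also up-regulated
  checkpoints, while the bottom quartile carries roughly twice as many
  copy-number events beyond the SCNA cutoffs;
* neoepitope-candidate peptides arrive proportional to each sample's
  missense count with ~10% of mutant IC50s under 50 nM;
* survival is exponential with a hazard ratio (default 1.8) on the
  CYT-low tier, under uniform administrative censoring.

Every draw flows from ``SimulationConfig.seed``; identical configs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_CHECKPOINT_GENES,
    DEFAULT_MMR_GENES,
    ExpressionMatrix,
    MAF_COLUMNS,
    VARIANT_CLASSIFICATIONS,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_expression",
    "simulate_mutations",
    "simulate_segments",
    "simulate_affinities",
    "simulate_clinical",
    "assign_hazard_from_expression",
    "make_truth",
]

#: all-zero gene planted so the CPM filter has something to remove
ZERO_GENE = "SIMZERO1"


@dataclass
class SimulationConfig:
    """Cohort-scale and effect-size knobs for the synthetic generator.

    Defaults define the reference study conditions: 200 tumors, 20
    normals, 2000 genes, 15% MSI with Poisson nonsynonymous burdens of 300
    (MSI) vs 60 (MSS), Beta(5,5) variant allele fractions binomially
    thinned at depth 100, a 1.5 log2 fold-change on checkpoint genes in
    MSI/CYT-high samples, Poisson SCNA event rates 40 (CYT-low) vs 20,
    two candidate peptides per missense mutation, and a 1.8 hazard ratio
    on the CYT-low tier.
    """

    n_tumor: int = 200
    n_normal: int = 20
    n_genes: int = 2000
    msi_fraction: float = 0.15
    burden_mean_msi: float = 300.0
    burden_mean_mss: float = 60.0
    vaf_beta_params: tuple[float, float] = (5.0, 5.0)
    read_depth: int = 100
    checkpoint_genes: tuple[str, ...] = DEFAULT_CHECKPOINT_GENES
    checkpoint_log2fc_msi: float = 1.5
    cyt_genes: tuple[str, ...] = ("GZMA", "PRF1")
    cyt_fraction: float = 0.25
    cyt_log2fc: float = 3.0
    cyt_effect_on_burden: float = 2.0
    scna_rate_cytlow: float = 40.0
    scna_rate_cythigh: float = 20.0
    n_background_segments: int = 40
    neo_rate_per_missense: float = 2.0
    hazard_ratio_cytlow: float = 1.8
    baseline_hazard: float = 1.0 / 60.0
    censor_time: float = 150.0
    silent_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 8:
            raise ValidationError("n_tumor must be >= 8 (quartile strata degenerate below)")
        if not (0 < self.msi_fraction < 1):
            raise ValidationError("msi_fraction must be in (0, 1)")
        if self.read_depth < 10:
            raise ValidationError("read_depth must be >= 10")
        for name in (
            "burden_mean_msi",
            "burden_mean_mss",
            "scna_rate_cytlow",
            "scna_rate_cythigh",
            "neo_rate_per_missense",
            "hazard_ratio_cytlow",
            "baseline_hazard",
            "cyt_effect_on_burden",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        a, b = self.vaf_beta_params
        if a <= 0 or b <= 0:
            raise ValidationError("vaf_beta_params must be positive")
        n_special = len(self.cyt_genes) + len(self.checkpoint_genes) + len(DEFAULT_MMR_GENES) + 1
        if self.n_genes < n_special + 10:
            raise ValidationError(f"n_genes must be >= {n_special + 10}")


def _rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _gene_panel(config: SimulationConfig) -> list[str]:
    special = list(config.cyt_genes) + list(config.checkpoint_genes) + list(DEFAULT_MMR_GENES) + [ZERO_GENE]
    filler = [f"G{i:05d}" for i in range(config.n_genes - len(special))]
    return special + filler


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tumors = [f"T{i:04d}" for i in range(config.n_tumor)]
    normals = [f"N{i:04d}" for i in range(config.n_normal)]
    return tumors, normals


def make_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-tumor ground-truth labels and latent rates.

    Columns: msi (MSI/MSS), cyt_tier (high/mid/low), burden, hazard_group.
    The CYT tiers assign exactly floor(cyt_fraction * n) samples to the
    high and low tails, chosen uniformly at random.
    """
    rng = rng or np.random.default_rng(config.seed)
    tumors, _ = _sample_ids(config)
    n = config.n_tumor
    msi = rng.random(n) < config.msi_fraction
    k = int(np.floor(config.cyt_fraction * n))
    perm = rng.permutation(n)
    tier = np.full(n, "mid", dtype=object)
    tier[perm[:k]] = "high"
    tier[perm[n - k:]] = "low"
    mean = np.where(msi, config.burden_mean_msi, config.burden_mean_mss)
    mean = mean * np.where(tier == "high", config.cyt_effect_on_burden, 1.0)
    burden = rng.poisson(mean)
    truth = pd.DataFrame(
        {
            "msi": np.where(msi, "MSI", "MSS"),
            "cyt_tier": tier,
            "burden": burden.astype(np.int64),
            "hazard_group": np.where(tier == "low", "low", "rest"),
        },
        index=pd.Index(tumors, name="sample_id"),
    )
    return truth


def simulate_expression(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Negative-binomial gene x sample counts with the planted shifts.

    Per-gene baseline means are log-normal; per-gene dispersions come from
    a log-normal prior; library-size factors span a >= 2-fold range across
    samples.  GZMA/PRF1 are shifted up (down) by ``cyt_log2fc`` in the
    planted high (low) CYT tier, and checkpoint genes up by
    ``checkpoint_log2fc_msi`` in samples that are MSI or CYT-high.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = _gene_panel(config)
    tumors, normals = _sample_ids(config)
    samples = tumors + normals
    n_genes, n_samples = len(genes), len(samples)

    base_mean = rng.lognormal(mean=np.log(50.0), sigma=1.2, size=n_genes)
    dispersion = rng.lognormal(mean=np.log(0.1), sigma=0.5, size=n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    for g in config.cyt_genes:
        base_mean[gi[g]] = 200.0
        dispersion[gi[g]] = 0.05
    for g in config.checkpoint_genes:
        base_mean[gi[g]] = 100.0
        dispersion[gi[g]] = 0.05
    base_mean[gi[ZERO_GENE]] = 0.0

    # library-size exponents rescaled to span exactly 1.2 on the log2 scale
    e = rng.uniform(-1.0, 1.0, size=n_samples)
    e = (e - e.min()) / (e.max() - e.min()) * 1.2 - 0.6
    lib_factor = 2.0**e

    mean = np.tile(base_mean[:, None], (1, n_samples)).astype(float)
    tier = truth["cyt_tier"].reindex(tumors).to_numpy()
    msi = (truth["msi"].reindex(tumors) == "MSI").to_numpy()
    t_cols = np.arange(len(tumors))
    cyt_fold = np.where(tier == "high", 2.0**config.cyt_log2fc,
                        np.where(tier == "low", 2.0**-config.cyt_log2fc, 1.0))
    for g in config.cyt_genes:
        mean[gi[g], t_cols] *= cyt_fold
        # normals sit above the tumor mid level (cytolytic activity is
        # lower in tumors than in normal mucosa)
        mean[gi[g], len(tumors):] *= 2.0 ** (config.cyt_log2fc / 2.0)
    cp_fold = np.where(msi | (tier == "high"), 2.0**config.checkpoint_log2fc_msi, 1.0)
    for g in config.checkpoint_genes:
        mean[gi[g], t_cols] *= cp_fold
    mean *= lib_factor[None, :]

    shape = 1.0 / dispersion
    lam = rng.gamma(shape[:, None], (mean * dispersion[:, None]))
    counts = rng.poisson(lam).astype(np.int64)
    counts[gi[ZERO_GENE], :] = 0

    lengths = pd.Series(rng.integers(500, 5001, size=n_genes), index=pd.Index(genes, name="gene"))
    meta = pd.DataFrame(
        {
            "tissue": ["tumor"] * len(tumors) + ["normal"] * len(normals),
            "dataset": "COAD",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(counts=counts_df, lengths=lengths, sample_meta=meta)


_CLASS_PROBS = {
    "Missense_Mutation": 0.78,
    "Nonsense_Mutation": 0.05,
    "Splice_Site": 0.05,
    "Frame_Shift_Del": 0.04,
    "Frame_Shift_Ins": 0.03,
    "In_Frame_Del": 0.02,
    "In_Frame_Ins": 0.02,
    "Nonstop_Mutation": 0.01,
}
_SNV_CLASSES = {"Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation", "Silent", "Splice_Site"}
# pyrimidine-reference substitution classes with a C>T-dominant spectrum
_SUBS = np.array(["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"])
_SUB_PROBS = np.array([0.08, 0.06, 0.50, 0.06, 0.20, 0.10])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_mutations(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """MAF-style mutation table realizing each sample's true burden.

    Nonsynonymous records follow a missense-dominant classification mix
    and a C>T-dominant substitution spectrum (half of SNVs written with
    the purine-strand ref/alt to exercise complementation); silent
    mutations are added at ``silent_fraction`` of the burden.  MSI samples
    carry 1 + Poisson(1) planted missense mutations in mismatch-repair
    genes; MSS samples carry none (the background gene pool excludes MMR
    genes).  VAFs are Beta draws thinned binomially into t_alt/t_ref at
    ``read_depth``.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = _gene_panel(config)
    pool = [g for g in genes if g not in DEFAULT_MMR_GENES and g != ZERO_GENE]
    tumors = truth.index.to_numpy()
    burden = truth["burden"].to_numpy()
    msi = (truth["msi"] == "MSI").to_numpy()

    classes = np.array(list(_CLASS_PROBS))
    class_p = np.array(list(_CLASS_PROBS.values()))
    class_p = class_p / class_p.sum()

    sample_col, gene_col, class_col = [], [], []
    n_silent = rng.poisson(config.silent_fraction * burden)
    n_mmr = np.where(msi, 1 + rng.poisson(1.0, size=len(tumors)), 0)
    for i, sid in enumerate(tumors):
        k = int(burden[i]) - int(n_mmr[i])
        k = max(k, 0)
        cls = rng.choice(classes, size=k, p=class_p)
        gs = rng.choice(pool, size=k + int(n_silent[i]))
        sample_col.extend([sid] * (k + int(n_mmr[i]) + int(n_silent[i])))
        gene_col.extend(gs[:k])
        class_col.extend(cls)
        if n_mmr[i]:
            gene_col.extend(rng.choice(list(DEFAULT_MMR_GENES), size=int(n_mmr[i])))
            class_col.extend(["Missense_Mutation"] * int(n_mmr[i]))
        gene_col.extend(gs[k:])
        class_col.extend(["Silent"] * int(n_silent[i]))

    n = len(sample_col)
    cls_arr = np.array(class_col, dtype=object)
    is_snv = np.isin(cls_arr, list(_SNV_CLASSES))

    sub = rng.choice(_SUBS, size=n, p=_SUB_PROBS)
    ref = np.array([s[0] for s in sub], dtype=object)
    alt = np.array([s[2] for s in sub], dtype=object)
    flip = rng.random(n) < 0.5
    ref = np.where(flip, [_COMPLEMENT[b] for b in ref], ref)
    alt = np.where(flip, [_COMPLEMENT[b] for b in alt], alt)
    # indel-style alleles for the non-SNV classes
    ins = np.isin(cls_arr, ["Frame_Shift_Ins", "In_Frame_Ins"])
    dele = np.isin(cls_arr, ["Frame_Shift_Del", "In_Frame_Del"])
    ref = np.where(ins, "-", np.where(dele, "AC", ref))
    alt = np.where(ins, "AA", np.where(dele, "-", alt))

    a, b = config.vaf_beta_params
    vaf = rng.beta(a, b, size=n)
    t_alt = rng.binomial(config.read_depth, vaf)
    t_ref = config.read_depth - t_alt

    maf = pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene": gene_col,
            "variant_classification": cls_arr,
            "ref_allele": ref,
            "alt_allele": alt,
            "t_ref_count": pd.array(t_ref, dtype="Int64"),
            "t_alt_count": pd.array(t_alt, dtype="Int64"),
            "chromosome": rng.integers(1, 23, size=n).astype(str),
            "position": pd.array(rng.integers(1, 100_000_000, size=n), dtype="Int64"),
        }
    )
    maf["known_classification"] = maf["variant_classification"].isin(VARIANT_CLASSIFICATIONS)
    return maf[MAF_COLUMNS]


def simulate_segments(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """SEG table with Poisson-many events beyond the SCNA cutoffs.

    The planted CYT-low tier draws events at ``scna_rate_cytlow``, all
    other tumors at ``scna_rate_cythigh``; amplification means sit above
    0.6 and deletion means below -0.4, and background segments are kept
    strictly inside the cutoffs so the true event count is exact.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    for sid, tier in truth["cyt_tier"].items():
        rate = config.scna_rate_cytlow if tier == "low" else config.scna_rate_cythigh
        n_events = rng.poisson(rate)
        n_bg = config.n_background_segments
        n = n_events + n_bg
        is_amp = rng.random(n_events) < 0.5
        means = np.empty(n)
        means[:n_events] = np.where(
            is_amp,
            0.6 + rng.exponential(0.4, size=n_events),
            -0.4 - rng.exponential(0.3, size=n_events),
        )
        means[n_events:] = np.clip(rng.normal(0.0, 0.1, size=n_bg), -0.35, 0.55)
        start = rng.integers(1, 100_000_000, size=n)
        length = rng.integers(10_000, 10_000_000, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "chromosome": rng.integers(1, 23, size=n).astype(str),
                    "start": start,
                    "end": start + length,
                    "num_probes": rng.integers(10, 2000, size=n),
                    "segment_mean": means,
                    "_true_event": np.concatenate([np.ones(n_events, bool), np.zeros(n_bg, bool)]),
                }
            )
        )
    seg = pd.concat(rows, ignore_index=True)
    return seg


def simulate_affinities(
    config: SimulationConfig,
    truth: pd.DataFrame,
    maf: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Peptide-affinity table with Poisson-many candidates per missense.

    Mutant IC50s are log-normal with ~10% of draws under 50 nM; wild-type
    IC50s are independent log-normal; MHC class is I/II with equal
    probability and ~10% of peptides are frameshift-derived.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_missense = (
        maf[maf["variant_classification"] == "Missense_Mutation"]
        .groupby("sample_id")
        .size()
        .reindex(truth.index, fill_value=0)
    )
    rows = []
    # sigma chosen so P(IC50 < 50 nM) ~ 0.10 for a log-normal about 500 nM
    sigma = np.log(500.0 / 50.0) / 1.2816
    for sid, nm in n_missense.items():
        n_pep = rng.poisson(config.neo_rate_per_missense * nm)
        if n_pep == 0:
            continue
        mut = rng.lognormal(np.log(500.0), sigma, size=n_pep)
        wt = rng.lognormal(np.log(500.0), 1.0, size=n_pep)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "peptide_id": [f"{sid}_p{j:05d}" for j in range(n_pep)],
                    "mhc_class": np.where(rng.random(n_pep) < 0.5, "I", "II"),
                    "mut_ic50": mut,
                    "wt_ic50": wt,
                    "variant_type": np.where(rng.random(n_pep) < 0.1, "frameshift", "missense"),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "peptide_id", "mhc_class", "mut_ic50", "wt_ic50", "variant_type"]
        )
    return pd.concat(rows, ignore_index=True)


def assign_hazard_from_expression(
    config: SimulationConfig,
    truth: pd.DataFrame,
    expr: ExpressionMatrix,
) -> pd.DataFrame:
    """Attach the elevated-hazard group to the realized cytolytic-low tumors.

    The survival effect is planted on the samples whose generated GZMA and
    PRF1 TPM both fall at or below the cohort medians — the group the
    median-split synergy analysis recovers.  This group contains the
    planted low-CYT tier plus the mid-tier tumors that happen to express
    both genes below the median.
    """
    from .cyt import compute_tpm
    from .survival import synergy_groups

    tpm = compute_tpm(expr, offset=0.01)
    two = tpm.tpm.loc[list(config.cyt_genes), truth.index].T
    grouping = synergy_groups(two)
    truth = truth.copy()
    truth["hazard_group"] = np.where(grouping == "both_low", "low", "rest")
    return truth


def simulate_clinical(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with the hazard ratio on the CYT-low tier and
    uniform administrative censoring on [0, censor_time]."""
    rng = rng or np.random.default_rng(config.seed)
    hazard = config.baseline_hazard * np.where(
        truth["hazard_group"].to_numpy() == "low", config.hazard_ratio_cytlow, 1.0
    )
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_time, size=len(truth))
    os_time = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(np.int64)
    return pd.DataFrame(
        {"sample_id": truth.index, "os_time": os_time, "os_event": os_event}
    ).reset_index(drop=True)


def simulate_cohort(config: SimulationConfig) -> dict:
    """Generate the full mutually consistent synthetic cohort.

    Returns a dict with keys ``expression`` (:class:`ExpressionMatrix`),
    ``maf``, ``segments``, ``clinical``, ``affinities`` (DataFrames) and
    ``truth`` — the per-tumor ground-truth table extended with the true
    SCNA and neoepitope-candidate counts.
    """
    r_truth, r_expr, r_mut, r_seg, r_aff, r_clin = _rngs(config, 6)
    truth = make_truth(config, r_truth)
    expr = simulate_expression(config, truth, r_expr)
    truth = assign_hazard_from_expression(config, truth, expr)
    maf = simulate_mutations(config, truth, r_mut)
    seg = simulate_segments(config, truth, r_seg)
    aff = simulate_affinities(config, truth, maf, r_aff)
    clin = simulate_clinical(config, truth, r_clin)
    truth = truth.copy()
    truth["scna_count"] = (
        seg.groupby("sample_id")["_true_event"].sum().reindex(truth.index, fill_value=0).astype(np.int64)
    )
    if len(aff):
        truth["neo_count"] = aff.groupby("sample_id").size().reindex(truth.index, fill_value=0).astype(np.int64)
    else:
        truth["neo_count"] = 0
    seg = seg.drop(columns=["_true_event"])
    return {
        "expression": expr,
        "maf": maf,
        "segments": seg,
        "clinical": clin,
        "affinities": aff,
        "truth": truth,
    }
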