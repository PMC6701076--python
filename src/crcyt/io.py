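"""Readers, writers and validation for the tabular inputs of the pipeline.

All tables travel as pandas DataFrames with fixed, validated schemas:

* expression — gene x sample raw counts with a per-gene maximum transcript
  length column and a separate sample-metadata table (tissue, dataset)
* MAF — TCGA-dialect tab-delimited somatic mutations
* SEG — copy-number segments with a log2-ratio segment mean
* clinical — overall-survival time and event indicator per sample
* affinity — predicted mutant / wild-type IC50 (nM) per candidate peptide
* histology — counted TILs, aggregates and percent-positive stains

Coordinates in MAF and SEG files are 1-based inclusive (TCGA convention).
Validation is total: malformed input raises :class:`ValidationError` naming
the file, the offending row and the field — never a silently truncated table.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("crcyt")

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "PipelineConfig",
    "NONSYNONYMOUS_CLASSES",
    "VARIANT_CLASSIFICATIONS",
    "setup_logging",
    "read_expression",
    "write_expression",
    "read_maf",
    "write_maf",
    "read_segments",
    "write_segments",
    "read_clinical",
    "write_clinical",
    "read_affinities",
    "write_affinities",
    "read_histology",
    "load_config",
    "save_config",
]


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract."""


def setup_logging(level: str = "INFO") -> None:
    """Route pipeline logs to standard error at the requested level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# controlled vocabularies
# ---------------------------------------------------------------------------

#: MAF Variant_Classification vocabulary accepted without a flag.
VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Splice_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Silent",
        "Translation_Start_Site",
        "Nonstop_Mutation",
        "3'UTR",
        "5'UTR",
        "Intron",
        "RNA",
    }
)

#: Non-silent coding classes counted toward the nonsynonymous burden.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
    }
)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts plus transcript lengths and sample metadata.

    Attributes
    ----------
    counts
        DataFrame indexed by gene symbol with one column per sample;
        non-negative integer read counts.
    lengths
        Maximum transcript length in bp per gene (same index as ``counts``),
        all >= 1.
    sample_meta
        DataFrame indexed by sample ID with columns ``tissue``
        (``tumor``/``normal``) and ``dataset`` (e.g. ``COAD``/``READ``).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.counts.index
        samples = self.counts.columns
        if genes.duplicated().any():
            dup = genes[genes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dup}")
        if samples.duplicated().any():
            dup = samples[samples.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)][0]
            raise ValidationError(f"negative count for gene {bad!r}")
        missing = genes.difference(self.lengths.index)
        if len(missing):
            raise ValidationError(f"missing transcript length for genes: {missing.tolist()}")
        self.lengths = self.lengths.reindex(genes)
        if (self.lengths < 1).any() or self.lengths.isna().any():
            bad = self.lengths.index[~(self.lengths >= 1)][0]
            raise ValidationError(f"transcript length < 1 bp for gene {bad!r}")
        meta_missing = samples.difference(self.sample_meta.index)
        if len(meta_missing):
            raise ValidationError(f"samples without metadata: {meta_missing.tolist()}")
        self.sample_meta = self.sample_meta.reindex(samples)
        bad_tissue = ~self.sample_meta["tissue"].isin(["tumor", "normal"])
        if bad_tissue.any():
            raise ValidationError(
                f"invalid tissue label for sample {self.sample_meta.index[bad_tissue][0]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def tumor_samples(self) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["tissue"] == "tumor"]


def read_expression(path: str | Path, meta_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    The file carries gene symbols in a ``gene`` first column, transcript
    lengths in a ``length`` second column, and one count column per sample.
    Sample metadata comes from ``meta_path`` (TSV: sample_id, tissue,
    dataset); if omitted, every sample is assumed a tumor from an
    ``unknown`` dataset.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in ("gene", "length"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("gene", "length")]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns found")
    counts = df[sample_cols]
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & counts.notna() | counts.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise ValidationError(f"{path}: non-numeric or missing count at data row {row + 1}")
    neg = (numeric < 0).to_numpy()
    if neg.any():
        row = int(np.argwhere(neg)[0][0])
        raise ValidationError(f"{path}: negative count at data row {row + 1}")
    counts = numeric.astype(np.int64)
    counts.index = pd.Index(df["gene"], name="gene")
    lengths = pd.Series(
        pd.to_numeric(df["length"], errors="coerce").to_numpy(),
        index=counts.index,
        name="length",
    )
    if lengths.isna().any():
        bad_gene = lengths.index[lengths.isna()][0]
        raise ValidationError(f"{path}: missing length for gene {bad_gene!r}")
    lengths = lengths.astype(np.int64)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    else:
        meta = pd.DataFrame(
            {"tissue": "tumor", "dataset": "unknown"}, index=pd.Index(sample_cols, name="sample_id")
        )
    return ExpressionMatrix(counts=counts, lengths=lengths, sample_meta=meta)


def write_expression(expr: ExpressionMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    out = expr.counts.copy()
    out.insert(0, "length", expr.lengths)
    out.reset_index().rename(columns={out.index.name or "index": "gene"}).to_csv(
        path, sep="\t", index=False
    )
    if meta_path is not None:
        expr.sample_meta.rename_axis("sample_id").reset_index().to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")
_MAF_RENAME = {
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
    "Tumor_Sample_Barcode": "sample_id",
    "Reference_Allele": "ref_allele",
    "Tumor_Seq_Allele2": "alt_allele",
    "Chromosome": "chromosome",
    "Start_Position": "position",
    "t_ref_count": "t_ref_count",
    "t_alt_count": "t_alt_count",
}
MAF_COLUMNS = [
    "sample_id",
    "gene",
    "variant_classification",
    "ref_allele",
    "alt_allele",
    "t_ref_count",
    "t_alt_count",
    "chromosome",
    "position",
    "known_classification",
]


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a TCGA-dialect MAF into the canonical mutation table.

    Lines starting with ``#`` are comments.  Unknown
    ``Variant_Classification`` values are retained verbatim but flagged
    ``known_classification = False`` so burden counting can exclude them
    without aborting the run.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory MAF column {col!r}")
    df = df.rename(columns=_MAF_RENAME)
    for col in ("ref_allele", "alt_allele", "chromosome"):
        if col not in df.columns:
            df[col] = pd.NA
    for col in ("t_ref_count", "t_alt_count", "position"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        else:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
    for col in ("t_ref_count", "t_alt_count"):
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"{path}: negative read count in column {col}")
    df["known_classification"] = df["variant_classification"].isin(VARIANT_CLASSIFICATIONS)
    n_unknown = int((~df["known_classification"]).sum())
    if n_unknown:
        logger.warning("%s: %d records with unknown Variant_Classification retained", path, n_unknown)
    return df[MAF_COLUMNS]


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    inverse = {v: k for k, v in _MAF_RENAME.items()}
    maf.drop(columns=["known_classification"], errors="ignore").rename(columns=inverse).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SEG / clinical / affinity / histology
# ---------------------------------------------------------------------------

_SEG_RENAME = {
    "Sample": "sample_id",
    "Chromosome": "chromosome",
    "Start": "start",
    "End": "end",
    "Num_Probes": "num_probes",
    "Segment_Mean": "segment_mean",
}


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG copy-number table (Sample, Chromosome, Start, End,
    Num_Probes, Segment_Mean); Num_Probes is optional."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Sample": str, "Chromosome": str})
    for col in ("Sample", "Chromosome", "Start", "End", "Segment_Mean"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory SEG column {col!r}")
    df = df.rename(columns=_SEG_RENAME)
    if "num_probes" not in df.columns:
        df["num_probes"] = pd.NA
    df["start"] = pd.to_numeric(df["start"], errors="raise").astype(np.int64)
    df["end"] = pd.to_numeric(df["end"], errors="raise").astype(np.int64)
    df["segment_mean"] = pd.to_numeric(df["segment_mean"], errors="raise").astype(float)
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValidationError(f"{path}: start > end at data row {int(np.argwhere(bad.to_numpy())[0][0]) + 1}")
    if ~np.isfinite(df["segment_mean"]).all():
        row = int(np.argwhere(~np.isfinite(df["segment_mean"].to_numpy()))[0][0])
        raise ValidationError(f"{path}: non-finite Segment_Mean at data row {row + 1}")
    return df[["sample_id", "chromosome", "start", "end", "num_probes", "segment_mean"]]


def write_segments(seg: pd.DataFrame, path: str | Path) -> None:
    inverse = {v: k for k, v in _SEG_RENAME.items()}
    seg.rename(columns=inverse).to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV (sample_id, os_time, os_event, covariates...)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory clinical column {col!r}")
    df["os_time"] = pd.to_numeric(df["os_time"], errors="raise").astype(float)
    df["os_event"] = pd.to_numeric(df["os_event"], errors="raise")
    if (df["os_time"] < 0).any():
        row = int(np.argwhere((df["os_time"] < 0).to_numpy())[0][0])
        raise ValidationError(f"{path}: negative os_time at data row {row + 1}")
    if ~df["os_event"].isin([0, 1]).all():
        row = int(np.argwhere((~df["os_event"].isin([0, 1])).to_numpy())[0][0])
        raise ValidationError(f"{path}: os_event not in {{0,1}} at data row {row + 1}")
    df["os_event"] = df["os_event"].astype(np.int64)
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False)


def read_affinities(path: str | Path) -> pd.DataFrame:
    """Read the peptide-affinity TSV (sample_id, peptide_id, mhc_class,
    mut_ic50, wt_ic50, variant_type); IC50s in nM, strictly positive."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "peptide_id": str, "mhc_class": str})
    for col in ("sample_id", "peptide_id", "mhc_class", "mut_ic50", "wt_ic50", "variant_type"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory affinity column {col!r}")
    for col in ("mut_ic50", "wt_ic50"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        bad = ~(df[col] > 0)
        if bad.any():
            row = int(np.argwhere(bad.to_numpy())[0][0])
            raise ValidationError(f"{path}: non-positive {col} at data row {row + 1}")
    bad_class = ~df["mhc_class"].isin(["I", "II"])
    if bad_class.any():
        row = int(np.argwhere(bad_class.to_numpy())[0][0])
        raise ValidationError(f"{path}: unknown mhc_class at data row {row + 1}")
    return df


def write_affinities(aff: pd.DataFrame, path: str | Path) -> None:
    aff.to_csv(path, sep="\t", index=False)


def read_histology(path: str | Path) -> pd.DataFrame:
    """Read a histology-score table; any ``*_pct`` / ``pct_*`` column is
    validated to lie in [0, 100]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing mandatory column 'sample_id'")
    for col in df.columns:
        if col.endswith("_pct") or col.startswith("pct_"):
            vals = pd.to_numeric(df[col], errors="raise")
            bad = (vals < 0) | (vals > 100)
            if bad.any():
                row = int(np.argwhere(bad.to_numpy())[0][0])
                raise ValidationError(f"{path}: percent outside [0,100] in {col} at data row {row + 1}")
            df[col] = vals.astype(float)
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

DEFAULT_MMR_GENES = ("MLH1", "MLH3", "MSH2", "MSH3", "MSH4", "MSH5", "MSH6", "PMS1", "PMS2")
DEFAULT_CHECKPOINT_GENES = (
    "CD274",
    "CTLA4",
    "PDCD1",
    "LAG3",
    "TIGIT",
    "IDO1",
    "HAVCR2",
    "VISTA",
    "VTCN1",
    "IDO2",
    "ADORA2A",
    "PDCD1LG2",
)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with published defaults.

    The cytolytic index is the geometric mean of ``cyt_genes`` TPM; strata
    take the top and bottom ``quartile_fraction`` of tumors.  MSI is called
    from missense mutations in ``mmr_genes``.  Neoepitopes are CDN when the
    mutant IC50 is below ``cdn_ic50_cutoff`` (nM) and ADN when the
    wild-type/mutant IC50 ratio exceeds the MHC-class DAI cutoff.  SCNA
    events are segments with segment mean >= ``scna_amp_cutoff`` or
    <= ``scna_del_cutoff``.
    """

    cyt_genes: tuple[str, ...] = ("GZMA", "PRF1")
    tpm_offset: float = 0.01
    quartile_fraction: float = 0.25
    mmr_genes: tuple[str, ...] = DEFAULT_MMR_GENES
    checkpoint_genes: tuple[str, ...] = DEFAULT_CHECKPOINT_GENES
    cdn_ic50_cutoff: float = 50.0
    dai_cutoff_mhc1: float = 10.0
    dai_cutoff_mhc2: float = 4.0
    scna_amp_cutoff: float = 0.6
    scna_del_cutoff: float = -0.4
    cpm_filter_threshold: float = 1.0
    cpm_filter_sample_fraction: float = 0.5
    de_fdr: float = 0.1
    survival_alpha: float = 0.05
    til_median: float = 5.0
    tan_median: float = 2.0
    mmr_positive_pct: float = 10.0
    stain_low_cut: float = 10.0
    math_min_vafs: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.cyt_genes = tuple(self.cyt_genes)
        self.mmr_genes = tuple(self.mmr_genes)
        self.checkpoint_genes = tuple(self.checkpoint_genes)
        if not (0 < self.quartile_fraction <= 0.5):
            raise ValidationError(f"quartile_fraction must be in (0, 0.5], got {self.quartile_fraction}")
        if not (0 < self.cpm_filter_sample_fraction <= 1):
            raise ValidationError("cpm_filter_sample_fraction must be in (0, 1]")
        if self.cdn_ic50_cutoff <= 0 or self.dai_cutoff_mhc1 <= 0 or self.dai_cutoff_mhc2 <= 0:
            raise ValidationError("IC50/DAI cutoffs must be positive")
        if not (self.scna_del_cutoff < 0 < self.scna_amp_cutoff):
            raise ValidationError("SCNA cutoffs must satisfy del < 0 < amp")
        if not (0 < self.de_fdr < 1) or not (0 < self.survival_alpha < 1):
            raise ValidationError("de_fdr and survival_alpha must be in (0, 1)")
        if self.tpm_offset < 0:
            raise ValidationError("tpm_offset must be >= 0")
        for name in ("til_median", "tan_median", "mmr_positive_pct", "stain_low_cut"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{name} must be a percent in [0, 100]")
        if self.math_min_vafs < 1:
            raise ValidationError("math_min_vafs must be >= 1")
        if not all(np.isfinite(v) for v in (
            self.cdn_ic50_cutoff, self.dai_cutoff_mhc1, self.dai_cutoff_mhc2,
            self.scna_amp_cutoff, self.scna_del_cutoff, self.tpm_offset,
        )):
            raise ValidationError("cutoffs must be finite")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; absent keys take the published defaults, unknown
    keys raise a warning, out-of-range values are rejected."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    for key in sorted(unknown):
        logger.warning("%s: unknown config key %r ignored", path, key)
    return PipelineConfig(**{k: v for k, v in raw.items() if k in known})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    for key in ("cyt_genes", "mmr_genes", "checkpoint_genes"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
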