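"""Core data containers, file I/O and configuration.

The package works on three kinds of tabular inputs, all plain delimited
text (tab-separated by default, comma accepted):

* feature-by-sample abundance matrices (gene counts or metabolite feature
  intensities) plus a sample-metadata table;
* replicated genotype-by-trait tables with a per-trait polarity
  (``higher_better`` for yield-like traits, ``earlier_better`` for
  heading-date-like traits);
* per-accession variant sets: SNPs/InDels as VCF 4.x, CNV/SV calls as
  interval tables with CHROM / POS1 / POS2 / TYPE / SIZE columns.

Coordinates are 1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("heteropattern")

#: column schema of a sample-metadata table
META_COLUMNS = [
    "sample_id",
    "genotype_id",
    "role",
    "female_parent_id",
    "male_parent_id",
    "stage",
    "replicate",
]

PATTERNS = ["additive", "partially_dominant", "dominant", "overdominant", "NA"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds and sizes shared by every analysis stage.

    Defaults follow the conventions of the quantitative heterosis
    framework this package implements: differential features at
    |log2FC| >= 2 and BH-adjusted p <= 1e-4, pattern contrasts at
    alpha = 0.05, a VIP screening threshold of 1, a latent-factor cap of
    100 for PLS regression and 5 components for PLS-DA with tenfold
    cross-validation, 2000 label permutations, a Spearman network
    threshold of 0.8, and a partial-dominance split at 0.5.
    """

    alpha: float = 0.05
    de_log2fc: float = 2.0
    de_adj_p: float = 1e-4
    fdr_method: str = "fdr_bh"
    vip_threshold: float = 1.0
    max_latent_regression: int = 100
    max_components_da: int = 5
    cv_folds: int = 10
    n_permutations: int = 2000
    network_rho: float = 0.8
    pd_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "de_adj_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be non-negative")
        if not 0 < self.pd_split < 1:
            raise ValueError("pd_split must lie in (0, 1)")
        if not 0 < self.network_rho <= 1:
            raise ValueError("network_rho must lie in (0, 1]")
        for name in ("max_latent_regression", "max_components_da",
                     "cv_folds", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def rng(self) -> np.random.Generator:
        """Root random generator; all stochastic steps derive from it."""
        return np.random.default_rng(self.seed)


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# omics matrices and sample metadata
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """Feature-by-sample abundance matrix.

    ``values`` is a features x samples DataFrame; ``layer_tag`` records
    which omics layer it holds (``"transcript"`` or ``"metabolite"``).
    """

    values: pd.DataFrame
    layer_tag: str = "transcript"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups)}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)}")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, features: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "OmicsMatrix":
        vals = self.values
        if features is not None:
            vals = vals.loc[list(features)]
        if samples is not None:
            vals = vals[list(samples)]
        return OmicsMatrix(vals.copy(), self.layer_tag)


@dataclass
class SampleMeta:
    """Per-sample metadata: genotype, parent/F1 role, parentage, stage, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", "genotype_id", "role") if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample metadata lacks required columns: {missing}")
        for col in META_COLUMNS:
            if col not in self.table.columns:
                self.table[col] = np.nan
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in metadata: {list(dups)}")
        bad_roles = set(self.table["role"]) - {"parent", "F1", "QC"}
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        parents = set(self.table.loc[self.table["role"] == "parent", "genotype_id"])
        f1 = self.table[self.table["role"] == "F1"]
        for _, row in f1.iterrows():
            for col in ("female_parent_id", "male_parent_id"):
                pid = row[col]
                if pd.isna(pid) or pid == "":
                    raise ValueError(
                        f"F1 sample {row['sample_id']} lacks {col}")
                if parents and pid not in parents:
                    raise ValueError(
                        f"F1 sample {row['sample_id']} names unknown parent {pid!r}")
        key = self.table[["genotype_id", "stage", "replicate"]].astype(str)
        if key.duplicated().any() and self.table["replicate"].notna().all():
            dup = self.table.loc[key.duplicated(), "sample_id"]
            raise ValueError(
                f"replicate indices not unique within (genotype, stage): {list(dup)}")

    def samples_of(self, genotype_id: str, stage: object | None = None) -> list[str]:
        t = self.table
        mask = t["genotype_id"] == genotype_id
        if stage is not None:
            mask &= t["stage"].astype(str) == str(stage)
        return list(t.loc[mask, "sample_id"])

    @property
    def stages(self) -> list:
        return sorted(self.table["stage"].dropna().unique(), key=str)


@dataclass
class CrossDesign:
    """Hybrid pedigree: each hybrid's female/male parents plus the pooled
    genotype id shared by a reciprocal pair (replicates of both members of
    a reciprocal pair are combined under the pooled id downstream)."""

    hybrids: pd.DataFrame  # hybrid_id, female_parent_id, male_parent_id, pooled_id

    def __post_init__(self) -> None:
        need = {"hybrid_id", "female_parent_id", "male_parent_id", "pooled_id"}
        missing = need - set(self.hybrids.columns)
        if missing:
            raise ValueError(f"cross design lacks columns: {sorted(missing)}")
        if self.hybrids["hybrid_id"].duplicated().any():
            raise ValueError("duplicate hybrid ids in cross design")
        for pooled, grp in self.hybrids.groupby("pooled_id"):
            sets = {frozenset((r.female_parent_id, r.male_parent_id))
                    for r in grp.itertuples()}
            if len(sets) != 1:
                raise ValueError(
                    f"reciprocal group {pooled!r} mixes different parent pairs")

    @property
    def pooled_ids(self) -> list[str]:
        return list(dict.fromkeys(self.hybrids["pooled_id"]))

    def parents_of(self, pooled_id: str) -> tuple[str, str]:
        """(female, male) parents of the first-listed member of a pooled pair."""
        grp = self.hybrids[self.hybrids["pooled_id"] == pooled_id]
        if grp.empty:
            raise KeyError(pooled_id)
        row = grp.iloc[0]
        return row["female_parent_id"], row["male_parent_id"]

    def members_of(self, pooled_id: str) -> list[str]:
        return list(self.hybrids.loc[self.hybrids["pooled_id"] == pooled_id,
                                     "hybrid_id"])


@dataclass
class TraitTable:
    """Replicated genotype x trait values with per-trait polarity.

    ``polarity[trait]`` is ``"higher_better"`` (default for yield-like
    traits) or ``"earlier_better"`` (heading-date-like traits, where a
    smaller value is agronomically favourable).
    """

    table: pd.DataFrame  # genotype_id, trait, replicate, value
    polarity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"genotype_id", "trait", "value"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"trait table lacks columns: {sorted(missing)}")
        for trait in self.table["trait"].unique():
            pol = self.polarity.setdefault(trait, "higher_better")
            if pol not in ("higher_better", "earlier_better"):
                raise ValueError(f"unknown polarity {pol!r} for trait {trait!r}")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))

    def replicate_values(self, genotype_id: str, trait: str) -> np.ndarray:
        mask = (self.table["genotype_id"] == genotype_id) & (self.table["trait"] == trait)
        return self.table.loc[mask, "value"].to_numpy(float)

    def genotype_means(self, trait: str) -> pd.Series:
        sub = self.table[self.table["trait"] == trait]
        return sub.groupby("genotype_id")["value"].mean()


# ---------------------------------------------------------------------------
# variant sets
# ---------------------------------------------------------------------------

SMALL_CLASSES = ("SNP", "InDel")
INTERVAL_CLASSES = ("CNV", "SV")
VARIANT_CLASSES = SMALL_CLASSES + INTERVAL_CLASSES


@dataclass
class VariantSet:
    """Typed, exact-match-comparable variant keys for one accession.

    Small-variant keys are ``(CHROM, POS, REF, ALT, GT)`` with the GT
    canonicalized (unphased, allele indices sorted); interval keys are
    ``(CHROM, POS1, POS2, TYPE, SIZE)``. Reference-equal genotypes (0/0)
    are not variants and are never stored.
    """

    accession: str
    keys: dict[str, set[tuple]] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for cls in VARIANT_CLASSES:
            self.keys.setdefault(cls, set())

    def add(self, variant_class: str, key: tuple) -> None:
        if variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {variant_class!r}")
        self.keys[variant_class].add(key)

    def counts(self) -> dict[str, int]:
        return {cls: len(s) for cls, s in self.keys.items()}


def canonical_gt(gt: str | Sequence[int]) -> str:
    """Canonical unphased genotype string: allele indices sorted, '/'-joined.

    ``"1|0"`` and ``"0/1"`` both map to ``"0/1"``. Returns ``None``-like
    empty string for missing calls.
    """
    if isinstance(gt, str):
        alleles = gt.replace("|", "/").split("/")
        if any(a in (".", "") for a in alleles):
            return ""
        idx = sorted(int(a) for a in alleles)
    else:
        if any(a is None or a < 0 for a in gt):
            return ""
        idx = sorted(int(a) for a in gt)
    return "/".join(str(a) for a in idx)


def _small_variant_class(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"


def read_vcf(path: str | Path, accession: str | None = None) -> VariantSet:
    """Read one accession's SNP/InDel calls from a (single-sample) VCF.

    Multi-allelic records are split per ALT allele; the per-ALT genotype is
    re-expressed against that allele ("0/1" het, "1/1" hom). Records with a
    missing genotype are skipped and counted; 0/0 records are dropped.
    """
    from cyvcf2 import VCF

    acc = accession or Path(path).stem.split(".")[0]
    vs = VariantSet(acc)
    vcf = VCF(str(path))
    for rec in vcf:
        gts = rec.genotypes
        if not gts:
            vs.n_skipped += 1
            continue
        alleles = [a for a in gts[0][:-1]]
        if any(a is None or a < 0 for a in alleles):
            vs.n_skipped += 1
            continue
        for i, alt in enumerate(rec.ALT or (), start=1):
            count = sum(1 for a in alleles if a == i)
            if count == 0:
                continue
            gt = "1/1" if count >= len(alleles) else "0/1"
            key = (rec.CHROM, rec.POS, rec.REF, alt, gt)
            vs.add(_small_variant_class(rec.REF, alt), key)
    if vs.n_skipped:
        logger.warning("%s: skipped %d records without usable genotype",
                       path, vs.n_skipped)
    return vs


def read_interval_table(path: str | Path, variant_class: str,
                        accession: str | None = None,
                        into: VariantSet | None = None) -> VariantSet:
    """Read CNV or SV calls from a delimited table with columns
    CHROM, POS1, POS2, TYPE and (optionally) SIZE; a missing SIZE defaults
    to the 1-based inclusive span POS2 - POS1 + 1."""
    if variant_class not in INTERVAL_CLASSES:
        raise ValueError(f"variant_class must be CNV or SV; got {variant_class!r}")
    df = read_table(path)
    df.columns = [c.upper() for c in df.columns]
    need = {"CHROM", "POS1", "POS2", "TYPE"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: interval table lacks columns {sorted(need - set(df.columns))}")
    acc = accession or Path(path).stem.split(".")[0]
    vs = into or VariantSet(acc)
    for row in df.itertuples():
        size = getattr(row, "SIZE", None)
        if size is None or (isinstance(size, float) and np.isnan(size)):
            size = int(row.POS2) - int(row.POS1) + 1
        vs.add(variant_class,
               (str(row.CHROM), int(row.POS1), int(row.POS2), str(row.TYPE), int(size)))
    return vs


def read_variant_sets(vcf_paths: Mapping[str, str | Path],
                      cnv_paths: Mapping[str, str | Path] | None = None,
                      sv_paths: Mapping[str, str | Path] | None = None,
                      ) -> dict[str, VariantSet]:
    """Read per-accession variant sets (VCF for SNP/InDel, interval tables
    for CNV/SV) and merge them under one :class:`VariantSet` per accession."""
    sets: dict[str, VariantSet] = {}
    for acc, path in vcf_paths.items():
        sets[acc] = read_vcf(path, acc)
    for cls, mapping in (("CNV", cnv_paths), ("SV", sv_paths)):
        for acc, path in (mapping or {}).items():
            base = sets.setdefault(acc, VariantSet(acc))
            read_interval_table(path, cls, acc, into=base)
    return sets


def write_vcf(records: Iterable[tuple], path: str | Path,
              sample: str = "SAMPLE") -> None:
    """Write minimal single-sample VCF 4.2 from (CHROM, POS, REF, ALT, GT)
    tuples (ALT may be a comma-joined multi-allele string)."""
    records = sorted(records, key=lambda r: (str(r[0]), int(r[1])))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = dict.fromkeys(str(r[0]) for r in records)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for chrom, pos, ref, alt, gt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def write_interval_table(records: Iterable[tuple], path: str | Path) -> None:
    """Write (CHROM, POS1, POS2, TYPE, SIZE) interval records as TSV."""
    df = pd.DataFrame(sorted(records), columns=["CHROM", "POS1", "POS2", "TYPE", "SIZE"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tabular readers / writers
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, accepting tab or comma separation."""
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep)


def read_omics_matrix(path: str | Path, meta_path: str | Path,
                      layer_tag: str = "transcript",
                      ) -> tuple[OmicsMatrix, SampleMeta]:
    """Read an abundance matrix (first column feature ids, remaining columns
    samples) together with its sample-metadata table, and validate the join.

    Samples present in only one of the two files are a hard error; the
    offenders are listed in the message.
    """
    raw = read_table(path)
    mat = raw.set_index(raw.columns[0])
    mat.index.name = "feature_id"
    matrix = OmicsMatrix(mat, layer_tag)
    meta = SampleMeta(read_table(meta_path))
    m_samples = set(matrix.sample_ids)
    d_samples = set(meta.table["sample_id"])
    only_matrix = sorted(m_samples - d_samples)
    only_meta = sorted(d_samples - m_samples)
    if only_matrix or only_meta:
        raise ValueError(
            "matrix/metadata sample mismatch: "
            f"in matrix only {only_matrix}; in metadata only {only_meta}")
    meta.table = meta.table.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    return matrix, meta


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path,
                     polarity: Mapping[str, str] | None = None) -> TraitTable:
    df = read_table(path)
    return TraitTable(df, dict(polarity or {}))


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    traits.table.to_csv(path, sep="\t", index=False)


def read_cross_design(path: str | Path) -> CrossDesign:
    return CrossDesign(read_table(path))


def write_cross_design(design: CrossDesign, path: str | Path) -> None:
    design.hybrids.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# missing values and normalization
# ---------------------------------------------------------------------------

def handle_missing(matrix: OmicsMatrix, meta: SampleMeta | None = None,
                   max_missing_frac: float = 0.5) -> OmicsMatrix:
    """Drop features exceeding the missing-value ceiling and impute the rest.

    A feature is dropped when its missing fraction exceeds
    ``max_missing_frac`` within every sample group (genotypes when metadata
    is given, the full sample set otherwise). Remaining missing values are
    imputed with half the feature's observed minimum, a conventional
    limit-of-detection stand-in for intensities below the instrument floor.
    """
    vals = matrix.values
    if meta is not None:
        groups = meta.table.groupby("genotype_id")["sample_id"].apply(list)
        frac = pd.DataFrame({g: vals[s].isna().mean(axis=1) for g, s in groups.items()})
        drop = frac.gt(max_missing_frac).all(axis=1)
    else:
        drop = vals.isna().mean(axis=1) > max_missing_frac
    if drop.any():
        logger.info("dropping %d features with >%.0f%% missing values",
                    int(drop.sum()), 100 * max_missing_frac)
    vals = vals.loc[~drop].copy()
    if vals.isna().any().any():
        fill = vals.min(axis=1) / 2.0
        vals = vals.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return OmicsMatrix(vals, matrix.layer_tag)


def rsd_filter(matrix: OmicsMatrix, qc_samples: Sequence[str],
               max_rsd: float = 0.25) -> OmicsMatrix:
    """Drop features whose relative standard deviation across QC samples
    exceeds ``max_rsd`` (default 25%)."""
    qc = matrix.values[list(qc_samples)]
    mean = qc.mean(axis=1)
    rsd = qc.std(axis=1, ddof=1) / mean.where(mean != 0, np.nan)
    keep = rsd.abs() <= max_rsd
    keep &= rsd.notna()
    logger.info("RSD filter: %d/%d features retained", int(keep.sum()), len(keep))
    return matrix.subset(features=matrix.values.index[keep])


def iqr_filter(matrix: OmicsMatrix, drop_frac: float = 0.4) -> OmicsMatrix:
    """Drop the ``drop_frac`` fraction of features with the smallest
    interquartile range (near-constant features carry little signal)."""
    if not 0 <= drop_frac < 1:
        raise ValueError("drop_frac must lie in [0, 1)")
    iqr = matrix.values.quantile(0.75, axis=1) - matrix.values.quantile(0.25, axis=1)
    n_keep = len(iqr) - int(np.floor(drop_frac * len(iqr)))
    keep = iqr.sort_values(ascending=False, kind="stable").index[:n_keep]
    keep = [f for f in matrix.feature_ids if f in set(keep)]  # original order
    return matrix.subset(features=keep)


def normalize(matrix: OmicsMatrix, sum_norm: bool = True, autoscale: bool = True,
              qc_samples: Sequence[str] | None = None,
              max_rsd: float | None = None,
              iqr_drop_frac: float | None = None) -> OmicsMatrix:
    """Filter and normalize an abundance matrix.

    Order of operations: RSD filter on QC samples (if requested), IQR
    filter, sample-wise sum normalization (each sample rescaled to the mean
    raw column total), feature-wise autoscaling (mean 0, unit variance;
    zero-variance features dropped with a log entry).
    """
    out = matrix
    if max_rsd is not None:
        if not qc_samples:
            raise ValueError("RSD filter requires qc_samples")
        out = rsd_filter(out, qc_samples, max_rsd)
    if iqr_drop_frac is not None:
        out = iqr_filter(out, iqr_drop_frac)
    vals = out.values.copy()
    if sum_norm:
        if (vals < 0).any().any():
            raise ValueError("sum normalization requires non-negative values")
        totals = vals.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"all-zero samples under sum normalization: {bad}")
        vals = vals * (totals.mean() / totals)
    if autoscale:
        sd = vals.std(axis=1, ddof=1)
        constant = sd == 0
        if constant.any():
            logger.info("autoscale: dropping %d zero-variance features",
                        int(constant.sum()))
            vals = vals.loc[~constant]
            sd = sd.loc[~constant]
        vals = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return OmicsMatrix(vals, out.layer_tag)


def genotype_means(matrix: OmicsMatrix, meta: SampleMeta,
                   by_stage: bool = False) -> pd.DataFrame:
    """Average replicate columns into genotype (or genotype x stage) means.

    Returns a features x groups DataFrame; group columns are genotype ids,
    or ``(genotype, stage)`` tuples when ``by_stage`` is set.
    """
    cols = {}
    t = meta.table
    if by_stage:
        for (g, s), grp in t.groupby(["genotype_id", "stage"]):
            cols[(g, s)] = matrix.values[list(grp["sample_id"])].mean(axis=1)
    else:
        for g, grp in t.groupby("genotype_id"):
            cols[g] = matrix.values[list(grp["sample_id"])].mean(axis=1)
    return pd.DataFrame(cols)
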