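"""File formats and core in-memory containers.

Conventions (fixed across the package):

* VCF positions are 1-based; phenotype BED-like intervals are 0-based
  half-open. Internally all variant positions are 1-based.
* Dosage counts the ALT allele (0, 1, 2; fractional allowed, NaN missing).
* "Minor allele" is determined from the pooled sample across populations,
  so MAF filters act on the pooled cohort frequency.
* Missing dosages are never imputed at I/O time; mean imputation happens
  only inside the association scan.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tqtlkit")

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
FEATURE_COLUMNS = ["id", "kind", "chrom", "tss", "start", "end", "cluster_id"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Sample-by-variant dosage matrix with variant and population metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_variants)`` with ALT-allele dosages
        in ``[0, 2]``; ``NaN`` marks missing genotypes.
    variants
        Frame with columns ``chrom, pos, id, ref, alt`` (``pos`` 1-based).
    sample_ids
        Sample identifiers, in dosage-row order.
    populations
        Population label per sample, aligned with ``sample_ids``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]
    populations: pd.Series

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant table does not match dosage columns")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id: {dup}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        self.populations = pd.Series(
            np.asarray(self.populations), index=self.sample_ids, name="population"
        )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def alt_freq(self) -> np.ndarray:
        """Pooled ALT-allele frequency per variant (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Pooled minor-allele frequency per variant, in [0, 0.5]."""
        f = self.alt_freq
        return np.minimum(f, 1.0 - f)

    def variant_index(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given variant ids (KeyError if absent)."""
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants not in dataset: {missing[:5]}")
        return idx

    def sample_subset(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Row indices for the given sample ids."""
        lookup = pd.Index(self.sample_ids)
        idx = lookup.get_indexer(list(sample_ids))
        if (idx < 0).any():
            raise KeyError("unknown sample id in subset")
        return idx


@dataclass
class PhenotypeMatrix:
    """Feature-by-sample phenotype values with feature coordinates.

    ``features`` carries one row per feature with columns
    ``id, kind, chrom, tss, start, end, cluster_id``; genes use ``tss``
    (1-based), introns use the half-open ``[start, end)`` interval and a
    ``cluster_id``. ``norm_state`` is ``"raw"`` or ``"qn"``.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    norm_state: str = "raw"
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features["id"].duplicated().any():
            raise ValueError("duplicate feature id")
        if not self.values.index.equals(pd.Index(self.features["id"])):
            self.values = self.values.loc[self.features["id"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, feature_ids: Sequence[str]) -> "PhenotypeMatrix":
        keep = self.features["id"].isin(set(feature_ids))
        return PhenotypeMatrix(
            values=self.values.loc[self.features.loc[keep, "id"]],
            features=self.features.loc[keep].reset_index(drop=True),
            norm_state=self.norm_state,
        )


@dataclass
class CovariateMatrix:
    """Samples-by-covariates numeric matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        non_numeric = self.data.columns[
            [not pd.api.types.is_numeric_dtype(t) for t in self.data.dtypes]
        ]
        if len(non_numeric):
            raise ValueError(f"non-numeric covariate columns: {list(non_numeric)}")

    def validate(self) -> "CovariateMatrix":
        """Reject constant columns (they are collinear with the intercept)."""
        for col in self.data.columns:
            if self.data[col].nunique(dropna=False) <= 1:
                raise ValueError(f"covariate column is constant: {col}")
        return self

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(sample_ids)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _opener(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_genotypes_vcf(
    path: str | Path, population_map: Mapping[str, str]
) -> GenotypeDataset:
    """Read a VCF (v4.x, GT field) into a :class:`GenotypeDataset`.

    GT ``0/0, 0/1, 1/1`` map to ALT dosages 0, 1, 2; ``./.`` to NaN.
    Multi-allelic records are skipped with a warning. Every VCF sample must
    appear in ``population_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in population_map]
    if missing:
        raise ValueError(f"samples absent from population_map: {missing[:5]}")

    rows: list[tuple] = []
    dosage_cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning(
                "skipping multi-allelic record %s:%d (%d ALT alleles)",
                rec.CHROM, rec.POS, len(rec.ALT),
            )
            continue
        dos = np.empty(len(samples))
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            dos[i] = float(sum(alleles)) if len(alleles) == 2 else np.nan
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append((rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0]))
        dosage_cols.append(dos)
    vcf.close()

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    )
    populations = pd.Series([population_map[s] for s in samples], index=samples)
    return GenotypeDataset(dosages, variants, samples, populations)


def write_genotypes_vcf(dataset: GenotypeDataset, path: str | Path) -> Path:
    """Write hard-call dosages as a VCF v4.2 with a GT field.

    Fractional dosages are rounded to the nearest hard call; NaN becomes
    ``./.``.
    """
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with _opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dataset.variants["chrom"].unique()
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"]
        fh.write("\t".join(header + list(dataset.sample_ids)) + "\n")
        for j, var in enumerate(dataset.variants.itertuples(index=False)):
            col = dataset.dosages[:, j]
            gts = [
                "./." if np.isnan(d) else gt_map[int(round(d))] for d in col
            ]
            fields = [
                str(var.chrom), str(var.pos), str(var.id), str(var.ref),
                str(var.alt), ".", "PASS", ".", "GT",
            ]
            fh.write("\t".join(fields + gts) + "\n")
    return path


# ---------------------------------------------------------------------------
# Phenotype BED-like files
# ---------------------------------------------------------------------------

def read_phenotype_bed(path: str | Path, kind: str = "gene") -> PhenotypeMatrix:
    """Read a tensor-style phenotype BED (``#chr start end id sample...``).

    Genes take their TSS as the 0-based interval start converted to a
    1-based position. Introns keep the half-open interval and parse the
    cluster id as the part of the feature id before the last ``":"``.
    """
    if kind not in ("gene", "intron"):
        raise ValueError(f"kind must be 'gene' or 'intron', got {kind!r}")
    with _opener(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header or not header.lstrip("#").strip():
            raise ValueError("missing header line")
        cols = header.lstrip("#").split("\t")
        if len(cols) < 5:
            raise ValueError("phenotype BED needs chrom/start/end/id + samples")
        sample_ids = cols[4:]
        feat_rows, value_rows, ids = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4 + len(sample_ids):
                raise ValueError(f"row width mismatch at line {lineno}")
            chrom, start, end, fid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(
                    f"inverted or empty interval at line {lineno}: {start} >= {end}"
                )
            if fid in ids:
                raise ValueError(f"duplicate feature id: {fid}")
            cluster = fid.rsplit(":", 1)[0] if kind == "intron" else ""
            feat_rows.append(
                (fid, kind, chrom, start + 1 if kind == "gene" else np.nan,
                 start, end, cluster)
            )
            value_rows.append([float(v) for v in parts[4:]])
            ids.append(fid)
    features = pd.DataFrame(feat_rows, columns=FEATURE_COLUMNS)
    values = pd.DataFrame(value_rows, index=pd.Index(ids, name="id"),
                          columns=sample_ids)
    return PhenotypeMatrix(values=values, features=features)


def write_phenotype_bed(pm: PhenotypeMatrix, path: str | Path) -> Path:
    """Write a :class:`PhenotypeMatrix` as a tensor-style phenotype BED."""
    path = Path(path)
    feats = pm.features
    with _opener(path, "wt") as fh:
        fh.write("#chr\tstart\tend\tid\t" + "\t".join(pm.sample_ids) + "\n")
        for _, f in feats.iterrows():
            if f["kind"] == "gene":
                start = int(f["tss"]) - 1
                end = int(f["tss"])
            else:
                start, end = int(f["start"]), int(f["end"])
            vals = pm.values.loc[f["id"]]
            fh.write(
                f"{f['chrom']}\t{start}\t{end}\t{f['id']}\t"
                + "\t".join(repr(float(v)) for v in vals) + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a tab-separated table with a header; coerce cells to numeric.

    Columns that fail numeric coercion are left as strings (result tables
    carry id columns); use :func:`read_covariates` for strictly numeric
    covariate input.
    """
    with _opener(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=0, index_col=index_col)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().all() or df[col].isna().all():
            if converted.notna().equals(df[col].notna()):
                df[col] = converted
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a table as TSV with full-precision floats."""
    path = Path(path)
    with _opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")
    return path


def read_covariates(path: str | Path) -> CovariateMatrix:
    """Read covariates (samples x named covariates); all cells must be numeric."""
    with _opener(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=0, index_col=0)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric covariate cell in column {col!r}, "
                f"sample {df.index[bad.to_numpy().nonzero()[0][0]]!r}"
            )
        df[col] = converted
    return CovariateMatrix(df).validate()
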