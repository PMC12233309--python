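"""Core in-memory containers for a tumour cohort.

The pipeline operates on three aligned tables: a biallelic genotype dosage
matrix (variants x samples), an expression matrix (genes x samples, TPM and
raw counts) with per-gene TSS annotation, and a clinical table with TNM
staging and right-censored survival.  All containers are thin dataclasses
around numpy arrays and pandas frames; sample order is the alignment
contract and is canonicalized (lexicographic) by :func:`align_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

VALID_DOSAGES = (0.0, 1.0, 2.0)


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical unique variant identifier ``chrom_pos_ref_alt``."""
    return f"{chrom}_{pos}_{ref}_{alt}"


@dataclass(frozen=True)
class Variant:
    """One biallelic variant.

    ``variant_id`` is derived from (chrom, pos, ref, alt) and is unique per
    site/allele pair.  Multi-allelic records must be split upstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def variant_id(self) -> str:
        return variant_id(self.chrom, self.pos, self.ref, self.alt)


def _check_dosage_values(dosage: np.ndarray) -> None:
    vals = dosage[~np.isnan(dosage)]
    if vals.size and not np.isin(vals, VALID_DOSAGES).all():
        bad = np.unique(vals[~np.isin(vals, VALID_DOSAGES)])
        raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")


@dataclass
class GenotypeMatrix:
    """Biallelic ALT-allele dosages, variants x samples.

    ``dosage`` is float with NaN for missing genotypes; hard calls are
    restricted to {0, 1, 2}.  ``gq`` and ``dp`` (same shape) are optional
    per-genotype quality and depth used by QC masking; ``dp``/``gq`` use
    NaN where the caller did not provide a value.
    """

    variants: pd.DataFrame  # index variant_id; columns chrom, pos, ref, alt, rsid
    samples: list
    dosage: np.ndarray
    gq: Optional[np.ndarray] = None
    dp: Optional[np.ndarray] = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n_v, n_s = self.dosage.shape
        if len(self.variants) != n_v:
            raise ValueError(
                f"variant table has {len(self.variants)} rows, dosage has {n_v}"
            )
        if len(self.samples) != n_s:
            raise ValueError(
                f"{len(self.samples)} samples, dosage has {n_s} columns"
            )
        if self.variants.index.has_duplicates:
            dups = self.variants.index[self.variants.index.duplicated()]
            raise ValueError(f"duplicate variant ids: {list(dups[:5])}")
        for arr_name in ("gq", "dp"):
            arr = getattr(self, arr_name)
            if arr is not None and np.asarray(arr).shape != self.dosage.shape:
                raise ValueError(f"{arr_name} shape mismatch")
        _check_dosage_values(self.dosage)

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.variants.index.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return GenotypeMatrix(
            variants=self.variants.iloc[idx].copy(),
            samples=list(self.samples),
            dosage=self.dosage[idx].copy(),
            gq=None if self.gq is None else self.gq[idx].copy(),
            dp=None if self.dp is None else self.dp[idx].copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        pos = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(
            variants=self.variants.copy(),
            samples=list(samples),
            dosage=self.dosage[:, pos].copy(),
            gq=None if self.gq is None else self.gq[:, pos].copy(),
            dp=None if self.dp is None else self.dp[:, pos].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Gene expression, genes x samples.

    ``genes`` carries one row per gene with chrom, tss (1-based), strand and
    biotype.  ``tpm`` is required; ``counts`` is optional (needed only for
    TMM normalization and the count-based gene filter).
    """

    genes: pd.DataFrame  # index gene_id; columns chrom, tss, strand, biotype
    samples: list
    tpm: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=float)
        n_g, n_s = self.tpm.shape
        if len(self.genes) != n_g:
            raise ValueError(f"gene table has {len(self.genes)} rows, tpm has {n_g}")
        if len(self.samples) != n_s:
            raise ValueError(f"{len(self.samples)} samples, tpm has {n_s} columns")
        if self.genes.index.has_duplicates:
            dups = self.genes.index[self.genes.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if (self.tpm < 0).any():
            raise ValueError("negative TPM values")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.tpm.shape:
                raise ValueError("counts shape mismatch")
            if (self.counts < 0).any():
                raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tpm.shape[1]

    def subset_genes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.genes.index.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(
            genes=self.genes.iloc[idx].copy(),
            samples=list(self.samples),
            tpm=self.tpm[idx].copy(),
            counts=None if self.counts is None else self.counts[idx].copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = [self.samples.index(s) for s in samples]
        return ExpressionMatrix(
            genes=self.genes.copy(),
            samples=list(samples),
            tpm=self.tpm[:, pos].copy(),
            counts=None if self.counts is None else self.counts[:, pos].copy(),
        )


CLINICAL_COLUMNS = ["sex", "age_group", "T", "N", "M", "time", "event"]


@dataclass
class ClinicalTable:
    """Clinical covariates and right-censored overall survival.

    One row per sample: sex in {male, female}; age_group 0 (<=50) / 1 (>50);
    tumour size T in 1..4; nodal spread N in 0..2; metastasis M in 0..1;
    time in days (> 0); event 1 = death observed, 0 = censored.
    """

    df: pd.DataFrame  # index sample id, columns CLINICAL_COLUMNS

    def __post_init__(self):
        df = self.df
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"clinical table missing columns: {missing_cols}")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        bad_sex = set(df["sex"].dropna()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
        checks = {
            "age_group": {0, 1},
            "T": {1, 2, 3, 4},
            "N": {0, 1, 2},
            "M": {0, 1},
            "event": {0, 1},
        }
        for col, allowed in checks.items():
            vals = set(df[col].dropna().astype(int))
            if not vals <= allowed:
                raise ValueError(f"invalid {col} values: {sorted(vals - allowed)}")
        times = df["time"].dropna()
        if (times <= 0).any():
            raise ValueError("survival time must be > 0")

    @property
    def samples(self) -> list:
        return list(self.df.index)

    def subset_samples(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.df.loc[list(samples)].copy())

    def incomplete_samples(self) -> list:
        """Samples with any missing clinical field (policy left to caller)."""
        return list(self.df.index[self.df[CLINICAL_COLUMNS].isna().any(axis=1)])


@dataclass
class CohortBundle:
    """Genotypes, expression and clinical restricted to one sample order."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    clinical: ClinicalTable
    dropped: dict = field(default_factory=dict)

    @property
    def samples(self) -> list:
        return list(self.genotypes.samples)

    def __post_init__(self):
        s = self.genotypes.samples
        if self.expression.samples != s or self.clinical.samples != s:
            raise ValueError("cohort bundle sample orders differ")


def align_cohort(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
) -> CohortBundle:
    """Restrict all three tables to their common samples, in canonical
    (lexicographic) order, recording what was dropped from each input."""
    sets = {
        "genotypes": set(genotypes.samples),
        "expression": set(expression.samples),
        "clinical": set(clinical.samples),
    }
    common = sets["genotypes"] & sets["expression"] & sets["clinical"]
    if not common:
        raise ValueError("no samples shared by genotypes, expression and clinical")
    order = sorted(common)
    dropped = {k: sorted(v - common) for k, v in sets.items()}
    return CohortBundle(
        genotypes=genotypes.subset_samples(order),
        expression=expression.subset_samples(order),
        clinical=clinical.subset_samples(order),
        dropped=dropped,
    )
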