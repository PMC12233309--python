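"""Variant- and genotype-level quality control.

Post-calling QC for a joint-called biallelic dosage matrix: per-genotype
masking on re-calculated genotype quality (GQ) and read depth (DP), then
variant-level removal of monomorphic sites, sites with excess genotype
missingness, and low-frequency sites.  Masking never changes the variant
count; it only sets unqualified genotypes to missing.  Upstream caller-side
filters (VQSR tranches, ExcessHet, QD) are out of scope and expected to have
been applied before the VCF reaches this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

try:  # sklearn is a light dependency; BaseEstimator gives get/set_params
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        pass

from .datatypes import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "GenotypeQC",
    "mask_low_quality_genotypes",
    "alt_allele_frequency",
    "minor_allele_frequency",
    "filter_variants",
    "mean_impute_dosage",
    "mean_impute_matrix",
    "hard_call",
]


@dataclass(frozen=True)
class QcThresholds:
    """Variant/genotype QC thresholds.

    maf_min is an exclusive retain bound: a variant is kept iff
    MAF > maf_min (sites with MAF <= 0.01 are removed by default).
    max_missing_fraction removes sites whose missing fraction exceeds it
    (`missing_direction="above"`); the opposite, literal-reading direction
    is available but discards nearly all data on real cohorts.
    """

    maf_min: float = 0.01
    max_missing_fraction: float = 0.25
    gq_min: float = 20.0
    dp_min: float = 3.0
    missing_direction: str = "above"

    def __post_init__(self):
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError(f"maf_min out of range: {self.maf_min}")
        if not (0.0 <= self.max_missing_fraction <= 1.0):
            raise ValueError(
                f"max_missing_fraction out of range: {self.max_missing_fraction}"
            )
        if self.missing_direction not in ("above", "below"):
            raise ValueError("missing_direction must be 'above' or 'below'")


def mask_low_quality_genotypes(
    g: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> GenotypeMatrix:
    """Set genotypes with GQ < gq_min or DP < dp_min to missing.

    Acts only where GQ/DP are present; a matrix without quality fields is
    returned unchanged.  The variant set is never altered.
    """
    dosage = g.dosage.copy()
    mask = np.zeros_like(dosage, dtype=bool)
    if g.gq is not None:
        with np.errstate(invalid="ignore"):
            mask |= np.nan_to_num(g.gq, nan=np.inf) < thresholds.gq_min
    if g.dp is not None:
        with np.errstate(invalid="ignore"):
            mask |= np.nan_to_num(g.dp, nan=np.inf) < thresholds.dp_min
    dosage[mask] = np.nan
    return GenotypeMatrix(
        variants=g.variants.copy(),
        samples=list(g.samples),
        dosage=dosage,
        gq=None if g.gq is None else g.gq.copy(),
        dp=None if g.dp is None else g.dp.copy(),
    )


def alt_allele_frequency(dosages: np.ndarray) -> float:
    """ALT-allele frequency over non-missing genotypes."""
    d = np.asarray(dosages, dtype=float)
    called = ~np.isnan(d)
    n = called.sum()
    if n == 0:
        raise ValueError("all genotypes missing: allele frequency undefined")
    return float(np.nansum(d) / (2.0 * n))


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Minor-allele frequency: min(f, 1 - f) of the ALT frequency."""
    f = alt_allele_frequency(dosages)
    return min(f, 1.0 - f)


def filter_variants(
    g: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple:
    """Remove monomorphic, high-missingness and low-MAF variants.

    Returns ``(filtered_matrix, exclusions)`` where exclusions is a frame
    (variant_id, reason) tagging each removed variant with the first
    triggering reason, checked in the order monomorphic -> missingness ->
    maf.  Idempotent: re-filtering the result removes nothing.
    """
    d = g.dosage
    called = ~np.isnan(d)
    n_called = called.sum(axis=1)
    alt_count = np.nansum(d, axis=1)
    miss_frac = 1.0 - n_called / d.shape[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.minimum(aaf, 1.0 - aaf)

    reasons = np.full(g.n_variants, "", dtype=object)
    mono = (alt_count == 0) | (n_called == 0)
    reasons[mono] = "monomorphic"
    if thresholds.missing_direction == "above":
        miss_bad = miss_frac > thresholds.max_missing_fraction
    else:
        miss_bad = miss_frac < thresholds.max_missing_fraction
    sel = (reasons == "") & miss_bad
    reasons[sel] = "missingness"
    sel = (reasons == "") & (maf <= thresholds.maf_min)
    reasons[sel] = "maf"

    keep = reasons == ""
    exclusions = pd.DataFrame(
        {
            "variant_id": g.variants.index[~keep],
            "reason": reasons[~keep],
        }
    ).reset_index(drop=True)
    kept = g.subset_variants(g.variants.index[keep])
    return kept, exclusions


def mean_impute_dosage(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the mean of the non-missing ones."""
    d = np.asarray(dosages, dtype=float).copy()
    miss = np.isnan(d)
    if miss.all():
        raise ValueError("all genotypes missing: cannot impute")
    d[miss] = d[~miss].mean()
    return d


def mean_impute_matrix(dosage: np.ndarray) -> np.ndarray:
    """Row-wise mean imputation of a variants x samples dosage matrix."""
    d = np.asarray(dosage, dtype=float).copy()
    if d.size == 0:
        return d
    n_called = (~np.isnan(d)).sum(axis=1)
    if (n_called == 0).any():
        raise ValueError("variant with all genotypes missing: cannot impute")
    means = np.nanmean(d, axis=1)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[0]]
    return d


def hard_call(dosages: np.ndarray) -> np.ndarray:
    """Round (possibly imputed) dosages to the nearest of {0, 1, 2}.

    NaN entries stay NaN; used for genotype-group counting and categorical
    (codominant) codings.
    """
    d = np.asarray(dosages, dtype=float)
    out = np.clip(np.round(d), 0, 2)
    return out


class GenotypeQC(BaseEstimator):
    """Genotype QC as a transformer: masking followed by variant filtering.

    Parameters mirror :class:`QcThresholds`.  ``fit`` records per-variant
    statistics and the exclusion table; ``transform`` applies both steps.
    """

    def __init__(
        self,
        maf_min: float = 0.01,
        max_missing_fraction: float = 0.25,
        gq_min: float = 20.0,
        dp_min: float = 3.0,
        missing_direction: str = "above",
    ):
        self.maf_min = maf_min
        self.max_missing_fraction = max_missing_fraction
        self.gq_min = gq_min
        self.dp_min = dp_min
        self.missing_direction = missing_direction

    def _thresholds(self) -> QcThresholds:
        return QcThresholds(
            maf_min=self.maf_min,
            max_missing_fraction=self.max_missing_fraction,
            gq_min=self.gq_min,
            dp_min=self.dp_min,
            missing_direction=self.missing_direction,
        )

    def fit(self, g: GenotypeMatrix, y=None):
        t = self._thresholds()
        masked = mask_low_quality_genotypes(g, t)
        kept, exclusions = filter_variants(masked, t)
        self.exclusions_ = exclusions
        self.n_input_ = g.n_variants
        self.n_kept_ = kept.n_variants
        self._kept = kept
        return self

    def transform(self, g: GenotypeMatrix = None) -> GenotypeMatrix:
        if not hasattr(self, "_kept"):
            raise RuntimeError("GenotypeQC is not fitted")
        if g is None:
            return self._kept
        t = self._thresholds()
        masked = mask_low_quality_genotypes(g, t)
        kept, _ = filter_variants(masked, t)
        return kept

    def fit_transform(self, g: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(g).transform()
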