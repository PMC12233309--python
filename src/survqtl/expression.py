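"""Expression normalization, gene filtering and covariate assembly.

Counts are normalized between samples by TMM (trimmed mean of M-values);
genes must clear joint TPM and count expression thresholds; the mapping
phenotype is optionally rank-based inverse-normal transformed per gene
(GTEx pipeline convention, default on).  Hidden expression structure is
captured by top principal components of the standardized expression matrix
(a PC proxy for PEER factors — the variational PEER model itself is not
implemented), and population structure by PCs of standardized dosages.
Clinical covariates are numerically encoded: sex male=1/female=0, age
dichotomized at 50 (>50 = 1), and TNM staging as integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        pass

from .datatypes import ClinicalTable, ExpressionMatrix, GenotypeMatrix
from .qc import mean_impute_matrix

__all__ = [
    "tmm_factors",
    "tmm_normalize",
    "filter_genes",
    "inverse_normal_transform",
    "latent_factors",
    "genotype_pcs",
    "assemble_covariates",
    "ExpressionPreprocessor",
]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    ok = (obs > 0) & (ref > 0)
    o, r = obs[ok], ref[ok]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # asymptotic binomial variance of M, used as inverse weight
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(v)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    ref_rule: str = "median_libsize",
) -> np.ndarray:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The default reference sample is the one whose library size (count sum)
    is closest to the median library size; ``ref_rule='upper_quartile'``
    instead picks the sample whose 75th percentile of library-scaled
    counts is closest to the mean such percentile (the edgeR convention).
    Trim fractions follow the canonical defaults: 30% on M-values, 5% on
    A-values, with inverse-variance weighting of the retained M-values.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] < 2:
        raise ValueError("TMM needs a genes x samples matrix with >= 2 samples")
    if (c < 0).any():
        raise ValueError("negative counts")
    lib = c.sum(axis=0)
    if (lib == 0).any():
        bad = np.where(lib == 0)[0]
        raise ValueError(f"sample(s) with all-zero counts at columns {bad.tolist()}")
    if ref_rule == "median_libsize":
        ref_idx = int(np.argmin(np.abs(lib - np.median(lib))))
    elif ref_rule == "upper_quartile":
        f75 = np.array(
            [np.quantile(c[:, j] / lib[j], 0.75) for j in range(c.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        raise ValueError(f"unknown ref_rule: {ref_rule}")
    factors = np.array(
        [
            _tmm_pair_factor(
                c[:, j], c[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, sum_trim,
            )
            for j in range(c.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def tmm_normalize(counts: np.ndarray, **kwargs) -> tuple:
    """TMM-normalized expression (counts per million on effective library
    sizes) plus the per-sample scaling factors.

    Returns ``(normalized, factors)``; effective library size is
    ``library_size * factor`` so a sample that is a scalar multiple of
    another normalizes to the same profile.
    """
    c = np.asarray(counts, dtype=float)
    factors = tmm_factors(c, **kwargs)
    eff_lib = c.sum(axis=0) * factors
    normalized = c / eff_lib[None, :] * 1e6
    return normalized, factors


def filter_genes(
    e: ExpressionMatrix,
    tpm_threshold: float = 0.1,
    tpm_fraction: float = 0.2,
    count_threshold: float = 6,
    count_fraction: float = 0.2,
) -> ExpressionMatrix:
    """Keep genes expressed above threshold in enough samples.

    A gene is retained iff TPM > 0.1 in at least 20% of samples AND
    counts >= 6 in at least 20% of samples (defaults).  Requires both TPM
    and counts.  Idempotent.
    """
    if e.counts is None:
        raise ValueError("gene filtering requires both tpm and counts")
    frac_tpm = (e.tpm > tpm_threshold).mean(axis=1)
    frac_cnt = (e.counts >= count_threshold).mean(axis=1)
    keep = (frac_tpm >= tpm_fraction) & (frac_cnt >= count_fraction)
    return e.subset_genes(e.genes.index[keep])


def inverse_normal_transform(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rank-based inverse-normal transform along ``axis``.

    Ranks (average for ties) are mapped through the normal quantile
    function at (rank - 0.5)/n.
    """
    x = np.asarray(values, dtype=float)

    def _int_1d(v):
        ranks = stats.rankdata(v, method="average")
        return stats.norm.ppf((ranks - 0.5) / v.size)

    return np.apply_along_axis(_int_1d, axis, x)


def _signed_svd_scores(mat: np.ndarray, k: int) -> np.ndarray:
    """Top-k right-singular-vector scores of a rows-standardized matrix.

    Returns a (k, n_samples) array with a deterministic sign convention:
    in each component the entry of largest magnitude is made positive.
    """
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    scores = vt[:k] * s[:k, None]
    for i in range(scores.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            scores[i] *= -1.0
    return scores


def _standardize_rows(mat: np.ndarray, drop_constant: bool = True) -> np.ndarray:
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not drop_constant and not keep.all():
        raise ValueError("constant rows cannot be standardized")
    z = (mat[keep] - mu[keep]) / sd[keep]
    return z


def latent_factors(expression: np.ndarray, k: int = 15) -> pd.DataFrame:
    """Top-k principal components of standardized expression (samples axis).

    A stand-in for PEER hidden factors: the components of the per-gene
    standardized matrix, scaled by their singular values.  Rows of the
    returned frame are samples, columns ``factor1..factork``; columns are
    mutually orthogonal.
    """
    x = np.asarray(expression, dtype=float)
    if k <= 0:
        raise ValueError("factor count k must be positive")
    if k >= min(x.shape):
        raise ValueError(f"k={k} must be < min(genes, samples)={min(x.shape)}")
    z = _standardize_rows(x)
    scores = _signed_svd_scores(z, k)
    return pd.DataFrame(
        scores.T, columns=[f"factor{i + 1}" for i in range(k)]
    )


def genotype_pcs(g: GenotypeMatrix, k: int = 5) -> pd.DataFrame:
    """Top-k genotype principal components (population-structure covariates).

    Dosages are mean-imputed and per-variant standardized; monomorphic
    variants drop out (zero variance).  Deterministic sign convention as in
    :func:`latent_factors`.  Rows are samples in the matrix's order.
    """
    if k <= 0:
        raise ValueError("PC count k must be positive")
    d = mean_impute_matrix(g.dosage)
    z = _standardize_rows(d)
    if z.shape[0] < k:
        raise ValueError(
            f"only {z.shape[0]} polymorphic variants; cannot compute {k} PCs"
        )
    scores = _signed_svd_scores(z, k)
    return pd.DataFrame(
        scores.T,
        index=pd.Index(g.samples, name="sample_id"),
        columns=[f"pc{i + 1}" for i in range(k)],
    )


def encode_clinical(clinical: ClinicalTable) -> pd.DataFrame:
    """Numeric clinical covariates: sex, age_group, T, N, M."""
    df = clinical.df
    incomplete = clinical.incomplete_samples()
    if incomplete:
        raise ValueError(
            f"samples with missing clinical fields: {incomplete[:10]}"
        )
    out = pd.DataFrame(index=df.index)
    out["sex"] = (df["sex"] == "male").astype(float)
    out["age_group"] = df["age_group"].astype(float)
    for col in ("T", "N", "M"):
        out[col] = df[col].astype(float)
    return out


def assemble_covariates(
    pcs: pd.DataFrame,
    factors: pd.DataFrame,
    clinical: ClinicalTable,
) -> pd.DataFrame:
    """Combine genotype PCs, expression factors and encoded clinical
    covariates into one samples x covariates frame.

    Constant (zero-variance) columns are rejected, and the assembled matrix
    must have full column rank — both are preconditions of the cis
    regression.
    """
    samples = list(clinical.df.index)
    pcs = pcs.copy()
    pcs.index = samples if len(pcs) == len(samples) else pcs.index
    factors = factors.copy()
    factors.index = samples if len(factors) == len(samples) else factors.index
    enc = encode_clinical(clinical)
    cov = pd.concat([pcs.loc[samples], factors.loc[samples], enc.loc[samples]], axis=1)
    if cov.columns.has_duplicates:
        raise ValueError("duplicate covariate column names")
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"missing values in covariates: {bad}")
    variances = cov.var(axis=0, ddof=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")
    mat = cov.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(cov)), mat]))
    if rank < mat.shape[1] + 1:
        raise ValueError("covariate matrix is rank deficient")
    return cov


class ExpressionPreprocessor(BaseEstimator):
    """Expression stage as a transformer.

    ``fit`` on an :class:`ExpressionMatrix` (with counts) applies the gene
    expression filter, TMM normalization, and computes ``n_factors`` hidden
    expression factors; ``phenotype_`` holds the mapping-ready matrix
    (inverse-normal transformed TPM by default).
    """

    def __init__(
        self,
        n_factors: int = 15,
        inverse_normal: bool = True,
        tpm_threshold: float = 0.1,
        count_threshold: float = 6,
        min_fraction: float = 0.2,
    ):
        self.n_factors = n_factors
        self.inverse_normal = inverse_normal
        self.tpm_threshold = tpm_threshold
        self.count_threshold = count_threshold
        self.min_fraction = min_fraction

    def fit(self, e: ExpressionMatrix, y=None):
        kept = filter_genes(
            e,
            tpm_threshold=self.tpm_threshold,
            tpm_fraction=self.min_fraction,
            count_threshold=self.count_threshold,
            count_fraction=self.min_fraction,
        )
        normalized, factors_tmm = tmm_normalize(kept.counts)
        pheno = np.log2(normalized + 1.0)
        if self.inverse_normal:
            pheno = inverse_normal_transform(pheno, axis=1)
        self.expression_ = kept
        self.tmm_factors_ = factors_tmm
        self.phenotype_ = pd.DataFrame(
            pheno, index=kept.genes.index, columns=kept.samples
        )
        self.factors_ = latent_factors(pheno, k=self.n_factors)
        self.factors_.index = pd.Index(kept.samples, name="sample_id")
        return self

    def transform(self, e: ExpressionMatrix = None) -> pd.DataFrame:
        if not hasattr(self, "phenotype_"):
            raise RuntimeError("ExpressionPreprocessor is not fitted")
        return self.phenotype_

    def fit_transform(self, e: ExpressionMatrix, y=None) -> pd.DataFrame:
        return self.fit(e).transform()
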