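"""Dual-level Cox survival screening of eGenes and eQTLs.

Genes are tested with their expression (TPM) as a continuous covariate;
variants under two inheritance codings — allelic (ALT-dosage as a numeric
covariate, one hazard ratio per allele copy) and codominant (het and
hom-ALT each against the reference genotype, two hazard ratios) — each
unadjusted and adjusted for staging covariates (T, N, M by default; a
validation cohort missing N/M adjusts for T only).  Variants with fewer
than three carriers in both the het and hom-ALT categories are excluded.

Negative log-hazard coefficients (HR < 1) are favourable: higher
expression / more ALT alleles associate with better survival.  Extreme
hazard ratios (HR > 50 or < 1/50, or CI ratio > 100) are sanitized to NA;
monotone-likelihood fits (all carriers of a genotype sharing one outcome)
are flagged and their HRs withheld.  BH correction is applied within each
family (level x inheritance x term x adjustment) separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        pass

from .coxph import cox_fit
from .eqtl import bh_qvalues
from .qc import hard_call

__all__ = [
    "RECORD_COLUMNS",
    "fit_cox",
    "gene_survival",
    "variant_survival",
    "sanitize_hr",
    "multiple_testing",
    "PrognosticSets",
    "build_prognostic_sets",
    "SurvivalScreen",
]

RECORD_COLUMNS = [
    "entity", "level", "inheritance", "term", "adjusted",
    "n", "n_events", "coef", "se", "hr", "ci_low", "ci_high", "p",
    "het_count", "homalt_count", "monotone", "sanitized",
]

DEFAULT_ADJUST = ("T", "N", "M")


def fit_cox(
    time,
    event,
    primary: np.ndarray,
    primary_names: Sequence[str],
    adjustment: Optional[np.ndarray] = None,
) -> list:
    """Fit one Cox model and report records for the primary covariate(s).

    ``primary`` is (n,) or (n, p_primary); ``adjustment`` optional extra
    columns whose coefficients are not reported.  Monotone-likelihood fits
    are flagged and their HR/CI withheld.
    """
    x = np.asarray(primary, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    design = x if adjustment is None else np.column_stack([x, adjustment])
    fit = cox_fit(time, event, design)
    lo, hi = fit.confidence_interval()
    records = []
    for j, name in enumerate(primary_names):
        monotone = bool(fit.monotone)
        records.append(
            {
                "term": name,
                "n": fit.n,
                "n_events": fit.n_events,
                "coef": float(fit.coef[j]),
                "se": float(fit.se[j]),
                "hr": np.nan if monotone else float(np.exp(fit.coef[j])),
                "ci_low": np.nan if monotone else float(lo[j]),
                "ci_high": np.nan if monotone else float(hi[j]),
                "p": float(fit.wald_p[j]),
                "monotone": monotone,
                "sanitized": monotone,
            }
        )
    return records


def _adjustment_matrix(clinical: pd.DataFrame, adjust_cols) -> np.ndarray:
    return clinical[list(adjust_cols)].to_numpy(dtype=float)


def gene_survival(
    expression,
    clinical: pd.DataFrame,
    entity: str,
    adjusted: bool = False,
    adjust_cols: Sequence[str] = DEFAULT_ADJUST,
) -> dict:
    """Cox record for one gene's continuous expression."""
    x = np.asarray(expression, dtype=float)
    adj = _adjustment_matrix(clinical, adjust_cols) if adjusted else None
    rec = fit_cox(
        clinical["time"].to_numpy(),
        clinical["event"].to_numpy(),
        x,
        ["expression"],
        adjustment=adj,
    )[0]
    rec.update(
        entity=entity, level="gene", inheritance="none", term="expression",
        adjusted=adjusted, het_count=np.nan, homalt_count=np.nan,
    )
    return sanitize_hr(rec)


def genotype_counts(dosages) -> tuple:
    """(het, homalt) counts from hard-called, non-missing genotypes."""
    calls = hard_call(np.asarray(dosages, dtype=float))
    calls = calls[~np.isnan(calls)]
    return int((calls == 1).sum()), int((calls == 2).sum())


def variant_survival(
    dosages,
    clinical: pd.DataFrame,
    entity: str,
    inheritance: str = "allelic",
    adjusted: bool = False,
    adjust_cols: Sequence[str] = DEFAULT_ADJUST,
    min_group: int = 3,
) -> tuple:
    """Cox record(s) for one variant under the given inheritance coding.

    Samples with missing genotype are dropped for this variant.  Returns
    ``(records, exclusion_reason)``; a variant failing the genotype-count
    filter (fewer than ``min_group`` in BOTH het and hom-ALT groups) or
    with a degenerate design yields ``([], reason)``.
    """
    calls = hard_call(np.asarray(dosages, dtype=float))
    ok = ~np.isnan(calls)
    calls = calls[ok]
    clin = clinical.loc[np.asarray(ok)]
    het = int((calls == 1).sum())
    homalt = int((calls == 2).sum())
    if het < min_group and homalt < min_group:
        return [], f"fewer than {min_group} samples in both het and hom-ALT groups"

    time = clin["time"].to_numpy()
    event = clin["event"].to_numpy()
    adj = _adjustment_matrix(clin, adjust_cols) if adjusted else None

    if inheritance == "allelic":
        primary = calls[:, None]
        names = ["dosage"]
    elif inheritance == "codominant":
        cols, names = [], []
        if het > 0:
            cols.append((calls == 1).astype(float))
            names.append("het")
        if homalt > 0:
            cols.append((calls == 2).astype(float))
            names.append("hom")
        if not cols:
            return [], "no ALT carriers"
        primary = np.column_stack(cols)
    else:
        raise ValueError(f"unknown inheritance model: {inheritance}")

    try:
        records = fit_cox(time, event, primary, names, adjustment=adj)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return [], f"degenerate design: {exc}"
    for rec in records:
        rec.update(
            entity=entity, level="variant", inheritance=inheritance,
            adjusted=adjusted, het_count=het, homalt_count=homalt,
        )
        sanitize_hr(rec)
    return records, None


def sanitize_hr(
    record: dict, hr_max: float = 50.0, ci_ratio_max: float = 100.0,
    symmetric: bool = True,
) -> dict:
    """Withhold unstable hazard ratios (in place; idempotent).

    HR and CI become NA when HR > 50 (or, symmetrically, < 1/50) or when
    the CI ratio ci_high/ci_low exceeds 100.  The coefficient and p-value
    are retained untouched.
    """
    hr = record.get("hr", np.nan)
    lo, hi = record.get("ci_low", np.nan), record.get("ci_high", np.nan)
    extreme = False
    if np.isfinite(hr):
        extreme |= hr > hr_max
        if symmetric:
            extreme |= hr < 1.0 / hr_max
    if np.isfinite(lo) and np.isfinite(hi) and lo > 0:
        extreme |= hi / lo > ci_ratio_max
    if extreme:
        record["hr"] = np.nan
        record["ci_low"] = np.nan
        record["ci_high"] = np.nan
        record["sanitized"] = True
    else:
        record.setdefault("sanitized", False)
    return record


def multiple_testing(
    records: pd.DataFrame,
    family_cols: Sequence[str] = ("level", "inheritance", "term", "adjusted"),
) -> pd.DataFrame:
    """BH q-values computed within each testing family separately.

    Gene-level and variant-level tests are never pooled, nor are different
    inheritance codings or adjustment states.
    """
    out = records.copy()
    out["fdr"] = np.nan
    for _, idx in out.groupby(list(family_cols), dropna=False).groups.items():
        p = out.loc[idx, "p"].to_numpy(dtype=float)
        finite = np.isfinite(p)
        if finite.any():
            q = np.full(p.shape, np.nan)
            q[finite] = bh_qvalues(p[finite])
            out.loc[idx, "fdr"] = q
    return out


@dataclass
class PrognosticSets:
    """Gene-level prognostic sets at an exploratory p threshold."""

    unadjusted: set
    adjusted: set
    union: set
    favourable: set
    unfavourable: set
    conflicts: set = field(default_factory=set)
    directions: dict = field(default_factory=dict)


def build_prognostic_sets(
    gene_records: pd.DataFrame, p_threshold: float = 0.05
) -> PrognosticSets:
    """Union of genes significant in the unadjusted and/or adjusted Cox
    models, each labeled favourable (coef < 0) or unfavourable (coef > 0)
    from the model(s) in which it was significant.

    A gene significant in both models with opposite coefficient signs is
    recorded in ``conflicts`` (and in neither direction set).
    """
    recs = gene_records[gene_records["level"] == "gene"]
    sig = recs[recs["p"] < p_threshold]
    set_a = set(sig.loc[~sig["adjusted"].astype(bool), "entity"])
    set_b = set(sig.loc[sig["adjusted"].astype(bool), "entity"])
    union = set_a | set_b
    favourable, unfavourable, conflicts = set(), set(), set()
    directions = {}
    for gene in union:
        coefs = sig.loc[sig["entity"] == gene, "coef"].to_numpy(dtype=float)
        if (coefs == 0).any():
            raise ValueError(f"gene {gene}: zero coefficient, direction undefined")
        signs = set(np.sign(coefs))
        if len(signs) > 1:
            conflicts.add(gene)
            continue
        if signs == {-1.0}:
            favourable.add(gene)
            directions[gene] = "favourable"
        else:
            unfavourable.add(gene)
            directions[gene] = "unfavourable"
    return PrognosticSets(
        unadjusted=set_a,
        adjusted=set_b,
        union=union,
        favourable=favourable,
        unfavourable=unfavourable,
        conflicts=conflicts,
        directions=directions,
    )


class SurvivalScreen(BaseEstimator):
    """Gene- and variant-level Cox screening as a fit-style estimator.

    ``fit(tpm, dosage, clinical)`` runs, for every gene row of ``tpm``,
    unadjusted and adjusted gene-level models, and for every variant row
    of ``dosage`` the allelic and codominant codings (both adjustment
    states).

    Fitted attributes
    -----------------
    gene_records_, variant_records_ : record frames with family-wise FDR
    prognostic_sets_ : :class:`PrognosticSets` at ``p_threshold``
    exclusions_ : variants excluded by the genotype-count filter
    """

    def __init__(
        self,
        adjust_cols: Sequence[str] = DEFAULT_ADJUST,
        min_group: int = 3,
        p_threshold: float = 0.05,
        fdr: float = 0.05,
    ):
        self.adjust_cols = adjust_cols
        self.min_group = min_group
        self.p_threshold = p_threshold
        self.fdr = fdr

    def fit(
        self,
        tpm: Optional[pd.DataFrame],
        dosage: Optional[pd.DataFrame],
        clinical: pd.DataFrame,
    ):
        gene_rows, var_rows, exclusions = [], [], []
        if tpm is not None:
            for gene_id, row in tpm.iterrows():
                for adjusted in (False, True):
                    gene_rows.append(
                        gene_survival(
                            row.to_numpy(), clinical, gene_id,
                            adjusted=adjusted, adjust_cols=self.adjust_cols,
                        )
                    )
        if dosage is not None:
            for variant_id, row in dosage.iterrows():
                d = row.to_numpy()
                for inheritance in ("allelic", "codominant"):
                    for adjusted in (False, True):
                        recs, reason = variant_survival(
                            d, clinical, variant_id,
                            inheritance=inheritance, adjusted=adjusted,
                            adjust_cols=self.adjust_cols,
                            min_group=self.min_group,
                        )
                        if reason is not None:
                            exclusions.append(
                                {
                                    "entity": variant_id,
                                    "inheritance": inheritance,
                                    "adjusted": adjusted,
                                    "reason": reason,
                                }
                            )
                        var_rows.extend(recs)
        self.gene_records_ = (
            multiple_testing(pd.DataFrame(gene_rows, columns=RECORD_COLUMNS))
            if gene_rows
            else pd.DataFrame(columns=RECORD_COLUMNS + ["fdr"])
        )
        self.variant_records_ = (
            multiple_testing(pd.DataFrame(var_rows, columns=RECORD_COLUMNS))
            if var_rows
            else pd.DataFrame(columns=RECORD_COLUMNS + ["fdr"])
        )
        self.exclusions_ = pd.DataFrame(
            exclusions, columns=["entity", "inheritance", "adjusted", "reason"]
        )
        self.prognostic_sets_ = (
            build_prognostic_sets(self.gene_records_, self.p_threshold)
            if gene_rows
            else PrognosticSets(set(), set(), set(), set(), set())
        )
        return self
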