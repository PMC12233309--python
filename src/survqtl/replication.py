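"""Prognostic-direction consistency of eGene-eQTL pairs and cross-cohort
replication tiers.

The consistency hypothesis: a variant that raises the expression of a
favourable gene (positive eQTL slope) should itself be favourable for
survival, and one that lowers it should be unfavourable — the predicted
variant direction is the product of the gene's prognostic direction and
the slope sign.  A pair is consistent when the observed variant-level Cox
direction matches the prediction.

Replication against a second cohort is two-tiered, compared pairwise per
Cox model (same inheritance coding and adjustment state): strict requires
validation significance (p < 0.05) plus sign agreement in at least one of
the discovery-significant models; lenient requires sign agreement only;
otherwise discordant.  Replicated variants are clumped into loci by
in-cohort LD (single-linkage on dosage r^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        pass

from .datatypes import GenotypeMatrix
from .survival_screen import PrognosticSets

__all__ = [
    "ConsistencyPair",
    "variant_direction_from_records",
    "classify_pair",
    "enumerate_consistent",
    "match_variants",
    "classify_tier",
    "ld_r2",
    "cluster_loci",
    "ReplicationAnalysis",
]

_DIR_SIGN = {"favourable": -1.0, "unfavourable": 1.0}  # sign of the Cox coef


@dataclass
class ConsistencyPair:
    gene: str
    variant: str
    slope: float
    gene_direction: str
    variant_direction: str
    satisfied_models: tuple
    consistent: bool
    direction_conflict: bool = False


def _model_key(rec) -> str:
    """Canonical model label, e.g. 'allelic', 'allelic_adj', 'codominant'."""
    base = str(rec["inheritance"])
    return base + ("_adj" if bool(rec["adjusted"]) else "")


def variant_direction_from_records(
    records: pd.DataFrame, p_threshold: float = 0.05
) -> tuple:
    """Observed prognostic direction of a variant from its significant Cox
    fits.

    For a codominant fit the hom-ALT coefficient is used when present,
    else the het coefficient.  Returns ``(direction, satisfied_models,
    conflict)`` where satisfied_models lists the model labels reaching
    p < threshold and conflict marks disagreement among them.
    """
    sig_models = []
    signs = []
    for (inheritance, adjusted), grp in records.groupby(
        ["inheritance", "adjusted"], sort=False
    ):
        sig = grp[grp["p"] < p_threshold]
        if sig.empty:
            continue
        label = str(inheritance) + ("_adj" if bool(adjusted) else "")
        sig_models.append(label)
        if inheritance == "codominant":
            hom = sig[sig["term"] == "hom"]
            chosen = hom if not hom.empty else sig[sig["term"] == "het"]
        else:
            chosen = sig
        coef = chosen["coef"].to_numpy(dtype=float)
        if (coef == 0).any():
            raise ValueError("zero Cox coefficient: direction undefined")
        signs.extend(np.sign(coef).tolist())
    if not sig_models:
        return None, (), False
    uniq = set(signs)
    conflict = len(uniq) > 1
    if conflict:
        direction = None
    else:
        direction = "favourable" if uniq == {-1.0} else "unfavourable"
    return direction, tuple(sig_models), conflict


def classify_pair(
    gene_direction: str,
    slope: float,
    variant_direction: str,
    satisfied_models: tuple = (),
    gene: str = "",
    variant: str = "",
    direction_conflict: bool = False,
) -> ConsistencyPair:
    """Consistency verdict for one eGene-eQTL pair.

    Predicted variant direction = gene direction flipped iff the eQTL
    slope is negative; consistent iff it equals the observed variant
    direction.  A zero slope or coefficient has no direction and raises.
    """
    if slope == 0:
        raise ValueError("zero eQTL slope: direction undefined")
    for d in (gene_direction, variant_direction):
        if d not in _DIR_SIGN:
            raise ValueError(f"unknown direction label: {d!r}")
    predicted_sign = _DIR_SIGN[gene_direction] * np.sign(slope)
    observed_sign = _DIR_SIGN[variant_direction]
    consistent = bool(predicted_sign == observed_sign) and not direction_conflict
    return ConsistencyPair(
        gene=gene,
        variant=variant,
        slope=float(slope),
        gene_direction=gene_direction,
        variant_direction=variant_direction,
        satisfied_models=tuple(satisfied_models),
        consistent=consistent,
        direction_conflict=direction_conflict,
    )


def enumerate_consistent(
    prognostic: PrognosticSets,
    significant_pairs: pd.DataFrame,
    variant_records: pd.DataFrame,
    p_threshold: float = 0.05,
) -> tuple:
    """Evaluate every candidate eGene-eQTL pair for prognostic consistency.

    Candidates are significant eQTL pairs whose gene is in the prognostic
    union set (with an unambiguous direction) and whose variant reaches
    p < threshold in at least one Cox model (variants already excluded by
    the genotype-count filter have no records and drop out here).

    Returns ``(pairs_frame, summary)`` with counts of distinct consistent
    genes, eQTLs and pairs.
    """
    rows = []
    sig = significant_pairs[significant_pairs.get("significant", True) == True]  # noqa: E712
    recs_by_variant = dict(tuple(variant_records.groupby("entity", sort=False)))
    for _, pair in sig.iterrows():
        gene = pair["gene_id"]
        variant = pair["variant_id"]
        gene_dir = prognostic.directions.get(gene)
        if gene_dir is None:
            continue
        recs = recs_by_variant.get(variant)
        if recs is None:
            continue
        v_dir, models, conflict = variant_direction_from_records(recs, p_threshold)
        if not models:
            continue
        if v_dir is None:  # conflicting directions among significant models
            rows.append(
                ConsistencyPair(
                    gene=gene, variant=variant, slope=float(pair["slope"]),
                    gene_direction=gene_dir, variant_direction="conflict",
                    satisfied_models=models, consistent=False,
                    direction_conflict=True,
                ).__dict__
            )
            continue
        cp = classify_pair(
            gene_dir, float(pair["slope"]), v_dir, models,
            gene=gene, variant=variant,
        )
        rows.append(cp.__dict__)
    pairs = pd.DataFrame(
        rows,
        columns=[
            "gene", "variant", "slope", "gene_direction",
            "variant_direction", "satisfied_models", "consistent",
            "direction_conflict",
        ],
    )
    consistent = pairs[pairs["consistent"].astype(bool)]
    summary = {
        "n_pairs_evaluated": int(len(pairs)),
        "n_consistent_pairs": int(len(consistent)),
        "n_consistent_genes": int(consistent["gene"].nunique()),
        "n_consistent_eqtls": int(consistent["variant"].nunique()),
    }
    return pairs, summary


def match_variants(
    discovery_variants: pd.DataFrame, validation: GenotypeMatrix
) -> pd.DataFrame:
    """Match discovery variants into a validation cohort by coordinates
    and alleles.

    Exact (chrom, pos, ref, alt) matches pass through; allele-swapped
    records (ref/alt exchanged) are harmonized by flipping the validation
    dosage (2 - d) and flagged.  Returns one row per discovery variant
    with matched (bool), validation_id and flipped.
    """
    val = validation.variants
    exact = {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"]): vid
        for vid, r in val.iterrows()
    }
    rows = []
    for vid, r in discovery_variants.iterrows():
        key = (r["chrom"], int(r["pos"]), r["ref"], r["alt"])
        swap = (r["chrom"], int(r["pos"]), r["alt"], r["ref"])
        if key in exact:
            rows.append(
                {"variant_id": vid, "matched": True,
                 "validation_id": exact[key], "flipped": False}
            )
        elif swap in exact:
            rows.append(
                {"variant_id": vid, "matched": True,
                 "validation_id": exact[swap], "flipped": True}
            )
        else:
            rows.append(
                {"variant_id": vid, "matched": False,
                 "validation_id": None, "flipped": False}
            )
    return pd.DataFrame(
        rows, columns=["variant_id", "matched", "validation_id", "flipped"]
    ).set_index("variant_id")


def harmonized_dosage(validation: GenotypeMatrix, validation_id: str, flipped: bool):
    d = validation.dosage[validation.variants.index.get_loc(validation_id)]
    return 2.0 - d if flipped else d


def classify_tier(
    discovery_records: pd.DataFrame,
    validation_records: Optional[pd.DataFrame],
    p_threshold: float = 0.05,
) -> str:
    """Replication tier of one matched pair, compared per Cox model.

    Only models significant in discovery are compared, each against the
    same model (inheritance x adjustment) in validation.  strict: some
    compared model is validation-significant with agreeing coefficient
    sign; lenient: signs agree somewhere but nothing reaches significance;
    discordant: no sign agreement; unmatched: no validation records.
    """
    if validation_records is None or validation_records.empty:
        return "unmatched"
    disc_sig = discovery_records[discovery_records["p"] < p_threshold]
    if disc_sig.empty:
        return "unmatched"
    any_agree = False
    for _, drec in disc_sig.iterrows():
        vmatch = validation_records[
            (validation_records["inheritance"] == drec["inheritance"])
            & (validation_records["adjusted"] == drec["adjusted"])
            & (validation_records["term"] == drec["term"])
        ]
        for _, vrec in vmatch.iterrows():
            if np.sign(vrec["coef"]) == np.sign(drec["coef"]):
                any_agree = True
                if vrec["p"] < p_threshold:
                    return "strict"
    return "lenient" if any_agree else "discordant"


def ld_r2(dosages_a, dosages_b, min_samples: int = 5) -> float:
    """Squared Pearson correlation of two dosage vectors over their
    jointly non-missing samples."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < min_samples:
        raise ValueError(f"fewer than {min_samples} jointly called samples")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero dosage variance: r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def cluster_loci(
    dosage: pd.DataFrame, r2_threshold: float = 0.1, min_samples: int = 5
) -> list:
    """Single-linkage clustering of variants into loci by LD.

    Variants are joined when pairwise r^2 >= threshold; loci are the
    connected components.  ``dosage`` is variants x samples (NaN missing).
    Returns a list of lists of variant ids; the locus count is the number
    of independent genomic signals.
    """
    ids = list(dosage.index)
    n = len(ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    mat = dosage.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r2 = ld_r2(mat[i], mat[j], min_samples=min_samples)
            except ValueError:
                continue
            if r2 >= r2_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return sorted(groups.values(), key=lambda grp: ids.index(grp[0]))


class ReplicationAnalysis(BaseEstimator):
    """Consistency + replication as a fit-style estimator.

    ``fit`` consumes the discovery cohort's prognostic sets, significant
    eQTL pairs and variant Cox records, plus the validation cohort's
    variant records keyed by the discovery variant id (already matched and
    harmonized).  Produces ``consistent_pairs_``, ``tiers_`` and locus
    clusters for strictly replicated variants when validation dosages are
    supplied.
    """

    def __init__(self, p_threshold: float = 0.05, r2_threshold: float = 0.1):
        self.p_threshold = p_threshold
        self.r2_threshold = r2_threshold

    def fit(
        self,
        prognostic: PrognosticSets,
        significant_pairs: pd.DataFrame,
        variant_records: pd.DataFrame,
        validation_records: Optional[pd.DataFrame] = None,
        validation_dosage: Optional[pd.DataFrame] = None,
    ):
        pairs, summary = enumerate_consistent(
            prognostic, significant_pairs, variant_records, self.p_threshold
        )
        self.consistent_pairs_ = pairs
        self.summary_ = summary

        tiers = []
        if validation_records is not None:
            val_by_variant = dict(
                tuple(validation_records.groupby("entity", sort=False))
            )
            disc_by_variant = dict(
                tuple(variant_records.groupby("entity", sort=False))
            )
            for variant in pairs.loc[pairs["consistent"].astype(bool), "variant"].unique():
                tier = classify_tier(
                    disc_by_variant[variant],
                    val_by_variant.get(variant),
                    self.p_threshold,
                )
                tiers.append({"variant": variant, "tier": tier})
        self.tiers_ = pd.DataFrame(tiers, columns=["variant", "tier"])

        self.loci_ = None
        if validation_dosage is not None and not self.tiers_.empty:
            strict = self.tiers_.loc[self.tiers_["tier"] == "strict", "variant"]
            present = [v for v in strict if v in validation_dosage.index]
            if present:
                self.loci_ = cluster_loci(
                    validation_dosage.loc[present], self.r2_threshold
                )
        return self
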