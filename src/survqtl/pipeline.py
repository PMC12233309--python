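"""End-to-end orchestration: synthetic twin cohorts through QC, cis-eQTL
mapping, dual-level survival screening, consistency classification and
cross-cohort replication, with every stage table written as TSV.

Re-running with the same config reproduces byte-identical tables; each
stage's outputs are plain frames so any single stage can also be invoked
directly from the library.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortBundle
from .eqtl import CisEqtlMapper, sensitivity_screen
from .expression import ExpressionPreprocessor, assemble_covariates, genotype_pcs
from .km import optimal_cutoff_scan
from .qc import GenotypeQC, mean_impute_matrix
from .replication import ReplicationAnalysis, harmonized_dosage, match_variants
from .simulate import PlantedEqtl, PlantedSurvival, SimulationConfig, make_paired_cohorts
from .survival_screen import SurvivalScreen

logger = logging.getLogger("survqtl")

__all__ = ["run_pipeline", "config_from_mapping", "analyze_cohort"]

STAGE_FILES = {
    "qc_exclusions": "qc_exclusions.tsv",
    "covariates": "covariates.tsv",
    "eqtl_pairs": "eqtl_pairs.tsv",
    "egenes": "egenes.tsv",
    "significant_pairs": "significant_pairs.tsv",
    "sensitivity": "sensitivity.tsv",
    "survival_genes": "survival_genes.tsv",
    "survival_variants": "survival_variants.tsv",
    "km_cutoffs": "km_cutoffs.tsv",
    "consistency_pairs": "consistency_pairs.tsv",
    "replication": "replication.tsv",
    "summary": "summary.json",
}


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat mapping (parsed YAML or
    JSON).  Planted effects may be given as lists of [gene, value] or
    [gene, value, cohort_b_fate]."""
    m = dict(mapping)
    eqtls = [
        PlantedEqtl(*row) if not isinstance(row, PlantedEqtl) else row
        for row in m.pop("planted_eqtls", [])
    ]
    surv = [
        PlantedSurvival(*row) if not isinstance(row, PlantedSurvival) else row
        for row in m.pop("planted_survival", [])
    ]
    for key in ("maf_range", "planted_maf_range"):
        if key in m:
            m[key] = tuple(m[key])
    return SimulationConfig(planted_eqtls=eqtls, planted_survival=surv, **m)


def analyze_cohort(
    bundle: CohortBundle,
    n_factors: int = 15,
    n_pcs: int = 5,
    min_perm: int = 1000,
    max_perm: int = 10000,
    fdr: float = 0.05,
    seed: int = 0,
    adjust_cols=("T", "N", "M"),
    scan_km: bool = False,
) -> dict:
    """Discovery-phase analysis of one aligned cohort.

    QC -> expression prep -> covariates -> cis mapping with permutations
    -> sensitivity screen of eGene top pairs -> gene-level Cox on eGenes
    and variant-level Cox on significant eQTLs -> consistency inputs.
    Returns a dict of stage tables and fitted estimators.
    """
    logger.info("stage qc: %d variants in", bundle.genotypes.n_variants)
    qc = GenotypeQC().fit(bundle.genotypes)
    geno = qc.transform()
    logger.info("stage qc: %d variants kept", geno.n_variants)

    prep = ExpressionPreprocessor(n_factors=n_factors).fit(bundle.expression)
    phenotype = prep.phenotype_
    pcs = genotype_pcs(geno, k=n_pcs)
    covariates = assemble_covariates(pcs, prep.factors_, bundle.clinical)

    dosage_imp = pd.DataFrame(
        mean_impute_matrix(geno.dosage),
        index=geno.variants.index,
        columns=geno.samples,
    )
    mapper = CisEqtlMapper(
        min_perm=min_perm, max_perm=max_perm, fdr=fdr, seed=seed
    ).fit(
        phenotype,
        dosage_imp,
        prep.expression_.genes,
        geno.variants,
        covariates,
    )
    logger.info(
        "stage eqtl: %d pairs tested, %d eGenes, %d significant pairs",
        mapper.pair_summary_["n_pairs_tested"],
        len(mapper.egenes_),
        mapper.pair_summary_["n_significant_pairs"],
    )

    # sensitivity screen of each eGene's top association (raw dosage calls)
    sens_rows = []
    raw_dosage = geno.dosage
    vindex = geno.variants.index
    egene_results = mapper.gene_results_[mapper.gene_results_["is_egene"]]
    passing_egenes = []
    for _, row in egene_results.iterrows():
        g_i = phenotype.index.get_loc(row["gene_id"])
        v_i = vindex.get_loc(row["top_variant"])
        res = sensitivity_screen(
            phenotype.to_numpy()[g_i], raw_dosage[v_i]
        )
        res.update(gene_id=row["gene_id"], variant_id=row["top_variant"])
        sens_rows.append(res)
        if res["passed"]:
            passing_egenes.append(row["gene_id"])
    sensitivity = pd.DataFrame(
        sens_rows,
        columns=[
            "gene_id", "variant_id", "p_additive", "p_dominant",
            "p_recessive", "het_count", "homalt_count", "passed",
        ],
    )

    sig_pairs = mapper.significant_pairs_
    sig_only = sig_pairs[sig_pairs["significant"]]
    egene_set = [g for g in mapper.egenes_]
    sig_variants = sig_only["variant_id"].unique().tolist()

    tpm_kept = pd.DataFrame(
        prep.expression_.tpm,
        index=prep.expression_.genes.index,
        columns=prep.expression_.samples,
    )
    # gene-level Cox uses the same normalized expression the mapping used;
    # KM cutoff scans below stay on the TPM scale
    screen = SurvivalScreen(adjust_cols=adjust_cols).fit(
        phenotype.loc[[g for g in egene_set if g in phenotype.index]],
        dosage_imp.loc[[v for v in sig_variants if v in dosage_imp.index]],
        bundle.clinical.df,
    )
    logger.info(
        "stage survival: %d gene records, %d variant records",
        len(screen.gene_records_), len(screen.variant_records_),
    )

    km_rows = []
    if scan_km:
        for gene in sorted(screen.prognostic_sets_.union):
            scan = optimal_cutoff_scan(
                tpm_kept.loc[gene].to_numpy(),
                bundle.clinical.df["time"].to_numpy(),
                bundle.clinical.df["event"].to_numpy(),
            )
            km_rows.append(
                {
                    "gene_id": gene,
                    "selected_cutoff": scan.selected_cutoff,
                    "selected_p": scan.selected_p,
                    "n_candidates": len(scan.cutoffs),
                }
            )
    km_cutoffs = pd.DataFrame(
        km_rows, columns=["gene_id", "selected_cutoff", "selected_p", "n_candidates"]
    )

    return {
        "qc": qc,
        "genotypes": geno,
        "prep": prep,
        "phenotype": phenotype,
        "covariates": covariates,
        "dosage": dosage_imp,
        "mapper": mapper,
        "sensitivity": sensitivity,
        "passing_egenes": passing_egenes,
        "screen": screen,
        "km_cutoffs": km_cutoffs,
        "tpm": tpm_kept,
    }


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / STAGE_FILES[name], sep="\t", index=False)


def run_pipeline(
    cfg: SimulationConfig,
    outdir,
    min_perm: int = 1000,
    max_perm: int = 10000,
    n_factors: int = 15,
    n_pcs: int = 5,
    scan_km: bool = False,
    validation_adjust=("T",),
) -> dict:
    """Run the whole twin-cohort workflow from a simulation config.

    Stage order: simulate -> qc -> prep -> eqtl -> sensitivity -> survival
    -> (optional KM scans) -> consistency -> replication -> summary.
    All stage tables land in ``outdir``; the returned dict carries them
    in memory together with the replication analysis.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("simulating twin cohorts (seed %d)", cfg.seed)
    bundle_a, truth_a, bundle_b, truth_b = make_paired_cohorts(cfg)

    disc = analyze_cohort(
        bundle_a,
        n_factors=n_factors,
        n_pcs=n_pcs,
        min_perm=min_perm,
        max_perm=max_perm,
        seed=cfg.seed,
        scan_km=scan_km,
    )

    _write(disc["qc"].exclusions_, outdir, "qc_exclusions")
    disc["covariates"].rename_axis("sample_id").reset_index().to_csv(
        outdir / STAGE_FILES["covariates"], sep="\t", index=False
    )
    _write(disc["mapper"].pairs_, outdir, "eqtl_pairs")
    _write(disc["mapper"].gene_results_, outdir, "egenes")
    _write(
        disc["mapper"].significant_pairs_[
            disc["mapper"].significant_pairs_["significant"]
        ],
        outdir,
        "significant_pairs",
    )
    _write(disc["sensitivity"], outdir, "sensitivity")
    _write(disc["screen"].gene_records_, outdir, "survival_genes")
    _write(disc["screen"].variant_records_, outdir, "survival_variants")
    _write(disc["km_cutoffs"], outdir, "km_cutoffs")

    # ---- validation cohort: survival of matched variants under T-only
    # adjustment (the validation cohort is assumed to lack N/M)
    sig_pairs = disc["mapper"].significant_pairs_
    sig_only = sig_pairs[sig_pairs["significant"]]
    disc_variants = disc["genotypes"].variants.loc[
        [v for v in sig_only["variant_id"].unique()]
    ]
    matches = match_variants(disc_variants, bundle_b.genotypes)
    val_dosage_rows = {}
    for vid, row in matches[matches["matched"]].iterrows():
        val_dosage_rows[vid] = harmonized_dosage(
            bundle_b.genotypes, row["validation_id"], row["flipped"]
        )
    val_dosage = pd.DataFrame.from_dict(
        val_dosage_rows, orient="index", columns=bundle_b.genotypes.samples
    )
    val_screen = SurvivalScreen(adjust_cols=validation_adjust).fit(
        None, val_dosage if len(val_dosage) else None, bundle_b.clinical.df
    )

    rep = ReplicationAnalysis().fit(
        disc["screen"].prognostic_sets_,
        sig_only,
        disc["screen"].variant_records_,
        validation_records=val_screen.variant_records_,
        validation_dosage=val_dosage if len(val_dosage) else None,
    )
    _write(rep.consistent_pairs_, outdir, "consistency_pairs")
    tiers = rep.tiers_.merge(
        matches.reset_index()[["variant_id", "matched", "flipped"]],
        left_on="variant",
        right_on="variant_id",
        how="left",
    ).drop(columns=["variant_id"])
    _write(tiers, outdir, "replication")

    summary = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "n_genes": cfg.n_genes,
        "n_variants": cfg.n_variants,
        "n_variants_post_qc": int(disc["genotypes"].n_variants),
        "n_pairs_tested": disc["mapper"].pair_summary_["n_pairs_tested"],
        "n_egenes": len(disc["mapper"].egenes_),
        "n_egenes_passing_sensitivity": len(disc["passing_egenes"]),
        "n_significant_pairs": disc["mapper"].pair_summary_[
            "n_significant_pairs"
        ],
        "n_unique_eqtls": disc["mapper"].pair_summary_["n_unique_eqtls"],
        "n_prognostic_genes_union": len(disc["screen"].prognostic_sets_.union),
        "n_prognostic_genes_unadjusted": len(
            disc["screen"].prognostic_sets_.unadjusted
        ),
        "n_prognostic_genes_adjusted": len(
            disc["screen"].prognostic_sets_.adjusted
        ),
        "consistency": rep.summary_,
        "n_matched_variants": int(matches["matched"].sum()),
        "tiers": rep.tiers_["tier"].value_counts().to_dict()
        if len(rep.tiers_)
        else {},
        "n_strict_loci": len(rep.loci_) if rep.loci_ is not None else 0,
    }
    with open(outdir / STAGE_FILES["summary"], "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return {
        "discovery": disc,
        "validation_screen": val_screen,
        "matches": matches,
        "replication": rep,
        "summary": summary,
        "truth_a": truth_a,
        "truth_b": truth_b,
        "bundles": (bundle_a, bundle_b),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj
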