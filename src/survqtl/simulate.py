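"""Synthetic twin-cohort generator.

Emulates the statistical structure the analysis assumes, at the scale of a
~100-patient tumour cohort: biallelic dosages in Hardy-Weinberg
proportions with a configurable MAF spectrum and missingness; TPM-scale
expression with cis effects planted inside +/-1 Mb of the TSS, shared
latent factors and log-normal baseline abundance; TNM-style clinical
covariates; and Weibull proportional-hazards survival driven by
standardized expression of planted genes plus clinical effects, with
administrative censoring.  A paired cohort re-draws genotypes at shifted
allele frequencies and retains, nulls or flips a configurable subset of
the planted effects — creating known strict-replicating, lenient-only and
discordant gene-variant pairs for end-to-end testing.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    CohortBundle,
    ExpressionMatrix,
    GenotypeMatrix,
)
from .qc import mean_impute_matrix

__all__ = [
    "PlantedEqtl",
    "PlantedSurvival",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_survival",
    "simulate_clinical",
    "simulate_cohort",
    "make_paired_cohorts",
]

# cohort-B fate of a planted effect
SHARED, NULLED, FLIPPED = "shared", "nulled", "flipped"


@dataclass(frozen=True)
class PlantedEqtl:
    """A cis effect of one variant on one gene (slope per ALT allele on the
    latent log-expression scale)."""

    gene: str
    slope: float
    cohort_b: str = SHARED  # shared | nulled | flipped


@dataclass(frozen=True)
class PlantedSurvival:
    """A log-hazard effect per unit standardized latent expression."""

    gene: str
    gamma: float
    cohort_b: str = SHARED


@dataclass
class SimulationConfig:
    """Stated world of the synthetic cohorts.

    Defaults mirror the discovery-cohort scale: 100 samples, ~300 genes,
    ~3000 variants (10 local variants per gene), MAF 0.05-0.5, 2% missing
    genotypes.  Planted eQTL variants draw their MAF from
    ``planted_maf_range`` and sit nearest the TSS.  Survival is Weibull
    (shape 1 = exponential baseline) with administrative censoring at
    ``censor_horizon`` days, tuned to an event fraction around 0.55.
    """

    seed: int
    n_samples: int = 100
    n_genes: int = 300
    n_variants: int = 3000
    maf_range: tuple = (0.05, 0.5)
    planted_maf_range: tuple = (0.2, 0.5)
    missing_rate: float = 0.02
    planted_eqtls: list = field(default_factory=list)
    planted_survival: list = field(default_factory=list)
    n_chromosomes: int = 5
    gene_spacing: int = 2_100_000  # keeps cis windows of neighbours disjoint
    cis_window: int = 1_000_000
    n_latent_factors: int = 2
    latent_sd: float = 0.5
    noise_sd: float = 1.0
    base_log_tpm_mean: float = 1.5
    base_log_tpm_sd: float = 2.0
    planted_base_bonus: float = 1.0  # planted genes stay above expression filters
    library_size: float = 2.0e7
    clinical_coefs: dict = field(
        default_factory=lambda: {"T": 0.4, "N": 0.4, "M": 0.7}
    )
    weibull_shape: float = 1.0
    weibull_scale: float = 3000.0
    censor_horizon: float = 2920.0
    male_fraction: float = 0.77
    over50_fraction: float = 0.8
    sharing_fraction: float = 1.0
    discordant_fraction: float = 0.0
    maf_shift_sd: float = 0.05
    ld_rho: float = 0.85  # within-gene-block allele-copula correlation (0 = no LD)

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5]: {self.maf_range}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0,1): {self.missing_rate}")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape/scale must be positive")
        for e in self.planted_eqtls:
            if not math.isfinite(e.slope):
                raise ValueError(f"non-finite planted slope for {e.gene}")
        for s in self.planted_survival:
            if not math.isfinite(s.gamma):
                raise ValueError(f"non-finite planted gamma for {s.gene}")
        if len(self.planted_eqtls) > self.n_variants:
            raise ValueError("more planted eQTLs than variants")

    # -- deterministic layout helpers -------------------------------------
    def gene_ids(self) -> list:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def gene_table(self) -> pd.DataFrame:
        """Genes laid out round-robin over chromosomes, spaced so that
        neighbouring cis windows do not overlap."""
        ids = self.gene_ids()
        per_chrom = math.ceil(self.n_genes / self.n_chromosomes)
        chroms, tss = [], []
        for i in range(self.n_genes):
            c = i // per_chrom
            j = i % per_chrom
            chroms.append(f"chr{c + 1}")
            tss.append(self.cis_window + 10_000 + j * self.gene_spacing)
        return pd.DataFrame(
            {"chrom": chroms, "tss": tss, "strand": "+", "biotype": "protein_coding"},
            index=pd.Index(ids, name="gene_id"),
        )


def _rng_for(cfg: SimulationConfig, stage: str, cohort: str) -> np.random.Generator:
    # stable per-stage streams: stage changes never reshuffle other stages
    stage_ids = {
        "genotypes": 1, "expression": 2, "clinical": 3, "survival": 4,
    }
    cohort_ids = {"A": 0, "B": 1}
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(cohort_ids[cohort], stage_ids[stage])
        )
    )


def _draw_block_ld_genotypes(
    rng: np.random.Generator,
    maf: np.ndarray,
    blocks: np.ndarray,
    n_samples: int,
    ld_rho: float,
) -> np.ndarray:
    """Hardy-Weinberg genotypes with exchangeable within-block LD.

    Each variant's two allele draws come from a Gaussian copula sharing a
    block-level latent with weight sqrt(ld_rho): marginally each allele is
    Bernoulli(maf) (so genotypes are Binomial(2, maf), exact HWE), while
    variants of one block are positively correlated — emulating local LD
    without modelling recombination.  ld_rho = 0 gives independent sites.
    """
    from scipy.stats import norm

    if not (0.0 <= ld_rho < 1.0):
        raise ValueError(f"ld_rho must be in [0, 1): {ld_rho}")
    n_v = maf.shape[0]
    dosage = np.empty((n_v, n_samples))
    thresh = norm.ppf(maf)
    for b in np.unique(blocks):
        sel = np.where(blocks == b)[0]
        shared = rng.normal(size=(2, n_samples))  # one latent per allele channel
        eps = rng.normal(size=(2, sel.size, n_samples))
        u = np.sqrt(ld_rho) * shared[:, None, :] + np.sqrt(1.0 - ld_rho) * eps
        allele = u < thresh[sel][None, :, None]
        dosage[sel] = allele.sum(axis=0)
    return dosage


def _variant_layout(cfg: SimulationConfig) -> tuple:
    """Cohort-independent variant panel: positions, alleles, base MAFs,
    LD-block ids and causal designations (seeded by cfg.seed only)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(9, 0))
    )
    genes = cfg.gene_table()
    per_gene = cfg.n_variants // cfg.n_genes
    if per_gene < 1:
        raise ValueError("need at least one variant per gene")
    planted_genes = [e.gene for e in cfg.planted_eqtls]
    unknown = set(planted_genes) - set(genes.index)
    if unknown:
        raise ValueError(f"planted eQTL genes not in layout: {sorted(unknown)}")

    rows, mafs, blocks = [], [], []
    causal = {}
    alleles = ("A", "C", "G", "T")
    n_extra = cfg.n_variants - per_gene * cfg.n_genes
    for g_i, (gene_id, grow) in enumerate(genes.iterrows()):
        k = per_gene + (1 if g_i < n_extra else 0)
        offsets = np.linspace(-cfg.cis_window + 5000, cfg.cis_window - 5000, k)
        for j, off in enumerate(offsets):
            pos = int(grow["tss"] + off)
            ref, alt = rng.choice(4, size=2, replace=False)
            is_causal = gene_id in planted_genes and j == k // 2
            if is_causal:
                maf = rng.uniform(*cfg.planted_maf_range)
            else:
                maf = rng.uniform(*cfg.maf_range)
            rows.append(
                {
                    "chrom": grow["chrom"],
                    "pos": pos,
                    "ref": alleles[ref],
                    "alt": alleles[alt],
                    "rsid": None,
                }
            )
            mafs.append(maf)
            blocks.append(g_i)
            if is_causal:
                causal[gene_id] = len(rows) - 1
    variants = pd.DataFrame(rows)
    variants.index = pd.Index(
        [f"{r.chrom}_{r.pos}_{r.ref}_{r.alt}" for r in variants.itertuples()],
        name="variant_id",
    )
    if variants.index.has_duplicates:
        raise RuntimeError("variant id collision in layout")
    return variants, np.asarray(mafs), np.asarray(blocks), causal


def simulate_genotypes(
    cfg: SimulationConfig,
    cohort: str = "A",
    base_maf: Optional[np.ndarray] = None,
) -> tuple:
    """Hardy-Weinberg genotypes with per-variant MAF and missingness.

    The variant panel (positions, alleles, base frequencies, causal-site
    designation) is derived from the config seed alone, so twin cohorts
    share it; only the genotype draws (and, for cohort B, the shifted
    frequencies) use the cohort-specific stream.  For every planted eQTL
    one variant adjacent to the gene's TSS is designated causal (MAF from
    ``planted_maf_range``).  Returns ``(GenotypeMatrix, info)`` with the
    causal-variant map and the frequencies used.
    """
    variants, maf_arr, blocks, causal = _variant_layout(cfg)
    rng = _rng_for(cfg, "genotypes", cohort)
    if cohort == "B":
        maf_arr = np.clip(
            maf_arr + rng.normal(0.0, cfg.maf_shift_sd, size=maf_arr.shape),
            0.02, 0.5,
        )
    if base_maf is not None:  # explicit frequency override
        maf_arr = np.asarray(base_maf, dtype=float)
    dosage = _draw_block_ld_genotypes(
        rng, maf_arr, np.asarray(blocks), cfg.n_samples, cfg.ld_rho
    )
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = np.nan

    samples = [f"{cohort}S{i:04d}" for i in range(cfg.n_samples)]
    g = GenotypeMatrix(variants=variants, samples=samples, dosage=dosage)
    info = {
        "causal_variant": {
            gene: variants.index[idx] for gene, idx in causal.items()
        },
        "maf": maf_arr,
    }
    return g, info


def _effective_effects(cfg: SimulationConfig, cohort: str) -> tuple:
    """Planted effect lists as seen by the given cohort."""
    def adjust(items, attr):
        out = []
        for it in items:
            value = getattr(it, attr)
            if cohort == "B":
                if it.cohort_b == NULLED:
                    continue
                if it.cohort_b == FLIPPED:
                    value = -value
            out.append((it.gene, value))
        return out

    return (
        adjust(cfg.planted_eqtls, "slope"),
        adjust(cfg.planted_survival, "gamma"),
    )


def simulate_expression(
    g: GenotypeMatrix,
    cfg: SimulationConfig,
    info: dict,
    cohort: str = "A",
) -> tuple:
    """Latent Gaussian expression with planted cis effects, mapped to TPM
    by exponentiation and to counts by Poisson sampling.

    latent = slope * dosage (mean-imputed) + latent-factor term + noise;
    TPM = exp(latent + per-gene base);  counts ~ Poisson(TPM/1e6 * library
    size).  Returns ``(ExpressionMatrix, latent_frame)``; downstream
    survival uses the latent values so planted hazards act on the same
    scale the eQTL slope was planted on.
    """
    rng = _rng_for(cfg, "expression", cohort)
    genes = cfg.gene_table()
    n_g, n_s = cfg.n_genes, cfg.n_samples
    eqtls, _ = _effective_effects(cfg, cohort)

    base = cfg.base_log_tpm_mean + cfg.base_log_tpm_sd * rng.normal(size=n_g)
    loadings = cfg.latent_sd * rng.normal(size=(n_g, cfg.n_latent_factors))
    factors = rng.normal(size=(cfg.n_latent_factors, n_s))
    noise = cfg.noise_sd * rng.normal(size=(n_g, n_s))
    latent = loadings @ factors + noise

    imputed = mean_impute_matrix(g.dosage)
    gene_pos = {gid: i for i, gid in enumerate(genes.index)}
    planted_gene_set = set()
    for gene, slope in eqtls:
        vid = info["causal_variant"].get(gene)
        if vid is None:
            raise ValueError(f"no causal variant designated for {gene}")
        vrow = g.variants.index.get_loc(vid)
        latent[gene_pos[gene]] += slope * imputed[vrow]
        planted_gene_set.add(gene)
    for gene in set(e.gene for e in cfg.planted_eqtls) | set(
        s.gene for s in cfg.planted_survival
    ):
        base[gene_pos[gene]] = (
            cfg.base_log_tpm_mean + cfg.planted_base_bonus
        )  # keep planted genes comfortably expressed

    tpm = np.exp(latent + base[:, None])
    counts = rng.poisson(tpm / 1e6 * cfg.library_size).astype(float)
    e = ExpressionMatrix(
        genes=genes, samples=list(g.samples), tpm=tpm, counts=counts
    )
    latent_frame = pd.DataFrame(latent, index=genes.index, columns=g.samples)
    return e, latent_frame


def simulate_clinical(cfg: SimulationConfig, samples, cohort: str = "A") -> pd.DataFrame:
    rng = _rng_for(cfg, "clinical", cohort)
    n = len(samples)
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    age_group = (rng.random(n) < cfg.over50_fraction).astype(int)
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=[0.35, 0.25, 0.3, 0.1])
    n_stage = rng.choice([0, 1, 2], size=n, p=[0.75, 0.15, 0.1])
    m_stage = rng.choice([0, 1], size=n, p=[0.8, 0.2])
    return pd.DataFrame(
        {
            "sex": sex,
            "age_group": age_group,
            "T": t_stage,
            "N": n_stage,
            "M": m_stage,
        },
        index=pd.Index(samples, name="sample_id"),
    )


def simulate_survival(
    latent: pd.DataFrame,
    clinical: pd.DataFrame,
    cfg: SimulationConfig,
    cohort: str = "A",
) -> ClinicalTable:
    """Weibull proportional-hazards event times with administrative
    censoring.

    log-hazard shift = sum of gamma * standardized latent expression over
    planted survival genes + centred clinical staging effects.  With U ~
    Uniform(0,1), T = scale * (-log U / exp(eta))^(1/shape); events past
    the censoring horizon are censored there.
    """
    rng = _rng_for(cfg, "survival", cohort)
    _, gammas = _effective_effects(cfg, cohort)
    n = clinical.shape[0]
    eta = np.zeros(n)
    for gene, gamma in gammas:
        if gene not in latent.index:
            raise ValueError(f"planted survival gene {gene} not simulated")
        x = latent.loc[gene].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        eta += gamma * z
    for col, coef in cfg.clinical_coefs.items():
        v = clinical[col].to_numpy(dtype=float)
        eta += coef * (v - v.mean())

    u = rng.uniform(size=n)
    raw = cfg.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.weibull_shape)
    event = (raw <= cfg.censor_horizon).astype(int)
    time = np.minimum(raw, cfg.censor_horizon)
    time = np.maximum(time, 1.0)  # days, floored at 1
    df = clinical.copy()
    df["time"] = time
    df["event"] = event
    return ClinicalTable(df)


def simulate_cohort(cfg: SimulationConfig, cohort: str = "A") -> tuple:
    """Full cohort bundle plus ground-truth metadata."""
    g, info = simulate_genotypes(cfg, cohort=cohort)
    e, latent = simulate_expression(g, cfg, info, cohort=cohort)
    clin = simulate_clinical(cfg, g.samples, cohort=cohort)
    surv = simulate_survival(latent, clin, cfg, cohort=cohort)
    bundle = CohortBundle(genotypes=g, expression=e, clinical=surv)
    truth = {
        "causal_variant": info["causal_variant"],
        "latent": latent,
        "eqtls": [
            {
                "gene": p.gene,
                "variant": info["causal_variant"].get(p.gene),
                "slope": p.slope,
                "cohort_b": p.cohort_b,
            }
            for p in cfg.planted_eqtls
        ],
        "survival": [
            {"gene": s.gene, "gamma": s.gamma, "cohort_b": s.cohort_b}
            for s in cfg.planted_survival
        ],
    }
    return bundle, truth


def assign_cohort_b_fates(
    eqtls: Sequence[PlantedEqtl],
    survival: Sequence[PlantedSurvival],
    sharing_fraction: float,
    discordant_fraction: float = 0.0,
) -> tuple:
    """Deterministically assign cohort-B fates to planted effects.

    The first ``round(sharing * k)`` effects are shared, the next
    ``round(discordant * k)`` flipped in sign, the remainder nulled.
    Gene-wise: an eQTL and a survival effect on the same gene get the same
    fate when both lists align by gene.
    """
    if not (0.0 <= sharing_fraction <= 1.0):
        raise ValueError("sharing fraction must be in [0, 1]")
    genes = [e.gene for e in eqtls]
    k = len(genes)
    n_shared = round(sharing_fraction * k)
    n_flip = round(discordant_fraction * k)
    if n_shared + n_flip > k:
        raise ValueError("sharing + discordant fractions exceed 1")
    fate_by_gene = {}
    for i, gene in enumerate(genes):
        if i < n_shared:
            fate_by_gene[gene] = SHARED
        elif i < n_shared + n_flip:
            fate_by_gene[gene] = FLIPPED
        else:
            fate_by_gene[gene] = NULLED
    new_eqtls = [replace(e, cohort_b=fate_by_gene.get(e.gene, NULLED)) for e in eqtls]
    new_survival = [
        replace(s, cohort_b=fate_by_gene.get(s.gene, NULLED)) for s in survival
    ]
    return new_eqtls, new_survival


def make_paired_cohorts(cfg: SimulationConfig) -> tuple:
    """Twin cohorts A (discovery) and B (validation).

    Cohort B re-draws genotypes at shifted MAFs (same variants/alleles)
    and keeps/flips/nulls planted effects according to each effect's
    ``cohort_b`` fate; when no per-effect fate deviates from 'shared' and
    ``sharing_fraction < 1`` (or discordant_fraction > 0), fates are
    assigned deterministically from those fractions.

    Returns ``(bundle_a, truth_a, bundle_b, truth_b)``.
    """
    cfg_b = cfg
    explicit = any(
        p.cohort_b != SHARED for p in list(cfg.planted_eqtls) + list(cfg.planted_survival)
    )
    if not explicit and (cfg.sharing_fraction < 1.0 or cfg.discordant_fraction > 0.0):
        eqtls, survival = assign_cohort_b_fates(
            cfg.planted_eqtls,
            cfg.planted_survival,
            cfg.sharing_fraction,
            cfg.discordant_fraction,
        )
        cfg_b = replace(cfg, planted_eqtls=eqtls, planted_survival=survival)
    bundle_a, truth_a = simulate_cohort(cfg_b, cohort="A")
    bundle_b, truth_b = simulate_cohort(cfg_b, cohort="B")
    return bundle_a, truth_a, bundle_b, truth_b
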