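"""Expression prep: TMM normalization, gene filtering, inverse-normal
transform, latent factors, genotype PCs, covariate assembly."""

import numpy as np
import pandas as pd
import pytest

from survqtl import (
    ExpressionPreprocessor,
    assemble_covariates,
    filter_genes,
    genotype_pcs,
    inverse_normal_transform,
    latent_factors,
    tmm_normalize,
)
from survqtl.datatypes import ClinicalTable, ExpressionMatrix, GenotypeMatrix
from survqtl.expression import tmm_factors

# edgeR::calcNormFactors(method="TMM") on the deterministic fixture below,
# computed once with the upper-quartile reference rule (frozen oracle)
EDGER_FACTORS = np.array(
    [1.0744485694, 1.0185654526, 0.9540521756, 0.9000623302,
     1.0007852636, 1.0632608236]
)


def _tmm_fixture():
    rng = np.random.default_rng(42)
    base = rng.lognormal(3, 1.5, size=50)
    factors_true = np.array([1.0, 1.6, 0.7, 1.2, 0.9, 2.5])
    return rng.poisson(
        base[:, None] * factors_true[None, :] * rng.lognormal(0, 0.3, size=(50, 6))
    )


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.array([[5.0], [10.0], [100.0]]), (1, 4))
        factors = tmm_factors(counts)
        np.testing.assert_allclose(factors, 1.0)

    def test_scaled_sample_normalizes_to_same_profile(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, size=200).astype(float) + 1
        counts = np.column_stack([a, 2 * a, a])
        normalized, _ = tmm_normalize(counts)
        np.testing.assert_allclose(normalized[:, 0], normalized[:, 1], rtol=1e-9)

    def test_factors_geometric_mean_one(self):
        counts = _tmm_fixture()
        f = tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_edger_oracle(self):
        """Frozen edgeR factors reproduced to 1e-8 under the edgeR
        reference rule; the default reference rule agrees within 5%."""
        counts = _tmm_fixture()
        mine = tmm_factors(counts, ref_rule="upper_quartile")
        np.testing.assert_allclose(mine, EDGER_FACTORS, rtol=1e-8)
        default = tmm_factors(counts)
        np.testing.assert_allclose(default, EDGER_FACTORS, rtol=0.05)

    def test_gene_order_invariance(self):
        counts = _tmm_fixture()
        perm = np.random.default_rng(3).permutation(counts.shape[0])
        np.testing.assert_allclose(tmm_factors(counts), tmm_factors(counts[perm]))

    def test_zero_sample_errors(self):
        counts = _tmm_fixture().astype(float)
        counts[:, 2] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(counts)


def _expr(tpm, counts, n_samples):
    n_g = tpm.shape[0]
    genes = pd.DataFrame(
        {"chrom": "chr1", "tss": np.arange(1, n_g + 1) * 1000,
         "strand": "+", "biotype": "protein_coding"},
        index=pd.Index([f"G{i}" for i in range(n_g)], name="gene_id"),
    )
    return ExpressionMatrix(
        genes=genes, samples=[f"S{j}" for j in range(n_samples)],
        tpm=tpm, counts=counts,
    )


class TestFilterGenes:
    def test_expression_thresholds(self):
        n = 100
        tpm = np.zeros((4, n))
        counts = np.zeros((4, n))
        # kept: TPM>0.1 in exactly 20 samples, counts>=6 in exactly 20
        tpm[0, :20] = 1.0
        counts[0, :20] = 6
        # removed: TPM>0.1 in only 19 samples
        tpm[1, :19] = 1.0
        counts[1, :30] = 10
        # removed: counts >= 6 in only 10 samples
        tpm[2, :50] = 1.0
        counts[2, :10] = 6
        # gene 3 all-zero: removed
        e = _expr(tpm, counts, n)
        kept = filter_genes(e)
        assert list(kept.genes.index) == ["G0"]

    def test_idempotent(self, small_bundle):
        bundle, _ = small_bundle
        once = filter_genes(bundle.expression)
        twice = filter_genes(once)
        assert list(twice.genes.index) == list(once.genes.index)


def test_inverse_normal_transform_is_rank_based():
    x = np.array([10.0, -3.0, 5.0, 100.0])
    out = inverse_normal_transform(x)
    assert np.argsort(out).tolist() == np.argsort(x).tolist()
    np.testing.assert_allclose(out.mean(), 0, atol=1e-12)
    # symmetric grid of normal quantiles at (rank-0.5)/n
    from scipy import stats

    expect = stats.norm.ppf((stats.rankdata(x) - 0.5) / x.size)
    np.testing.assert_allclose(np.sort(out), np.sort(expect))


class TestLatentFactors:
    def test_rank_one_pattern_recovered(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=40)
        loadings = rng.uniform(0.5, 2.0, size=25)
        mat = np.outer(loadings, pattern) + rng.normal(0, 1e-6, (25, 40))
        f = latent_factors(mat, k=1)
        r = np.corrcoef(f["factor1"], pattern)[0, 1]
        assert abs(r) > 0.999

    def test_orthogonality_and_sign_convention(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(30, 20))
        f = latent_factors(mat, k=4).to_numpy()
        gram = f.T @ f
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_planted_factor_recovered_in_simulation(self):
        """A single strong latent factor is recovered with |r| > 0.95."""
        rng = np.random.default_rng(2)
        n, g = 100, 300
        scores = rng.normal(size=n)
        loadings = rng.normal(0, 1.0, size=g)
        mat = np.outer(loadings, scores) + rng.normal(0, 0.3, (g, n))
        f = latent_factors(mat, k=3)
        r = np.corrcoef(f["factor1"], scores)[0, 1]
        assert abs(r) > 0.95

    def test_k_validation(self):
        with pytest.raises(ValueError):
            latent_factors(np.random.default_rng(0).normal(size=(10, 5)), k=0)
        with pytest.raises(ValueError):
            latent_factors(np.random.default_rng(0).normal(size=(10, 5)), k=5)


def _geno(dosage):
    n_v = dosage.shape[0]
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, n_v + 1), "ref": "A", "alt": "T",
         "rsid": None},
        index=pd.Index([f"chr1_{i}_A_T" for i in range(1, n_v + 1)],
                       name="variant_id"),
    )
    return GenotypeMatrix(
        variants=variants,
        samples=[f"S{j}" for j in range(dosage.shape[1])],
        dosage=dosage,
    )


class TestGenotypePcs:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        n_half, n_v = 50, 200
        p1 = rng.uniform(0.1, 0.4, n_v)
        p2 = np.clip(p1 + rng.choice([-0.25, 0.25], n_v), 0.05, 0.95)
        pop1 = rng.binomial(2, p1[:, None], (n_v, n_half))
        pop2 = rng.binomial(2, p2[:, None], (n_v, n_half))
        g = _geno(np.hstack([pop1, pop2]).astype(float))
        pcs = genotype_pcs(g, k=5)
        labels = np.array([0] * n_half + [1] * n_half)
        r = np.corrcoef(pcs["pc1"], labels)[0, 1]
        assert abs(r) > 0.9

    def test_variant_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.3, (60, 30)).astype(float)
        g = _geno(dosage)
        pcs1 = genotype_pcs(g, k=3).to_numpy()
        perm = rng.permutation(60)
        g2 = g.subset_variants(g.variants.index[perm])
        pcs2 = genotype_pcs(g2, k=3).to_numpy()
        for j in range(3):
            r = np.corrcoef(pcs1[:, j], pcs2[:, j])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8

    def test_too_few_polymorphic_variants(self):
        dosage = np.zeros((4, 10))
        dosage[0, :5] = 1
        with pytest.raises(ValueError, match="polymorphic"):
            genotype_pcs(_geno(dosage), k=3)


class TestAssembleCovariates:
    def test_clinical_encoding(self, toy_clinical):
        rng = np.random.default_rng(5)
        n = len(toy_clinical.samples)
        pcs = pd.DataFrame(rng.normal(size=(n, 2)), columns=["pc1", "pc2"])
        fac = pd.DataFrame(rng.normal(size=(n, 2)), columns=["factor1", "factor2"])
        cov = assemble_covariates(pcs, fac, toy_clinical)
        df = toy_clinical.df
        np.testing.assert_array_equal(
            cov["sex"], (df["sex"] == "male").astype(float)
        )
        np.testing.assert_array_equal(cov["T"], df["T"].astype(float))
        np.testing.assert_array_equal(cov["age_group"], df["age_group"].astype(float))

    def test_missing_clinical_field_errors(self, toy_clinical):
        df = toy_clinical.df.copy()
        df.loc[df.index[2], "T"] = np.nan
        broken = ClinicalTable(df)
        rng = np.random.default_rng(6)
        n = len(df)
        pcs = pd.DataFrame(rng.normal(size=(n, 2)), columns=["pc1", "pc2"])
        fac = pd.DataFrame(rng.normal(size=(n, 2)), columns=["factor1", "factor2"])
        with pytest.raises(ValueError, match="missing clinical"):
            assemble_covariates(pcs, fac, broken)

    def test_constant_column_rejected(self, toy_clinical):
        rng = np.random.default_rng(7)
        n = len(toy_clinical.samples)
        pcs = pd.DataFrame(
            {"pc1": rng.normal(size=n), "pc2": np.ones(n)}  # degenerate
        )
        fac = pd.DataFrame(rng.normal(size=(n, 1)), columns=["factor1"])
        with pytest.raises(ValueError, match="constant covariate"):
            assemble_covariates(pcs, fac, toy_clinical)


def test_expression_preprocessor_end_to_end(small_bundle):
    bundle, _ = small_bundle
    prep = ExpressionPreprocessor(n_factors=5).fit(bundle.expression)
    phen = prep.phenotype_
    assert phen.shape[1] == bundle.expression.n_samples
    assert prep.factors_.shape == (bundle.expression.n_samples, 5)
    # inverse-normal phenotype: every gene row is centred (ties from
    # low-count genes shift the mean slightly via average ranks)
    np.testing.assert_allclose(phen.to_numpy().mean(axis=1), 0, atol=0.02)
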