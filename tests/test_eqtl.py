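"""cis-eQTL mapping: window arithmetic, the nominal scan and its
Frisch-Waugh equivalence, the adaptive permutation pass, BH calling and
the inheritance-model sensitivity screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survqtl import (
    call_egenes,
    call_significant_pairs,
    cis_pairs,
    nominal_scan,
    permutation_pass,
    sensitivity_screen,
)
from survqtl.eqtl import bh_qvalues, residualize


class TestCisPairs:
    def setup_method(self):
        self.genes = pd.DataFrame(
            {"chrom": ["chr1"], "tss": [1_000_000]},
            index=pd.Index(["G1"], name="gene_id"),
        )

    def _variants(self, chrom, pos):
        return pd.DataFrame(
            {"chrom": [chrom], "pos": [pos]},
            index=pd.Index([f"{chrom}_{pos}_A_T"], name="variant_id"),
        )

    def test_boundary_inclusive(self):
        pairs = cis_pairs(self.genes, self._variants("chr1", 2_000_000))
        assert len(pairs) == 1
        assert pairs["tss_distance"].iloc[0] == 1_000_000

    def test_just_outside_window(self):
        pairs = cis_pairs(self.genes, self._variants("chr1", 2_000_001))
        assert len(pairs) == 0

    def test_different_chromosome_excluded(self):
        pairs = cis_pairs(self.genes, self._variants("chr2", 1_000_000))
        assert len(pairs) == 0

    def test_signed_distance(self):
        pairs = cis_pairs(self.genes, self._variants("chr1", 999_000))
        assert pairs["tss_distance"].iloc[0] == -1_000


def _scan_frames(y, x, gene="G1", variant="V1"):
    phenotype = pd.DataFrame([y], index=pd.Index([gene], name="gene_id"),
                             columns=[f"S{i}" for i in range(len(y))])
    dosage = pd.DataFrame([x], index=pd.Index([variant], name="variant_id"),
                          columns=phenotype.columns)
    pairs = pd.DataFrame({"gene_id": [gene], "variant_id": [variant],
                          "tss_distance": [0]})
    return pairs, phenotype, dosage


class TestNominalScan:
    def test_closed_form_toy(self):
        """n=6, x=(0,0,1,1,2,2), y=(1.0,1.2,1.4,1.6,1.9,2.1): OLS slope
        Sxy/Sxx = 1.8/4 = 0.45 and p from t with 4 df."""
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1.0, 1.2, 1.4, 1.6, 1.9, 2.1])
        pairs, phen, dos = _scan_frames(y, x)
        out = nominal_scan(pairs, phen, dos)
        rec = out.iloc[0]
        assert rec["slope"] == pytest.approx(0.45)
        # independent closed form for the t-test
        sxx = ((x - x.mean()) ** 2).sum()
        resid = y - y.mean() - 0.45 * (x - x.mean())
        se = math.sqrt(resid @ resid / 4 / sxx)
        from scipy import stats

        t = 0.45 / se
        assert rec["slope_se"] == pytest.approx(se, rel=1e-9)
        assert rec["nominal_p"] == pytest.approx(2 * stats.t.sf(t, 4), rel=1e-9)

    def test_frisch_waugh_equivalence(self, rng):
        """Residualize-then-regress equals the joint covariate regression
        to 1e-8 on random instances."""
        for _ in range(20):
            n = 40
            k = int(rng.integers(1, 5))
            cov = pd.DataFrame(
                rng.normal(size=(n, k)), columns=[f"c{i}" for i in range(k)],
                index=[f"S{i}" for i in range(n)],
            )
            x = rng.binomial(2, 0.4, n).astype(float)
            y = 0.5 * x + cov.to_numpy() @ rng.normal(size=k) + rng.normal(size=n)
            pairs, phen, dos = _scan_frames(y, x)
            cov.index = phen.columns
            a = nominal_scan(pairs, phen, dos, cov).iloc[0]
            b = nominal_scan(pairs, phen, dos, cov, method="direct").iloc[0]
            assert a["slope"] == pytest.approx(b["slope"], abs=1e-8)
            assert a["nominal_p"] == pytest.approx(b["nominal_p"], abs=1e-8)
            assert a["slope_se"] == pytest.approx(b["slope_se"], abs=1e-8)

    def test_collinear_dosage_skipped_with_reason(self, rng):
        n = 30
        x = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(size=n)
        pairs, phen, dos = _scan_frames(y, x)
        cov = pd.DataFrame({"dup": x}, index=phen.columns)
        out = nominal_scan(pairs, phen, dos, cov)
        assert len(out) == 0
        skipped = out.attrs["skipped"]
        assert len(skipped) == 1
        assert "variance" in skipped["reason"].iloc[0]

    def test_null_pvalues_uniform(self, rng):
        """Under independence the nominal p is U(0,1) (KS check)."""
        from scipy import stats

        n, m = 50, 400
        phen = pd.DataFrame(
            rng.normal(size=(m, n)),
            index=pd.Index([f"G{i}" for i in range(m)], name="gene_id"),
            columns=[f"S{i}" for i in range(n)],
        )
        dos = pd.DataFrame(
            rng.binomial(2, 0.3, size=(m, n)).astype(float),
            index=pd.Index([f"V{i}" for i in range(m)], name="variant_id"),
            columns=phen.columns,
        )
        pairs = pd.DataFrame(
            {"gene_id": phen.index, "variant_id": dos.index,
             "tss_distance": 0}
        )
        out = nominal_scan(pairs, phen, dos)
        ks = stats.kstest(out["nominal_p"], "uniform")
        assert ks.pvalue > 0.01


class TestPermutationPass:
    def _planted(self, rng, n=40, beta=1.0):
        x = rng.binomial(2, 0.4, size=(3, n)).astype(float)
        y = beta * x[0] + rng.normal(size=n)
        return y, x

    def test_empirical_p_bounds_and_determinism(self, rng):
        y, x = self._planted(rng)
        res1 = permutation_pass(
            "G", y, x, ["v0", "v1", "v2"], min_perm=200, max_perm=500,
            rng=np.random.default_rng(11),
        )
        res2 = permutation_pass(
            "G", y, x, ["v0", "v1", "v2"], min_perm=200, max_perm=500,
            rng=np.random.default_rng(11),
        )
        m = res1.n_permutations
        assert 1.0 / (m + 1) <= res1.empirical_p <= 1.0
        assert res1.empirical_p == res2.empirical_p
        assert res1.beta_approx_p == res2.beta_approx_p
        assert res1.top_variant == "v0"

    def test_null_gene_empirical_p_large(self, rng):
        x = rng.binomial(2, 0.4, size=(2, 50)).astype(float)
        y = rng.normal(size=50)
        res = permutation_pass("G", y, x, ["a", "b"], min_perm=200,
                               max_perm=500, rng=np.random.default_rng(1))
        assert res.empirical_p > 0.01

    def test_exhaustive_fallback_tiny_n(self):
        """n=5 -> 5! = 120 < min_perm: every permutation enumerated."""
        y = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        x = np.array([[0.0, 1.0, 0.0, 2.0, 1.0]])
        res = permutation_pass("G", y, x, ["v"], min_perm=1000,
                               max_perm=2000, rng=np.random.default_rng(0))
        assert res.n_permutations == math.factorial(5)

    def test_beta_approximation_tracks_empirical(self, rng):
        """Spearman correlation of beta-approximated and empirical
        gene-level p across simulated genes > 0.95."""
        from scipy import stats

        emp, beta_p = [], []
        n = 30
        for i in range(80):
            x = rng.binomial(2, 0.35, size=(4, n)).astype(float)
            strength = rng.uniform(0, 0.8)
            y = strength * x[0] + rng.normal(size=n)
            res = permutation_pass(
                f"G{i}", y, x, list("abcd"), min_perm=300, max_perm=300,
                adaptive_stop=10**9, rng=np.random.default_rng(1000 + i),
            )
            emp.append(res.empirical_p)
            beta_p.append(res.beta_approx_p)
        rho = stats.spearmanr(emp, beta_p).statistic
        assert rho > 0.95


class TestBhCalling:
    def test_bh_step_up_arithmetic(self):
        res = call_egenes(pd.DataFrame({
            "gene_id": list("abcd"),
            "beta_approx_p": [0.01, 0.02, 0.03, 0.04],
        }))
        np.testing.assert_allclose(res["qval"], 0.04)
        assert res["is_egene"].all()

    def test_single_gene(self):
        res = call_egenes(pd.DataFrame({"gene_id": ["a"],
                                        "beta_approx_p": [0.2]}))
        assert res["qval"].iloc[0] == pytest.approx(0.2)
        assert not res["is_egene"].iloc[0]

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0),
                    min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_bh_matches_brute_force_step_up(self, pvals):
        """q-values equal an independent brute-force step-up."""
        p = np.array(pvals)
        q = bh_qvalues(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        np.testing.assert_allclose(q, brute, rtol=1e-12)

    def test_significant_pairs_counting(self):
        recs = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "variant_id": ["v1", "v1", "v2", "v3"],
            "nominal_p": [1e-12, 1e-12, 1e-12, 0.9],
        })
        out, summary = call_significant_pairs(recs)
        assert summary["n_significant_pairs"] == 3
        assert summary["n_unique_eqtls"] == 2
        assert summary["targets_per_eqtl"]["v1"] == 2

    def test_one_extreme_pair_among_thousand(self, rng):
        p = rng.uniform(0.2, 1.0, 1000)
        p[123] = 1e-12
        recs = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(1000)],
            "variant_id": [f"v{i}" for i in range(1000)],
            "nominal_p": p,
        })
        out, summary = call_significant_pairs(recs)
        assert summary["n_significant_pairs"] == 1
        assert out.loc[123, "significant"]


class TestSensitivityScreen:
    def test_low_counts_and_no_significance_excluded(self, rng):
        # 2 het, 1 homalt, no association
        x = np.array([0] * 27 + [1, 1, 2], dtype=float)
        y = rng.normal(size=30)
        res = sensitivity_screen(y, x)
        assert res["het_count"] == 2 and res["homalt_count"] == 1
        if all(
            not (np.isfinite(res[k]) and res[k] < 0.05)
            for k in ("p_additive", "p_dominant", "p_recessive")
        ):
            assert res["passed"] is False

    def test_adequate_counts_pass_regardless_of_p(self, rng):
        x = np.array([0] * 20 + [1] * 50, dtype=float)  # 50 hets
        y = rng.normal(size=70)
        res = sensitivity_screen(y, x)
        assert res["passed"] is True
        # recessive recoding is constant (no homalt): reported NA
        assert np.isnan(res["p_recessive"])

    def test_significant_model_passes_with_low_counts(self):
        x = np.array([0] * 29 + [1], dtype=float)
        y = x * 5.0 + np.linspace(0, 0.1, 30)
        res = sensitivity_screen(y, x)
        assert res["het_count"] == 1 and res["homalt_count"] == 0
        assert res["p_additive"] < 0.05
        assert res["passed"] is True
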