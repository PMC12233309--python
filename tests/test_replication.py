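"""Prognostic-direction consistency, cross-cohort tiers, LD clustering."""

import numpy as np
import pandas as pd
import pytest

from survqtl import (
    classify_pair,
    classify_tier,
    cluster_loci,
    enumerate_consistent,
    ld_r2,
    match_variants,
)
from survqtl.datatypes import GenotypeMatrix
from survqtl.replication import harmonized_dosage
from survqtl.survival_screen import PrognosticSets


class TestClassifyPair:
    @pytest.mark.parametrize(
        "gene_dir,slope,variant_dir,expect",
        [
            # full 2 x 2 x 2 truth table
            ("favourable", +1.0, "favourable", True),
            ("favourable", +1.0, "unfavourable", False),
            ("favourable", -1.0, "favourable", False),
            ("favourable", -1.0, "unfavourable", True),
            ("unfavourable", +1.0, "favourable", False),
            ("unfavourable", +1.0, "unfavourable", True),
            ("unfavourable", -1.0, "favourable", True),
            ("unfavourable", -1.0, "unfavourable", False),
        ],
    )
    def test_truth_table(self, gene_dir, slope, variant_dir, expect):
        pair = classify_pair(gene_dir, slope, variant_dir)
        assert pair.consistent is expect

    def test_published_style_examples(self):
        """An unfavourable gene with negative slope and favourable variant
        is consistent, and vice versa (missense/pseudogene cases)."""
        assert classify_pair("unfavourable", -0.470105, "favourable").consistent
        assert classify_pair("favourable", -0.854169, "unfavourable").consistent

    def test_zero_slope_errors(self):
        with pytest.raises(ValueError, match="zero eQTL slope"):
            classify_pair("favourable", 0.0, "favourable")


def _variant_records(entity, entries):
    """entries: list of (inheritance, adjusted, term, coef, p)."""
    rows = []
    for inheritance, adjusted, term, coef, p in entries:
        rows.append(
            {"entity": entity, "level": "variant", "inheritance": inheritance,
             "term": term, "adjusted": adjusted, "coef": coef, "p": p,
             "se": 0.1, "hr": np.exp(coef), "ci_low": 0.1, "ci_high": 10.0,
             "n": 60, "n_events": 40, "het_count": 10, "homalt_count": 5,
             "monotone": False, "sanitized": False}
        )
    return pd.DataFrame(rows)


class TestEnumerateConsistent:
    def _progn(self, directions):
        fav = {g for g, d in directions.items() if d == "favourable"}
        unf = set(directions) - fav
        return PrognosticSets(
            unadjusted=set(directions), adjusted=set(), union=set(directions),
            favourable=fav, unfavourable=unf, directions=dict(directions),
        )

    def test_constructed_consistent_and_inconsistent(self):
        """5 consistent and 5 inconsistent pairs by sign construction:
        exactly the 5 consistent ones are recovered."""
        directions, pairs_rows, var_frames = {}, [], []
        for i in range(10):
            g, v = f"g{i}", f"v{i}"
            directions[g] = "favourable"
            slope = 1.0
            # favourable gene, positive slope -> variant must be favourable
            coef = -0.5 if i < 5 else +0.5
            pairs_rows.append(
                {"gene_id": g, "variant_id": v, "slope": slope,
                 "significant": True}
            )
            var_frames.append(
                _variant_records(v, [("allelic", False, "dosage", coef, 0.01)])
            )
        pairs, summary = enumerate_consistent(
            self._progn(directions),
            pd.DataFrame(pairs_rows),
            pd.concat(var_frames, ignore_index=True),
        )
        assert summary["n_consistent_pairs"] == 5
        assert set(pairs.loc[pairs["consistent"], "variant"]) == {
            f"v{i}" for i in range(5)
        }

    def test_empty_prognostic_set(self):
        pairs, summary = enumerate_consistent(
            PrognosticSets(set(), set(), set(), set(), set()),
            pd.DataFrame({"gene_id": ["g"], "variant_id": ["v"],
                          "slope": [1.0], "significant": [True]}),
            _variant_records("v", [("allelic", False, "dosage", 0.5, 0.01)]),
        )
        assert len(pairs) == 0

    def test_counts_inequality(self, small_cfg):
        """pairs >= max(genes, eQTLs) in any summary."""
        directions = {f"g{i}": "unfavourable" for i in range(3)}
        rows = [
            {"gene_id": f"g{i}", "variant_id": "v0", "slope": 1.0,
             "significant": True}
            for i in range(3)
        ]
        pairs, summary = enumerate_consistent(
            self._progn(directions),
            pd.DataFrame(rows),
            _variant_records("v0", [("allelic", False, "dosage", 0.5, 0.01)]),
        )
        assert (
            summary["n_consistent_pairs"]
            >= max(summary["n_consistent_genes"], summary["n_consistent_eqtls"])
        )


def _val_matrix():
    variants = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 200, 300],
            "ref": ["A", "T", "G"],
            "alt": ["T", "A", "C"],
            "rsid": [None] * 3,
        },
        index=pd.Index(["chr1_100_A_T", "chr1_200_T_A", "chr2_300_G_C"],
                       name="variant_id"),
    )
    dosage = np.array([[0, 1, 2, 1], [2, 2, 0, 1], [1, 0, 0, 2]], dtype=float)
    return GenotypeMatrix(variants=variants, samples=list("WXYZ"), dosage=dosage)


class TestMatchVariants:
    def _discovery(self, chrom, pos, ref, alt):
        return pd.DataFrame(
            {"chrom": [chrom], "pos": [pos], "ref": [ref], "alt": [alt]},
            index=pd.Index([f"{chrom}_{pos}_{ref}_{alt}"], name="variant_id"),
        )

    def test_exact_match(self):
        m = match_variants(self._discovery("chr1", 100, "A", "T"), _val_matrix())
        row = m.iloc[0]
        assert row["matched"] and not row["flipped"]
        assert row["validation_id"] == "chr1_100_A_T"

    def test_allele_swap_harmonized(self):
        """ref/alt swapped in validation: matched with dosage flip 2-d."""
        m = match_variants(self._discovery("chr1", 200, "A", "T"), _val_matrix())
        row = m.iloc[0]
        assert row["matched"] and row["flipped"]
        d = harmonized_dosage(_val_matrix(), row["validation_id"], True)
        np.testing.assert_allclose(d, [0, 0, 2, 1])

    def test_different_alt_unmatched(self):
        m = match_variants(self._discovery("chr2", 300, "G", "A"), _val_matrix())
        assert not m.iloc[0]["matched"]


class TestClassifyTier:
    def _disc(self):
        return _variant_records(
            "v", [("allelic", False, "dosage", +0.5, 0.01)]
        )

    def test_strict(self):
        val = _variant_records("v", [("allelic", False, "dosage", +0.3, 0.01)])
        assert classify_tier(self._disc(), val) == "strict"

    def test_lenient(self):
        val = _variant_records("v", [("allelic", False, "dosage", +0.3, 0.2)])
        assert classify_tier(self._disc(), val) == "lenient"

    def test_discordant(self):
        val = _variant_records("v", [("allelic", False, "dosage", -0.3, 0.01)])
        assert classify_tier(self._disc(), val) == "discordant"

    def test_unmatched(self):
        assert classify_tier(self._disc(), None) == "unmatched"
        assert classify_tier(self._disc(), pd.DataFrame()) == "unmatched"

    def test_same_model_comparison_only(self):
        """A significant validation coefficient under a different model
        does not grant strict status."""
        val = _variant_records("v", [("codominant", False, "hom", +0.5, 0.01),
                                     ("allelic", False, "dosage", +0.3, 0.2)])
        assert classify_tier(self._disc(), val) == "lenient"


class TestLd:
    def test_identical_and_anticorrelated(self):
        a = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2 - a) == pytest.approx(1.0)

    def test_allele_flip_invariance(self, rng):
        a = rng.integers(0, 3, 30).astype(float)
        b = rng.integers(0, 3, 30).astype(float)
        r2 = ld_r2(a, b)
        assert ld_r2(2 - a, b) == pytest.approx(r2)
        assert ld_r2(a, 2 - b) == pytest.approx(r2)

    def test_missing_pairs_excluded_and_min_samples(self):
        a = np.array([0, 1, 2, np.nan, 1, 0], dtype=float)
        b = np.array([0, 1, 2, 1, np.nan, 0], dtype=float)
        r2 = ld_r2(a, b, min_samples=4)
        assert r2 == pytest.approx(1.0)
        with pytest.raises(ValueError, match="jointly called"):
            ld_r2(a, b, min_samples=5)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero dosage variance"):
            ld_r2(np.zeros(10), np.arange(10, dtype=float) % 3)

    def test_chain_single_linkage(self):
        """a~b and b~c correlated, a~c not: one locus of three."""
        rng = np.random.default_rng(0)
        n = 200
        a = rng.integers(0, 3, n).astype(float)
        b = a.copy()
        flip = rng.random(n) < 0.2
        b[flip] = rng.integers(0, 3, flip.sum())
        c = b.copy()
        flip = rng.random(n) < 0.2
        c[flip] = rng.integers(0, 3, flip.sum())
        dosage = pd.DataFrame(
            np.vstack([a, b, c]),
            index=pd.Index(["a", "b", "c"], name="variant_id"),
        )
        assert ld_r2(a, c) >= 0.1  # chain via b regardless
        loci = cluster_loci(dosage, r2_threshold=0.1)
        assert loci == [["a", "b", "c"]]

    def test_independent_variants_separate_loci(self, rng):
        dosage = pd.DataFrame(
            rng.binomial(2, 0.4, size=(5, 500)).astype(float),
            index=pd.Index(list("abcde"), name="variant_id"),
        )
        loci = cluster_loci(dosage, r2_threshold=0.5)
        assert len(loci) == 5

    def test_matches_networkx_connected_components(self, rng):
        """Locus groups equal graph connected components on 20 random
        variants (independent oracle via networkx)."""
        import networkx as nx

        n, m = 20, 60
        base = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        # correlate some variants by copying with noise
        for i in range(0, n, 4):
            for j in range(1, 3):
                if i + j < n:
                    base[i + j] = base[i]
                    flip = rng.random(m) < 0.15
                    base[i + j, flip] = rng.integers(0, 3, flip.sum())
        dosage = pd.DataFrame(
            base, index=pd.Index([f"v{i}" for i in range(n)], name="variant_id")
        )
        thr = 0.1
        loci = cluster_loci(dosage, r2_threshold=thr)
        g = nx.Graph()
        g.add_nodes_from(dosage.index)
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    if ld_r2(base[i], base[j]) >= thr:
                        g.add_edge(f"v{i}", f"v{j}")
                except ValueError:
                    pass
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(grp) for grp in loci} == expected
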