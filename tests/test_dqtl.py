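"""MAF filtering, the genome-wide dependency scan, marker selection and
marker characterisation."""

import numpy as np
import pandas as pd
import pytest

from guidebias import dqtl
from guidebias.config import InputError
from guidebias.types import VariantGenotypes


def make_genotypes(dos, chrom="chr1", start=1000, step=1000):
    dos = np.asarray(dos, dtype=float)
    n_s, n_v = dos.shape
    variants = pd.DataFrame({
        "chrom": chrom, "pos0": start + np.arange(n_v) * step,
        "ref": "A", "alt": "C"})
    variants.index = pd.Index([f"v{i}" for i in range(n_v)],
                              name="variant_id")
    dosages = pd.DataFrame(dos, columns=variants.index,
                           index=pd.Index([f"s{i}" for i in range(n_s)],
                                          name="sample_id"))
    return VariantGenotypes(variants=variants, dosages=dosages)


class TestMafFilter:
    def test_rare_variant_removed_common_kept(self):
        # 100 samples: v0 has one het carrier (f=0.005), v1 is balanced
        dos = np.zeros((100, 2))
        dos[0, 0] = 1
        dos[:50, 1] = 2
        g = make_genotypes(dos)
        kept = dqtl.filter_by_maf(g, 0.01)
        assert list(kept.variants.index) == ["v1"]

    def test_boundary_is_strict(self):
        # f exactly 0.01 must be removed (strictly greater required)
        dos = np.zeros((100, 1))
        dos[0, 0] = 2
        g = make_genotypes(dos)
        assert dqtl.filter_by_maf(g, 0.01).n_variants == 0

    def test_counts_match_bruteforce_recount(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.5 * rng.random(30), size=(40, 30))
        g = make_genotypes(dos)
        kept = dqtl.filter_by_maf(g, 0.05)
        brute = 0
        for j in range(30):
            f = dos[:, j].mean() / 2
            if min(f, 1 - f) > 0.05:
                brute += 1
        assert kept.n_variants == brute


class TestScan:
    def test_perfect_signal_recovered(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
        dep = pd.Series(0.8 * dos[:, 3],
                        index=[f"s{i}" for i in range(60)])
        lineage = pd.Series("L0", index=dep.index)
        res = dqtl.dqtl_scan(dep, make_genotypes(dos), lineage)
        row = res.set_index("variant_id").loc["v3"]
        assert row["beta"] == pytest.approx(0.8)
        assert row["p"] < 1e-20

    def test_null_scan_rarely_significant(self):
        rng = np.random.default_rng(2)
        n_sig_runs = 0
        for rep in range(40):
            dos = rng.binomial(2, 0.3, size=(50, 40)).astype(float)
            dep = pd.Series(rng.normal(size=50),
                            index=[f"s{i}" for i in range(50)])
            lineage = pd.Series(rng.choice(["a", "b"], 50), index=dep.index)
            res = dqtl.dqtl_scan(dep, make_genotypes(dos), lineage)
            if res["significant"].any():
                n_sig_runs += 1
        assert n_sig_runs <= 2  # BY at 0.05 over 40 null scans

    def test_by_dominates_bh_dominates_p(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.3, size=(50, 30)).astype(float)
        dep = pd.Series(rng.normal(size=50),
                        index=[f"s{i}" for i in range(50)])
        res = dqtl.dqtl_scan(dep, make_genotypes(dos),
                             pd.Series("L0", index=dep.index))
        assert (res["q"] >= res["q_bh"] - 1e-12).all()
        assert (res["q_bh"] >= res["p"] - 1e-12).all()

    def test_constant_dosage_skipped(self):
        dos = np.ones((30, 2))
        dos[:, 1] = np.random.default_rng(4).binomial(2, 0.5, 30)
        dep = pd.Series(np.random.default_rng(5).normal(size=30),
                        index=[f"s{i}" for i in range(30)])
        res = dqtl.dqtl_scan(dep, make_genotypes(dos),
                             pd.Series("L0", index=dep.index))
        assert list(res["variant_id"]) == ["v1"]

    def test_too_few_samples_rejected(self):
        dos = np.zeros((5, 2))
        dep = pd.Series(np.arange(5.0), index=[f"s{i}" for i in range(5)])
        with pytest.raises(InputError):
            dqtl.dqtl_scan(dep, make_genotypes(dos),
                           pd.Series("L0", index=dep.index))


class TestSelectMarker:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos0",
                                           "beta", "p", "q", "significant"])

    def test_unique_minimum(self):
        res = self._results([("a", "chr1", 10, 1, 0.01, 0.02, True),
                             ("b", "chr1", 20, 1, 0.001, 0.01, True)])
        assert dqtl.select_marker(res)["variant_id"] == "b"

    def test_tie_broken_by_genomic_order(self):
        res = self._results([("b", "chr1", 20, 1, 0.01, 0.02, True),
                             ("a", "chr1", 10, 1, 0.01, 0.02, True)])
        assert dqtl.select_marker(res)["variant_id"] == "a"

    def test_none_significant_returns_none(self):
        res = self._results([("a", "chr1", 10, 1, 0.5, 0.9, False)])
        assert dqtl.select_marker(res) is None
        assert dqtl.select_marker(
            res, require_significant=False)["variant_id"] == "a"

    def test_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=30)
        res = self._results([(f"v{i}", "chr1", i * 5, 1.0, p[i],
                              p[i] * 2, True) for i in range(30)])
        best = dqtl.select_marker(res)
        brute = res.loc[res["q"].idxmin(), "variant_id"]
        assert best["variant_id"] == brute


class TestAncestryMaf:
    def test_hand_counted_toy_table(self):
        dos = np.array([[2], [1], [0], [0], [0], [np.nan]])
        g = make_genotypes(dos)
        labels = pd.Series(["AFR", "AFR", "EUR", "EUR", "EAS", "EAS"],
                           index=g.samples)
        freqs, diff, flag = dqtl.ancestry_maf("v0", g, labels)
        assert freqs["AFR"] == pytest.approx(0.75)  # (2+1)/4
        assert freqs["EUR"] == 0.0
        assert freqs["EAS"] == 0.0  # one NaN dropped
        assert diff == pytest.approx(0.75)
        assert flag

    def test_equal_frequencies_not_flagged(self):
        dos = np.tile([[1.0]], (6, 1))
        g = make_genotypes(dos)
        labels = pd.Series(["AFR", "AFR", "EUR", "EUR", "EAS", "EAS"],
                           index=g.samples)
        _, diff, flag = dqtl.ancestry_maf("v0", g, labels)
        assert diff == 0.0 and not flag

    def test_flag_invariant_under_allele_swap(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, 0.4, size=(40, 1)).astype(float)
        g = make_genotypes(dos)
        g_swapped = make_genotypes(2 - dos)
        labels = pd.Series(rng.choice(["AFR", "EUR", "EAS"], 40),
                           index=g.samples)
        _, d1, f1 = dqtl.ancestry_maf("v0", g, labels)
        _, d2, f2 = dqtl.ancestry_maf("v0", g_swapped, labels)
        assert d1 == pytest.approx(d2)
        assert f1 == f2

    def test_paper_style_example(self):
        # AFR 0.5 vs EUR 0.1 -> differential 0.4 -> flagged
        dos = np.array([[1], [1], [0], [0], [0], [1], [0], [0], [0], [0]],
                       dtype=float)
        g = make_genotypes(dos)
        labels = pd.Series(["AFR"] * 2 + ["EUR"] * 5 + ["EAS"] * 3,
                           index=g.samples)
        freqs, diff, flag = dqtl.ancestry_maf("v0", g, labels)
        assert freqs["AFR"] == pytest.approx(0.5)
        assert freqs["EUR"] == pytest.approx(0.1)
        assert flag


class TestProximal:
    @pytest.mark.parametrize("mc,mp,tc,tp,expect", [
        ("chr1", 500_000, "chr1", 0, True),
        ("chr1", 1_000_000, "chr1", 0, False),  # boundary: strictly less
        ("chr2", 10, "chr1", 0, False),
    ])
    def test_rule(self, mc, mp, tc, tp, expect):
        prox, _ = dqtl.classify_proximal(mc, mp, tc, tp)
        assert prox is expect

    def test_cross_chromosome_distance_infinite(self):
        _, dist = dqtl.classify_proximal("chr2", 10, "chr1", 0)
        assert np.isinf(dist)


class TestEqtl:
    def test_null_association_flat(self):
        rng = np.random.default_rng(8)
        dos = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        g = make_genotypes(dos)
        expr = pd.Series(rng.normal(size=100), index=g.samples)
        lin = pd.Series("L0", index=g.samples)
        res = dqtl.eqtl_test("v0", g, expr, lin)
        assert abs(res["beta"]) < 0.5 and res["p"] > 0.001

    def test_simulated_eqtl_detected(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        g = make_genotypes(dos)
        expr = pd.Series(2.0 * (dos[:, 0] >= 1)
                         + rng.normal(0, 0.5, 100), index=g.samples)
        res = dqtl.eqtl_test("v0", g, expr,
                             pd.Series("L0", index=g.samples))
        assert res["p"] < 0.001

    def test_het_and_hom_collapse_to_presence(self):
        rng = np.random.default_rng(10)
        dos = np.array([[0]] * 10 + [[1]] * 10 + [[2]] * 10, dtype=float)
        g = make_genotypes(dos)
        expr = pd.Series(np.where(dos[:, 0] >= 1, 1.0, 0.0)
                         + rng.normal(0, 0.01, 30), index=g.samples)
        res = dqtl.eqtl_test("v0", g, expr,
                             pd.Series("L0", index=g.samples))
        # presence coding: beta ~ 1 (not ~0.5 as additive coding would give)
        assert res["beta"] == pytest.approx(1.0, abs=0.05)
        assert res["n_present"] == 20

    def test_single_class_missing(self):
        dos = np.ones((10, 1))
        g = make_genotypes(dos)
        expr = pd.Series(np.arange(10.0), index=g.samples)
        assert dqtl.eqtl_test("v0", g, expr,
                              pd.Series("L0", index=g.samples)) is None


class TestLd:
    def test_identical_vectors(self):
        assert dqtl.ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        assert dqtl.ld_r2([0, 0, 1, 1, 2, 2],
                          [2, 2, 1, 1, 0, 0]) == pytest.approx(1.0)

    def test_independent_variants_null_expectation(self):
        rng = np.random.default_rng(11)
        n = 30
        r2s = [dqtl.ld_r2(rng.binomial(2, 0.5, n).astype(float),
                          rng.binomial(2, 0.5, n).astype(float))
               for _ in range(500)]
        r2s = [r for r in r2s if np.isfinite(r)]
        # E[r^2] = 1/(n-1) for independent vectors
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), rel=0.3)

    def test_constant_vector_missing(self):
        assert np.isnan(dqtl.ld_r2([1, 1, 1], [0, 1, 2]))


class TestWeakExpression:
    def test_worked_toy_matrix(self):
        expr = pd.DataFrame({
            "zero": [0.0, 0.0, 0.0],
            "boundary": [5.0, 5.0, 5.0],   # median exactly 5: not flagged
            "low": [1.0, 2.0, 3.0],
            "high": [100.0, 90.0, 80.0],
            "mixed": [0.0, 0.0, 50.0],
        })
        flags, frac = dqtl.weak_expression_fraction(expr, 5.0)
        assert flags.to_dict() == {"zero": True, "boundary": False,
                                   "low": True, "high": False,
                                   "mixed": True}
        assert frac == pytest.approx(3 / 5)
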