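"""LMM association scan, conditional analysis, thresholds and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from founderlip.genotypes import GenotypeMatrix, Variant
from founderlip.gwas import (association_scan, bonferroni_threshold,
                             classify_significance, conditional_scan,
                             genomic_control_lambda,
                             multiple_testing_threshold, parse_region,
                             records_to_frame, replication_exclusion_power,
                             threshold_from_pc_count)
from founderlip.pedigree import RelatednessMatrix
from founderlip.phenotypes import TraitMatrix
from founderlip.simulate import scaled_component


def _unrelated(n=80, m=5, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    K = RelatednessMatrix(ids, 0.5 * np.eye(n), "kinship")
    dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    g = GenotypeMatrix(ids, [Variant("1", 1000 * (k + 1), "A", "G", f"v{k}")
                             for k in range(m)], dos)
    y = rng.standard_normal(n)
    vals = pd.DataFrame({"t": y}, index=ids)
    tm = TraitMatrix(vals, pd.DataFrame(index=vals.index))
    tm.prepared = vals
    return K, g, tm, y, dos


class TestAssociationScan:
    def test_equals_ols_for_unrelated_subjects(self):
        """With an identity-proportional kinship the scan reduces to
        per-variant ordinary least squares (closed-form oracle)."""
        K, g, tm, y, dos = _unrelated()
        n = len(y)
        for rec, k in zip(association_scan("t", g, K, tm), range(5)):
            X = np.column_stack([np.ones(n), dos[:, k]])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert rec.beta == pytest.approx(beta[1], rel=1e-8, abs=1e-12)
            assert rec.se == pytest.approx(se, rel=1e-8)
            assert rec.p == pytest.approx(p, rel=1e-8)

    def test_allele_flip_negates_beta(self):
        K, g, tm, y, dos = _unrelated()
        flipped = GenotypeMatrix(
            g.ids,
            [Variant(v.chrom, v.pos, v.alt, v.ref, v.rsid)
             for v in g.variants],
            2.0 - dos)
        a = association_scan("t", g, K, tm)
        b = association_scan("t", flipped, K, tm)
        for ra, rb in zip(a, b):
            assert ra.beta == pytest.approx(-rb.beta, rel=1e-10)
            assert ra.p == pytest.approx(rb.p, rel=1e-10)

    def test_joint_subject_permutation_invariance(self, pop200):
        rng = np.random.default_rng(1)
        n = pop200.n
        y = scaled_component(pop200.chol_additive, 0.4, rng) \
            + scaled_component(np.eye(n), 0.6, rng)
        dos = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        g = GenotypeMatrix(pop200.subjects,
                           [Variant("1", 1000 * (k + 1), "A", "G", f"v{k}")
                            for k in range(3)], dos)
        tm = pop200.trait_matrix({"t": y})
        p0 = [r.p for r in association_scan("t", g, pop200.kinship, tm)]
        perm = rng.permutation(n)
        subj_p = [pop200.subjects[i] for i in perm]
        g_p = GenotypeMatrix(subj_p, g.variants, dos[perm])
        tm_p = pop200.trait_matrix({})
        vals = pd.DataFrame({"t": y[perm]}, index=subj_p)
        tm_p = TraitMatrix(vals, pd.DataFrame(index=vals.index))
        tm_p.prepared = vals
        K_p = pop200.kinship.subset(subj_p)
        p1 = [r.p for r in association_scan("t", g_p, K_p, tm_p)]
        assert np.allclose(p0, p1, rtol=1e-6)

    def test_monomorphic_and_collinear_skipped(self):
        K, g, tm, y, dos = _unrelated()
        dup = GenotypeMatrix(
            g.ids,
            g.variants + [Variant("1", 99_000, "A", "G", "dup0"),
                          Variant("1", 99_500, "A", "G", "mono")],
            np.column_stack([dos, dos[:, 0], np.zeros(len(y))]))
        recs = association_scan("t", dup, K, tm, conditioning=["v0"])
        by_id = {r.rsid: r for r in recs}
        assert by_id["dup0"].skipped == "collinear"
        assert by_id["v0"].skipped == "collinear"
        assert by_id["mono"].skipped == "monomorphic"

    def test_injected_effect_is_genome_wide_significant(self, pop600):
        """A 1.2 SD effect at MAF ~0.06 (the scale of the largest
        drifted-variant effects) clears the adjusted threshold."""
        rng = np.random.default_rng(2)
        n = pop600.n
        hits = 0
        for rep in range(10):
            snp = rng.binomial(2, 0.06, size=n).astype(float)
            y = scaled_component(pop600.chol_additive, 0.4, rng) \
                + scaled_component(np.eye(n), 0.6, rng) + 1.2 * snp
            g = GenotypeMatrix(pop600.subjects,
                               [Variant("1", 1000, "A", "G", "causal")],
                               snp[:, None])
            tm = pop600.trait_matrix({"t": y})
            rec = association_scan("t", g, pop600.kinship, tm)[0]
            hits += rec.p < 4.5e-10
        assert hits >= 9


class TestConditionalScan:
    def test_no_signal_returns_empty(self, pop200):
        rng = np.random.default_rng(3)
        n = pop200.n
        y = rng.standard_normal(n)
        dos = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        g = GenotypeMatrix(pop200.subjects,
                           [Variant("1", 1000 * (k + 1), "A", "G", f"v{k}")
                            for k in range(4)], dos)
        tm = pop200.trait_matrix({"t": y})
        res = conditional_scan("t", g, pop200.kinship, tm, alpha=5e-8)
        assert res.signals == []

    def test_region_parsing(self):
        assert parse_region("2:999-2000") == ("2", 1000, 2000)

    def test_unassociated_conditioner_barely_moves_pvalues(self, pop600):
        rng = np.random.default_rng(4)
        n = pop600.n
        snp = rng.binomial(2, 0.2, size=n).astype(float)
        null_snp = rng.binomial(2, 0.3, size=n).astype(float)
        y = scaled_component(pop600.chol_additive, 0.4, rng) \
            + scaled_component(np.eye(n), 0.6, rng) + 0.4 * snp
        g = GenotypeMatrix(
            pop600.subjects,
            [Variant("1", 1000, "A", "G", "causal"),
             Variant("9", 5000, "A", "G", "far")],
            np.column_stack([snp, null_snp]))
        tm = pop600.trait_matrix({"t": y})
        p0 = records_to_frame(
            association_scan("t", g, pop600.kinship, tm))
        p1 = records_to_frame(
            association_scan("t", g, pop600.kinship, tm,
                             conditioning=["far"]))
        shift = abs(np.log10(p1.loc[0, "p"]) - np.log10(p0.loc[0, "p"]))
        assert shift < 0.5


class TestThresholds:
    def test_perfectly_correlated_traits_need_one_pc(self, pop200):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(pop200.n)
        tm = pop200.trait_matrix(
            {f"t{k}": base * (k + 1) for k in range(4)})
        th = multiple_testing_threshold(tm)
        assert th.pc_count == 1
        assert th.significance_threshold == th.base_level

    def test_printed_pc_count_reproduces_printed_threshold(self):
        th = threshold_from_pc_count(355, 110)
        # equality at the printed precision (two significant digits)
        assert float(f"{th.significance_threshold:.1e}") == 4.5e-10
        assert th.suggestive_threshold == 5e-8

    def test_independent_traits_need_all_pcs(self):
        """10 independent traits at large n: population eigenvalues are
        all 1, so 9 components only reach 90% < 95%."""
        rng = np.random.default_rng(6)
        n = 10_000
        ids = [f"s{i}" for i in range(n)]
        vals = pd.DataFrame(rng.standard_normal((n, 10)),
                            index=ids,
                            columns=[f"t{k}" for k in range(10)])
        tm = TraitMatrix(vals, pd.DataFrame(index=vals.index))
        tm.prepared = vals
        th = multiple_testing_threshold(tm)
        assert th.pc_count == 10
        assert th.significance_threshold == pytest.approx(5e-9)

    def test_too_few_complete_cases(self, pop200):
        rng = np.random.default_rng(7)
        vals = {f"t{k}": rng.standard_normal(pop200.n)
                for k in range(pop200.n + 5)}
        tm = pop200.trait_matrix(vals)
        with pytest.raises(ValueError, match="subset"):
            multiple_testing_threshold(tm)

    def test_bonferroni(self):
        assert bonferroni_threshold(0.05, 702) == pytest.approx(
            0.05 / 702)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_significance_bands_partition(self):
        th = threshold_from_pc_count(355, 110)
        p = np.array([1e-12, 1e-9, 1e-7, 0.5])
        bands = classify_significance(p, th)
        assert list(bands) == ["significant", "suggestive", "ns", "ns"]


class TestReplicationPower:
    def test_null_effect_gives_size(self):
        assert replication_exclusion_power(0.0, 0.1, 500, 0.05) \
            == pytest.approx(0.05)

    def test_extreme_noncentrality_saturates(self):
        # beta*sqrt(2 maf (1-maf) n) = 10
        maf, n = 0.1, 1000
        beta = 10 / np.sqrt(2 * maf * (1 - maf) * n)
        assert replication_exclusion_power(beta, maf, n, 0.05) > 0.999

    def test_winners_curse_halving_reduces_power(self):
        full = replication_exclusion_power(0.3, 0.1, 800, 0.05, 1.0)
        half = replication_exclusion_power(0.3, 0.1, 800, 0.05, 0.5)
        assert half < full

    @pytest.mark.parametrize("kwargs", [
        {"beta": 0.5, "maf": 0.7, "n": 100, "alpha": 0.05},
        {"beta": 0.5, "maf": 0.1, "n": 1, "alpha": 0.05},
        {"beta": 0.5, "maf": 0.1, "n": 100, "alpha": 1.5},
    ])
    def test_out_of_range_inputs(self, kwargs):
        with pytest.raises(ValueError):
            replication_exclusion_power(**kwargs)


def test_genomic_control_lambda_near_one_under_null():
    rng = np.random.default_rng(8)
    p = rng.uniform(size=20_000)
    assert 0.95 < genomic_control_lambda(p) < 1.05
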