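"""Variance-component engine: REML/ML fits, LRTs, sequential selection."""

import numpy as np
import pytest

from founderlip.genotypes import class_covariance
from founderlip.pedigree import RelatednessMatrix
from founderlip.varcomp import (FitControl, NonIdentifiableError,
                                VarCompModel, fit_reml,
                                fit_variance_components, lrt_compare,
                                sequential_component_selection,
                                variance_proportions)
from founderlip.simulate import scaled_component, _chol_psd

import pandas as pd


def _grid_reml_loglik(y, X, A, s2a, s2e):
    """Independent dense evaluation of the restricted log-likelihood."""
    n, p = X.shape
    V = s2a * A + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldC = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldC + y @ P @ y)


class TestFitReml:
    def test_identity_component_is_not_identifiable(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        I = RelatednessMatrix([f"s{i}" for i in range(30)], np.eye(30),
                              "grm")
        with pytest.raises(NonIdentifiableError):
            fit_reml(y, None, [("dup", I)])

    def test_matches_grid_search_on_small_pedigree(self, pop200):
        """Grid-plus-refinement maximization of the restricted likelihood
        lands on the same estimates as AI-REML (12 subjects)."""
        subj = pop200.subjects[:12]
        A = pop200.additive.subset(subj)
        rng = np.random.default_rng(1)
        L = _chol_psd(A.values)
        y = 0.8 * (L @ rng.standard_normal(12)) + rng.standard_normal(12)
        X = np.ones((12, 1))
        fit = fit_reml(y, X, [("additive", A)])

        coarse = np.linspace(1e-6, 4.0, 200)
        best = max(((_grid_reml_loglik(y, X, A.values, a, b), a, b)
                    for a in coarse for b in coarse))
        fine_a = np.linspace(max(best[1] - 0.05, 1e-8), best[1] + 0.05, 120)
        fine_b = np.linspace(max(best[2] - 0.05, 1e-8), best[2] + 0.05, 120)
        best = max(((_grid_reml_loglik(y, X, A.values, a, b), a, b)
                    for a in fine_a for b in fine_b))
        assert abs(fit.sigma2[0] - best[1]) < 1e-3
        assert abs(fit.sigma2_e - best[2]) < 1e-3
        assert fit.loglik >= best[0] - 1e-8

    def test_matches_balanced_sib_anova(self, balanced_sib_pedigree):
        """Closed-form one-way ANOVA (sib correlation) estimator equals
        REML for balanced full-sib families with interior estimates."""
        from founderlip.pedigree import kinship_matrix
        ped, offspring = balanced_sib_pedigree
        A = RelatednessMatrix(offspring,
                              2 * kinship_matrix(ped, offspring).values,
                              "additive")
        rng = np.random.default_rng(2)
        L = _chol_psd(A.values)
        y = np.sqrt(0.6) * (L @ rng.standard_normal(200)) \
            + np.sqrt(0.4) * rng.standard_normal(200)
        fit = fit_reml(y, None, [("additive", A)])
        Y = y.reshape(50, 4)
        msb = 4 * ((Y.mean(1) - Y.mean()) ** 2).sum() / 49
        msw = ((Y - Y.mean(1, keepdims=True)) ** 2).sum() / 150
        s2b = (msb - msw) / 4
        assert s2b > 0  # interior
        assert abs(fit.sigma2[0] - 2 * s2b) < 1e-6
        assert abs(fit.sigma2_e - (msw - s2b)) < 1e-6

    def test_shift_and_reparameterization_invariance(self, pop200):
        subj = pop200.subjects[:80]
        A = pop200.additive.subset(subj)
        rng = np.random.default_rng(3)
        L = _chol_psd(A.values)
        y = L @ rng.standard_normal(80) + rng.standard_normal(80)
        x = rng.standard_normal(80)
        X1 = np.column_stack([np.ones(80), x])
        X2 = np.column_stack([2 * np.ones(80), 3 * x + 5])  # same span
        f0 = fit_reml(y, X1, [("additive", A)])
        f1 = fit_reml(y + 7.5, X1, [("additive", A)])
        f2 = fit_reml(y, X2, [("additive", A)])
        assert abs(f0.sigma2[0] - f1.sigma2[0]) < 1e-8
        assert abs(f0.sigma2[0] - f2.sigma2[0]) < 1e-8
        assert abs(f0.sigma2_e - f2.sigma2_e) < 1e-8

    def test_fitted_covariance_is_positive_definite(self, pop200):
        subj = pop200.subjects[:100]
        A = pop200.additive.subset(subj)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(100)
        fit = fit_reml(y, None, [("additive", A)])
        V = fit.sigma2[0] * A.values + fit.sigma2_e * np.eye(100)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_boundary_fit_is_flagged_and_zero(self, pop200):
        # independent noise: additive component collapses to the boundary
        # for some draws; find one and check the flag
        A = pop200.additive
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.standard_normal(pop200.n)
            fit = fit_reml(y, None, [("additive", A)])
            if fit.boundary:
                assert fit.sigma2[0] == 0.0
                assert "additive" in fit.boundary
                break
        else:
            pytest.fail("no boundary fit in 20 null draws")

    def test_ml_and_reml_converge_with_n(self, pop600):
        """ML is biased downward in small samples; the ML-REML gap in
        h2 shrinks as n grows."""
        rng = np.random.default_rng(6)
        gaps = []
        for n_sub in (60, 600):
            subj = pop600.subjects[:n_sub]
            A = pop600.additive.subset(subj)
            L = _chol_psd(A.values)
            gap = []
            for _ in range(10):
                y = scaled_component(L, 0.5, rng) \
                    + scaled_component(np.eye(n_sub), 0.5, rng)
                fr = fit_reml(y, None, [("additive", A)])
                fm = fit_reml(y, None, [("additive", A)], method="ML")
                gap.append(abs(fr.lambdas["additive"]
                               - fm.lambdas["additive"]))
            gaps.append(np.mean(gap))
        assert gaps[1] < gaps[0]

    def test_null_effect_covariate_leaves_h2_unchanged(self, pop600):
        """Adding a genotype fixed effect with true effect 0 (the
        enriched-variant adjustment pattern) does not shift h2."""
        subj = pop600.subjects
        A = pop600.additive
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(10):
            y = scaled_component(pop600.chol_additive, 0.5, rng) \
                + scaled_component(np.eye(pop600.n), 0.5, rng)
            snp = rng.binomial(2, 0.2, size=pop600.n).astype(float)
            f0 = fit_reml(y, None, [("additive", A)])
            f1 = fit_reml(y, np.column_stack([np.ones(pop600.n), snp]),
                          [("additive", A)])
            diffs.append(f1.lambdas["additive"] - f0.lambdas["additive"])
        assert abs(np.mean(diffs)) < 0.02


class TestLrt:
    def _two_fits(self, pop200, seed=8):
        subj = pop200.subjects[:100]
        A = pop200.additive.subset(subj)
        rng = np.random.default_rng(seed)
        y = (_chol_psd(A.values) @ rng.standard_normal(100)) * 0.7 \
            + rng.standard_normal(100)
        null = fit_reml(y, None, [])
        alt = fit_reml(y, None, [("additive", A)])
        return null, alt

    def test_equal_likelihoods_give_p_one(self, pop200):
        null, _ = self._two_fits(pop200)
        stat, p = lrt_compare(null, null)
        assert stat == 0.0
        assert p == 1.0

    def test_mixture_quantile_arithmetic(self, pop200):
        null, alt = self._two_fits(pop200)
        alt.loglik = null.loglik + 2.706 / 2
        stat, p = lrt_compare(null, alt)
        assert stat == pytest.approx(2.706)
        assert p == pytest.approx(0.05, abs=2e-4)  # half the chi2(1) tail
        _, p_plain = lrt_compare(null, alt, null_dist="chisq")
        assert p_plain == pytest.approx(0.10, abs=4e-4)

    def test_mismatched_methods_rejected(self, pop200):
        null, alt = self._two_fits(pop200)
        null.method = "ML"
        with pytest.raises(ValueError, match="same likelihood"):
            lrt_compare(null, alt)

    def test_reml_with_different_fixed_effects_rejected(self, pop200):
        null, alt = self._two_fits(pop200)
        null.fixed_signature = ("intercept", "snp:x")
        with pytest.raises(ValueError, match="fixed effects"):
            lrt_compare(null, alt)


class TestProportions:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(9)
        n = 60
        ids = [f"s{i}" for i in range(n)]
        M = rng.standard_normal((n, 5))
        K = RelatednessMatrix(ids, M @ M.T / 5 + 0.5 * np.eye(n), "grm")
        y = rng.standard_normal(n)
        fit = fit_reml(y, None, [("grm", K)])
        lam = variance_proportions(fit)
        total = sum(v for k, v in lam.items() if k not in ("h2",))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pure_residual_heritability_is_zero(self):
        rng = np.random.default_rng(10)
        fit = fit_reml(rng.standard_normal(40), None, [])
        assert variance_proportions(fit)["h2"] == 0.0


class TestSequentialSelection:
    @staticmethod
    def _data_and_components(pop200, seed, lam_tag=0.3):
        """A trait whose only non-kinship structure is a TAG-species
        covariance block."""
        rng = np.random.default_rng(seed)
        n = pop200.n
        species = {f"TAG_{k}": rng.standard_normal(n) for k in range(6)}
        other = {f"PC_{k}": rng.standard_normal(n) for k in range(6)}
        S_tag = class_covariance(pd.DataFrame(species,
                                              index=pop200.subjects))
        S_pc = class_covariance(pd.DataFrame(other, index=pop200.subjects))
        y = scaled_component(_chol_psd(S_tag.values), lam_tag, rng) \
            + scaled_component(pop200.chol_additive, 0.2, rng) \
            + scaled_component(np.eye(n), 1 - lam_tag - 0.2, rng)
        tm = pop200.trait_matrix({"trait": y})
        base = VarCompModel("trait", [("additive", pop200.additive)])
        return tm, base, [("TAG", S_tag), ("PC", S_pc)]

    def test_signal_class_selected_first(self, pop200):
        wins = 0
        for rep in range(20):
            tm, base, cands = self._data_and_components(pop200, 100 + rep)
            res = sequential_component_selection(base, cands, tm,
                                                 alpha=0.05)
            wins += bool(res.selected and res.selected[0] == "TAG")
        assert wins >= 18

    def test_no_signal_returns_base_model(self, pop200):
        rng = np.random.default_rng(11)
        tm = pop200.trait_matrix(
            {"trait": rng.standard_normal(pop200.n)})
        base = VarCompModel("trait", [("additive", pop200.additive)])
        cands = []
        res = sequential_component_selection(base, cands, tm, alpha=0.05)
        assert res.selected == []
        assert res.final_fit.component_names == ["additive"]

    def test_selection_trace_is_monotone(self, pop200):
        tm, base, cands = self._data_and_components(pop200, 42)
        res = sequential_component_selection(base, cands, tm, alpha=0.05)
        for step in res.steps[:-1]:
            assert step.accepted and step.p_value < 0.05
        if res.steps and not res.steps[-1].accepted:
            assert not (res.steps[-1].p_value < 0.05)


def test_fit_variance_components_drops_missing_subjects(pop200):
    rng = np.random.default_rng(12)
    y = rng.standard_normal(pop200.n)
    y[:10] = np.nan
    tm = pop200.trait_matrix({"trait": y})
    fit = fit_variance_components(
        VarCompModel("trait", [("additive", pop200.additive)]), tm)
    assert fit.n == pop200.n - 10
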