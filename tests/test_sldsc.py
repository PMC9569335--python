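"""The stratified LD-score regression engine.

Statistical checks draw chi-square statistics directly from the model
E[chi2_j] = 1 + N sum_C tau_C l(j,C) with synthesized LD-score tables, so
the engine is tested against its own generative assumption at scale; the
panel-based route is covered in the synthetic-data and acceptance suites.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epienrich.sldsc import (
    RegressionResult,
    coefficient_difference_test,
    fit_conditional,
    fit_sldsc,
    heritability_summary,
)


def _ld_table(rng, m, names, base=1.0, scale=4.0):
    data = {n: base + scale * rng.uniform(size=m) for n in names}
    return pd.DataFrame(data, index=[f"rs{i}" for i in range(m)])


def _draw_chisq(rng, ld, tau_map, n_gwas):
    lam = np.ones(len(ld))
    for name, tau in tau_map.items():
        lam += n_gwas * tau * ld[name].to_numpy()
    return lam * rng.chisquare(1, size=len(ld))


class TestFitSldsc:
    def test_point_estimates_equal_normal_equations_solve(self):
        rng = np.random.default_rng(20)
        ld = _ld_table(rng, 300, ["a", "b"])
        y = _draw_chisq(rng, ld, {"a": 1e-5}, 10_000)
        res = fit_sldsc(y, 10_000, ld, ["a", "b"], n_blocks=10,
                        use_weights=False)
        X = np.column_stack([10_000 * ld["a"], 10_000 * ld["b"],
                             np.ones(300)])
        theta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.tau, theta[:2], rtol=1e-8)
        assert res.intercept == pytest.approx(theta[2], rel=1e-8)

    def test_null_recovery_tau_zero_intercept_one(self):
        rng = np.random.default_rng(21)
        ld = _ld_table(rng, 20_000, ["a"])
        y = _draw_chisq(rng, ld, {}, 50_000)
        res = fit_sldsc(y, 50_000, ld, ["a"], n_blocks=200)
        assert abs(res.tau[0]) < 3 * res.se[0]
        assert abs(res.intercept - 1.0) < 3 * res.intercept_se

    @pytest.mark.parametrize("use_weights", [True, False])
    def test_recovers_planted_tau(self, use_weights):
        # weighting affects efficiency, not consistency
        tau_true = 5e-6
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ld = _ld_table(rng, 20_000, ["a"])
            y = _draw_chisq(rng, ld, {"a": tau_true}, 50_000)
            res = fit_sldsc(y, 50_000, ld, ["a"], n_blocks=200,
                            use_weights=use_weights)
            hits += abs(res.tau[0] - tau_true) < 3 * res.se[0]
        assert hits >= 18

    def test_one_sided_p_is_uniform_under_null(self):
        rng = np.random.default_rng(22)
        pvals = []
        for _ in range(200):
            ld = _ld_table(rng, 2000, ["a"])
            y = _draw_chisq(rng, ld, {}, 50_000)
            res = fit_sldsc(y, 50_000, ld, ["a"], n_blocks=50)
            pvals.append(res.p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_columns_named_in_error(self):
        rng = np.random.default_rng(23)
        ld = _ld_table(rng, 100, ["a"])
        ld["b"] = ld["a"] * 2.0
        y = rng.chisquare(1, 100)
        with pytest.raises(ValueError, match="collinear.*b"):
            fit_sldsc(y, 1000, ld, ["a", "b"], n_blocks=5)

    def test_too_few_variants_reduces_blocks_with_warning(self):
        rng = np.random.default_rng(24)
        ld = _ld_table(rng, 40, ["a"])
        y = _draw_chisq(rng, ld, {}, 1000)
        with pytest.warns(UserWarning, match="reducing jackknife blocks"):
            res = fit_sldsc(y, 1000, ld, ["a"], n_blocks=200)
        assert res.n_blocks == 20

    def test_jackknife_se_shrinks_as_sqrt_n(self):
        # log-log slope of SE vs n_variants should be about -1/2
        sizes = [5000, 10_000, 20_000, 40_000]
        ses = []
        for m in sizes:
            reps = []
            for seed in range(5):
                rng = np.random.default_rng(1000 * m + seed)
                ld = _ld_table(rng, m, ["a"])
                y = _draw_chisq(rng, ld, {"a": 5e-6}, 50_000)
                reps.append(fit_sldsc(y, 50_000, ld, ["a"],
                                      n_blocks=200).se[0])
            ses.append(np.mean(reps))
        slope = np.polyfit(np.log(sizes), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestFitConditional:
    def test_empty_conditioning_reduces_to_unconditional_fit(self):
        rng = np.random.default_rng(25)
        ld = _ld_table(rng, 500, ["a"])
        y = _draw_chisq(rng, ld, {"a": 1e-5}, 10_000)
        res1 = fit_sldsc(y, 10_000, ld, ["a"], n_blocks=20)
        res2 = fit_conditional(y, 10_000, ld, "a", [], n_blocks=20)
        np.testing.assert_allclose(res1.tau, res2.tau)
        assert res2.target == "a"

    def test_target_in_conditioning_set_rejected(self):
        rng = np.random.default_rng(26)
        ld = _ld_table(rng, 100, ["a", "b"])
        with pytest.raises(ValueError, match="conditioning"):
            fit_conditional(rng.chisquare(1, 100), 1000, ld, "a", ["a", "b"])

    def test_independent_conditioning_leaves_target_unchanged(self):
        # conditioning on an annotation with independent LD scores moves
        # the target coefficient by less than 1 SE (paired simulation)
        rng = np.random.default_rng(27)
        within = 0
        for _ in range(20):
            ld = _ld_table(rng, 10_000, ["a", "b"])
            y = _draw_chisq(rng, ld, {"a": 5e-6}, 50_000)
            uncond = fit_sldsc(y, 50_000, ld, ["a"], n_blocks=100)
            cond = fit_conditional(y, 50_000, ld, "a", ["b"], n_blocks=100)
            if abs(cond.tau[0] - uncond.tau[0]) < uncond.se[0]:
                within += 1
        assert within >= 18

    def test_conditioning_on_causal_annotation_attenuates_overlap(self):
        # a non-causal annotation correlated with the causal one loses its
        # apparent signal once the causal annotation enters the model
        rng = np.random.default_rng(28)
        attenuated = 0
        n_reps = 50
        for _ in range(n_reps):
            m = 5000
            causal = 1.0 + 4.0 * rng.uniform(size=m)
            # overlap: target LD scores share half their variation
            target = 0.5 * causal + 0.5 * (1.0 + 4.0 * rng.uniform(size=m))
            ld = pd.DataFrame({"causal": causal, "target": target},
                              index=[f"rs{i}" for i in range(m)])
            y = _draw_chisq(rng, ld, {"causal": 5e-6}, 50_000)
            uncond = fit_sldsc(y, 50_000, ld, ["target"], n_blocks=50)
            cond = fit_conditional(y, 50_000, ld, "target", ["causal"],
                                   n_blocks=50)
            if cond.tau[0] < uncond.tau[0]:
                attenuated += 1
        p = stats.binomtest(attenuated, n_reps, alternative="greater").pvalue
        assert p < 0.01


class TestCoefficientDifference:
    def _result(self, tau, se, name="a"):
        tau, se = np.array([tau]), np.array([se])
        return RegressionResult([name], tau, se, tau / se,
                                stats.norm.sf(tau / se), 1.0, 0.1, 100, 10)

    def test_equal_coefficients_give_z_zero_p_half(self):
        z, p = coefficient_difference_test(
            self._result(2e-6, 1e-6), self._result(2e-6, 1e-6), "a")
        assert z == 0.0 and p == pytest.approx(0.5)

    def test_closed_form_example(self):
        z, p = coefficient_difference_test(
            self._result(2e-6, 1e-6), self._result(0.0, 1e-6), "a")
        assert z == pytest.approx(2 / np.sqrt(2), abs=1e-4)
        assert p == pytest.approx(0.0786, abs=5e-4)

    def test_antisymmetric_under_argument_swap(self):
        r1, r2 = self._result(3e-6, 1e-6), self._result(1e-6, 2e-6)
        z12, p12 = coefficient_difference_test(r1, r2, "a")
        z21, p21 = coefficient_difference_test(r2, r1, "a")
        assert z21 == pytest.approx(-z12)
        assert p21 == pytest.approx(1 - p12)

    def test_missing_annotation_raises(self):
        with pytest.raises(KeyError):
            coefficient_difference_test(self._result(1e-6, 1e-6),
                                        self._result(1e-6, 1e-6), "zzz")


class TestHeritabilitySummary:
    def test_zero_tau_gives_zero_h2(self):
        rng = np.random.default_rng(29)
        ld = _ld_table(rng, 200, ["a"])
        res = fit_sldsc(rng.chisquare(1, 200), 1000, ld, ["a"], n_blocks=10)
        res.tau = np.zeros_like(res.tau)
        res.jackknife_estimates = np.zeros_like(res.jackknife_estimates)
        h = heritability_summary(res, {"a": 500})
        assert h.h2 == 0.0

    def test_scale_identity(self):
        # doubling every |C| with tau halved leaves h2 unchanged
        rng = np.random.default_rng(30)
        ld = _ld_table(rng, 500, ["a", "b"])
        y = _draw_chisq(rng, ld, {"a": 1e-5}, 10_000)
        res = fit_sldsc(y, 10_000, ld, ["a", "b"], n_blocks=20)
        h1 = heritability_summary(res, {"a": 100, "b": 200})
        res2 = RegressionResult(
            res.annotations, res.tau / 2, res.se, res.z, res.p,
            res.intercept, res.intercept_se, res.n_variants, res.n_blocks,
            res.jackknife_estimates.copy())
        res2.jackknife_estimates[:, :-1] /= 2
        h2 = heritability_summary(res2, {"a": 200, "b": 400})
        assert h2.h2 == pytest.approx(h1.h2, rel=1e-12)

    def test_recovers_planted_total_heritability(self):
        # analytic-model data: h2 = tau * |C| with |C| the annotated count
        tau_true, m = 5e-6, 20_000
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            ld = _ld_table(rng, m, ["a"])
            y = _draw_chisq(rng, ld, {"a": tau_true}, 50_000)
            res = fit_sldsc(y, 50_000, ld, ["a"], n_blocks=200)
            h = heritability_summary(res, {"a": m})
            hits += abs(h.h2 - tau_true * m) < 3 * h.se
        assert hits >= 9

    def test_missing_sizes_raise(self):
        rng = np.random.default_rng(31)
        ld = _ld_table(rng, 100, ["a"])
        res = fit_sldsc(rng.chisquare(1, 100), 1000, ld, ["a"], n_blocks=5)
        with pytest.raises(KeyError):
            heritability_summary(res, {})
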