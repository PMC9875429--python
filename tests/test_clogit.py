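"""Conditional-logit likelihood, Newton fit, effect transforms and LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from aircrossover.clogit import (
    ClogitDesign,
    RankDeficiencyError,
    conditional_loglik,
    fit_clogit,
    likelihood_ratio_test,
    percent_change,
)


def brute_loglik(beta, strata):
    """Independent oracle: naive product of per-stratum probabilities."""
    total = 0.0
    for xs, case_idx in strata:
        num = np.exp(beta * xs[case_idx])
        total += np.log(num / np.sum(np.exp(beta * np.asarray(xs))))
    return total


def design_from_strata(strata):
    rows = []
    for s, (xs, case_idx) in enumerate(strata):
        for j, x in enumerate(xs):
            rows.append((f"s{s}", x, int(j == case_idx)))
    df = pd.DataFrame(rows, columns=["stratum_id", "x", "is_case"])
    return ClogitDesign.from_frame(df, ["x"])


class TestLoglik:
    def test_null_beta_uniform_closed_form(self, rng):
        strata = [(rng.normal(size=4), rng.integers(4)) for _ in range(11)]
        d = design_from_strata(strata)
        ll, _, _ = conditional_loglik(np.zeros(1), d)
        assert ll == pytest.approx(-11 * np.log(4.0))

    def test_single_stratum_direct_evaluation(self):
        d = design_from_strata([(np.array([1.0, 0.0, 0.0, 0.0]), 0)])
        ll, _, _ = conditional_loglik(np.array([np.log(2.0)]), d)
        assert ll == pytest.approx(np.log(2.0 / 5.0))

    def test_stratum_constant_shift_invariance(self, rng):
        strata = [(rng.normal(size=4), rng.integers(4)) for _ in range(6)]
        d = design_from_strata(strata)
        beta = np.array([0.7])
        ll0, g0, h0 = conditional_loglik(beta, d)
        X2 = d.X.copy()
        X2[4:8] += 7.0  # shift every row of the second stratum
        d2 = ClogitDesign(X2, d.y, d.starts, d.columns)
        ll1, g1, h1 = conditional_loglik(beta, d2)
        assert ll1 == pytest.approx(ll0, abs=1e-12)
        np.testing.assert_allclose(g1, g0, atol=1e-10)
        np.testing.assert_allclose(h1, h0, atol=1e-10)

    def test_gradient_and_hessian_match_finite_differences(self, rng):
        strata = [(rng.normal(size=5), rng.integers(5)) for _ in range(7)]
        d = design_from_strata(strata)
        beta = np.array([0.4])
        _, g, h = conditional_loglik(beta, d)
        eps = 1e-6
        lp, _, _ = conditional_loglik(beta + eps, d)
        lm, _, _ = conditional_loglik(beta - eps, d)
        assert g[0] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)
        eps2 = 1e-4  # wider step for the noisier second difference
        lp2, _, _ = conditional_loglik(beta + eps2, d)
        lm2, _, _ = conditional_loglik(beta - eps2, d)
        l0, _, _ = conditional_loglik(beta, d)
        assert h[0, 0] == pytest.approx((lp2 - 2 * l0 + lm2) / eps2**2, abs=1e-3)

    def test_stratum_without_control_rejected(self):
        df = pd.DataFrame(
            {"stratum_id": ["a"], "x": [1.0], "is_case": [1]}
        )
        with pytest.raises(ValueError):
            ClogitDesign.from_frame(df, ["x"])


class TestFit:
    def test_symmetric_two_strata_give_zero(self):
        strata = [(np.array([1.0, 0.0]), 0), (np.array([0.0, 1.0]), 0)]
        fit = fit_clogit(design_from_strata(strata))
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(-2 * np.log(2.0))

    @pytest.mark.parametrize("n_strata,sizes_seed", [(1, 0), (2, 1), (3, 2), (3, 3)])
    def test_matches_brute_force_maximiser(self, n_strata, sizes_seed):
        rng = np.random.default_rng(sizes_seed)
        strata = [
            (rng.normal(size=rng.integers(2, 6)), 0) for _ in range(n_strata)
        ]
        strata = [(xs, int(rng.integers(xs.size))) for xs, _ in strata]
        d = design_from_strata(strata)
        res = minimize_scalar(
            lambda b: -brute_loglik(b, strata), bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        if abs(res.x) > 9.5:
            return  # likelihood maximised at the search bound: separated design
        fit = fit_clogit(d)
        assert fit.params["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rows = []
        for s in range(200):
            x = rng.normal(size=(4, 2))
            eta = x @ np.array([0.5, -0.3])
            p = np.exp(eta) / np.exp(eta).sum()
            case = rng.choice(4, p=p)
            for j in range(4):
                rows.append((s, x[j, 0], x[j, 1], int(j == case)))
        df = pd.DataFrame(rows, columns=["stratum_id", "x1", "x2", "is_case"])
        ours = fit_clogit(ClogitDesign.from_frame(df, ["x1", "x2"]))
        ref = ConditionalLogit(
            df["is_case"], df[["x1", "x2"]], groups=df["stratum_id"]
        ).fit(disp=False)
        # statsmodels' optimiser converges more loosely than our Newton
        np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=5e-4)
        np.testing.assert_allclose(np.sqrt(np.diag(ours.cov)), ref.bse, rtol=1e-3)
        assert ours.loglik >= ref.llf - 1e-8
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_no_within_stratum_variation_is_rank_deficient(self):
        df = pd.DataFrame(
            {
                "stratum_id": ["a"] * 3 + ["b"] * 3,
                "x": [2.0] * 3 + [5.0] * 3,
                "is_case": [1, 0, 0, 1, 0, 0],
            }
        )
        with pytest.raises(RankDeficiencyError):
            fit_clogit(ClogitDesign.from_frame(df, ["x"]))

    def test_bic_bookkeeping(self, rng):
        strata = [(rng.normal(size=4), rng.integers(4)) for _ in range(9)]
        fit = fit_clogit(design_from_strata(strata))
        assert fit.bic == pytest.approx(-2 * fit.loglik + 1 * np.log(9))
        # serialization carries the convergence block
        blob = fit.to_json()
        assert '"loglik"' in blob and '"iterations"' in blob


class TestPercentChange:
    def _fit(self, beta, se=0.01):
        from aircrossover.clogit import FitResult

        return FitResult(
            params=pd.Series({"x": beta}),
            cov=pd.DataFrame([[se**2]], index=["x"], columns=["x"]),
            loglik=0.0,
            n_strata=100,
            n_params=1,
            bic=0.0,
            n_iter=1,
            grad_norm=0.0,
        )

    def test_zero_beta_symmetric(self):
        est = percent_change(self._fit(0.0), "x")
        assert est.percent == pytest.approx(0.0)
        assert est.ci_low < 0.0 < est.ci_high
        # symmetric on the log-odds scale around beta = 0
        assert np.log1p(est.ci_low / 100) == pytest.approx(-np.log1p(est.ci_high / 100))

    def test_inverse_transform_matches_reported_so2_row(self):
        est = percent_change(self._fit(np.log(1.0290)), "x")
        assert est.percent == pytest.approx(2.90, abs=1e-10)

    def test_monotone_in_beta(self):
        vals = [percent_change(self._fit(b), "x").percent for b in (-0.1, 0.0, 0.1, 0.2)]
        assert vals == sorted(vals)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(KeyError):
            percent_change(self._fit(0.0), "y")


class TestLRT:
    def _two_fits(self, rng, extra_null=True):
        rows = []
        for s in range(150):
            x = rng.normal(size=(4, 2))
            eta = 0.8 * x[:, 0]
            p = np.exp(eta) / np.exp(eta).sum()
            case = rng.choice(4, p=p)
            for j in range(4):
                rows.append((s, x[j, 0], x[j, 1], int(j == case)))
        df = pd.DataFrame(rows, columns=["stratum_id", "x1", "x2", "is_case"])
        full = fit_clogit(ClogitDesign.from_frame(df, ["x1", "x2"]))
        red = fit_clogit(ClogitDesign.from_frame(df, ["x1"]))
        return full, red

    def test_equal_fits_statistic_zero(self, rng):
        full, _ = self._two_fits(rng)
        stat, df, p = likelihood_ratio_test(full, full)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_statistic_equals_deviance_difference(self, rng):
        full, red = self._two_fits(rng)
        stat, df, p = likelihood_ratio_test(full, red)
        assert stat == pytest.approx(2 * (full.loglik - red.loglik))
        assert df == 1
        assert stat >= 0.0

    def test_non_nested_rejected(self, rng):
        full, red = self._two_fits(rng)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(red, full)
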