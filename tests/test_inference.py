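import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from osmofit.data import Dataset
from osmofit.inference import (
    anova_oneway,
    factorial_lm,
    logistic_survival_model,
    tukey_hsd,
    welch_t_test,
)
from osmofit.simulate import CellParams, GardenSimConfig, simulate_garden

from conftest import make_box


class TestOneWayAnova:
    def test_hand_computed_decomposition(self):
        table = anova_oneway([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        name, ssb, dfb, F, p = table.terms[0]
        assert (ssb, dfb) == (pytest.approx(54.0), 2)
        assert table.residual == (pytest.approx(6.0), 6)
        assert F == pytest.approx(27.0)

    def test_identical_groups_give_zero_f(self):
        table = anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        assert table.terms[0][3] == 0.0
        assert table.terms[0][4] == 1.0

    def test_label_permutation_invariance(self):
        g = [[1.0, 2.5], [3.0, 4.0], [0.5, 0.7, 0.9]]
        a = anova_oneway(g)
        b = anova_oneway(g[::-1])
        assert a.terms[0][3] == pytest.approx(b.terms[0][3])

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            anova_oneway([[1, 2, 3]])

    @given(
        data=st.lists(
            st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=10),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_scipy_closed_form(self, data):
        groups = [np.asarray(g) for g in data]
        if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
            return
        table = anova_oneway(groups)
        F_ref, p_ref = scipy.stats.f_oneway(*groups)
        # scipy can return a tiny negative F (and p = nan) from rounding
        # when the between-group variation is numerically zero
        if np.isfinite(F_ref) and F_ref > 1e-8:
            assert table.terms[0][3] == pytest.approx(F_ref, rel=1e-9, abs=1e-9)
            assert table.terms[0][4] == pytest.approx(p_ref, rel=1e-6, abs=1e-12)
        ssb, ssw = table.terms[0][1], table.residual[0]
        assert ssb + ssw == pytest.approx(table.total_sum_sq)


class TestTukey:
    def test_two_group_case_equals_pooled_t_test(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        res = tukey_hsd({"a": x, "b": y})
        _, _, _, q, p_adj, _ = res.pairs[0]
        t, p_t = scipy.stats.ttest_ind(x, y, equal_var=True)
        assert q == pytest.approx(abs(t) * np.sqrt(2), rel=1e-9)
        assert p_adj == pytest.approx(p_t, rel=1e-4)

    def test_large_shift_always_significant(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(0, 1, 10) for k in "abc"}
        groups["d"] = rng.normal(10, 1, 10)
        res = tukey_hsd(groups)
        for a, b, *_, sig in res.pairs:
            assert sig == ("d" in (a, b))

    def test_zero_pooled_variance_is_an_error(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": np.ones(3), "b": np.ones(3)})


class TestFactorialModel:
    def balanced_2x2(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for t in (0, 1):
            for o in ("FW", "BW"):
                for _ in range(4):
                    y = 1.0 * t + 2.0 * (o == "BW") + noise * rng.normal()
                    rows.append({"treatment": t, "origin": o, "y": y})
        return pd.DataFrame(rows)

    def test_additive_design_has_zero_interaction_ss(self):
        table = factorial_lm(self.balanced_2x2(), "y", ["treatment", "origin"])
        terms = {name: ss for name, ss, *_ in table.terms}
        assert terms["treatment:origin"] == pytest.approx(0.0, abs=1e-20)

    def test_decomposition_identity(self):
        table = factorial_lm(self.balanced_2x2(noise=0.5, seed=2), "y", ["treatment", "origin"])
        total = sum(ss for _, ss, *_ in table.terms) + table.residual[0]
        assert total == pytest.approx(table.total_sum_sq)

    def test_single_factor_reduces_to_oneway(self):
        df = self.balanced_2x2(noise=0.5, seed=3)
        table = factorial_lm(df, "y", ["origin"], with_interaction=False)
        groups = [g["y"].to_numpy() for _, g in df.groupby("origin")]
        ref = anova_oneway(groups)
        assert table.terms[0][3] == pytest.approx(ref.terms[0][3])
        assert table.residual[0] == pytest.approx(ref.residual[0])

    def test_reports_lr_chi2_per_term(self):
        table = factorial_lm(self.balanced_2x2(noise=0.5, seed=4), "y", ["treatment", "origin"])
        assert table.chi2 is not None
        frame = table.to_frame()
        assert {"lr_chi2", "p_chi2"} <= set(frame.columns)


class TestLogisticSurvival:
    def flat_garden(self, seed, p=0.03):
        cells = {
            ("FW", t): CellParams(p_death_male=p, p_death_female=p, egg_rate=1.0)
            for t in (0.0, 1.0, 3.0, 5.0, 11.0)
        }
        return simulate_garden(GardenSimConfig(cells=cells, boxes_per_cell=8, seed=seed))

    def test_flat_truth_slope_ci_covers_zero(self):
        """Survival independent of salinity: slope CI covers 0 in >= 93% of runs."""
        n_sim, covered = 200, 0
        for s in range(n_sim):
            ds = self.flat_garden(seed=20_000 + s)
            out = logistic_survival_model(ds)
            lo, hi = out["coefficients"].loc["salinity", ["ci_lo", "ci_hi"]]
            if lo <= 0 <= hi:
                covered += 1
        assert covered / n_sim >= 0.93

    def test_shares_engine_with_mortality_fit(self):
        ds = self.flat_garden(seed=9, p=0.05)
        out = logistic_survival_model(ds)
        # refit mortality on the same box aggregates: logit coefs flip sign
        import statsmodels.api as sm

        rows = [(b.treatment, b.alive_on(30), b.n_initial) for b in ds.records]
        sal = np.array([r[0] for r in rows], dtype=float)
        alive = np.array([r[1] for r in rows], dtype=float)
        n = np.array([r[2] for r in rows], dtype=float)
        exog = sm.add_constant(sal)
        dead_fit = sm.GLM(np.column_stack([n - alive, alive]), exog, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            out["coefficients"]["coef"].to_numpy(), -dead_fit.params, rtol=1e-6, atol=1e-8
        )

    def test_sex_interaction_recovered(self):
        """Sex-specific salinity effects recovered within 2 SE of the truth."""
        # male daily hazard grows faster with salinity than female
        def cell(t):
            return CellParams(
                p_death_male=0.01 + 0.004 * t, p_death_female=0.01 + 0.001 * t, egg_rate=1.0
            )

        cells = {("FW", t): cell(t) for t in (0.0, 1.0, 3.0, 5.0, 11.0)}
        ds = simulate_garden(GardenSimConfig(cells=cells, boxes_per_cell=20, seed=77))
        out = logistic_survival_model(ds, predictors=("salinity", "sex"))
        coef = out["coefficients"]
        # true 30-day logit slopes by sex, from the generating hazards
        t = np.array([0.0, 1.0, 3.0, 5.0, 11.0])
        def logit_slope(p0, k):
            s = (1 - (p0 + k * t)) ** 30
            return np.polyfit(t, np.log(s / (1 - s)), 1)[0]

        true_f = logit_slope(0.01, 0.001)
        true_m = logit_slope(0.01, 0.004)
        est_int = coef.loc["salinity:sex_M", "coef"]
        se_int = coef.loc["salinity:sex_M", "se"]
        assert est_int == pytest.approx(true_m - true_f, abs=2 * se_int)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_instance(self):
        t, df, p = welch_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 2, 7)
        t1, _, p1 = welch_t_test(x, y)
        t2, _, p2 = welch_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_zero_variance_unequal_means(self):
        t, _, p = welch_t_test([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0
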