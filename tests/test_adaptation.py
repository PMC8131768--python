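import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osmofit.adaptation import (
    adaptation_report,
    classify_tradeoff,
    local_adaptation_index,
    maladaptation_magnitude,
    trait_average_la,
)

fitness_values = st.floats(min_value=0.0, max_value=1e6, allow_nan=False, allow_infinity=False)
positive_fitness = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False)


class TestLocalAdaptationIndex:
    @pytest.mark.parametrize(
        "w_native,w_foreign,expected",
        [
            (0.49, 0.35, 0.3333),  # survival at the freshwater home site
            (77.90, 24.00, 1.0579),  # fecundity at the freshwater home site
            (0.19, 0.31, -0.48),  # freshwater population away at 1 ppt
        ],
    )
    def test_published_mean_pairs(self, w_native, w_foreign, expected):
        est = local_adaptation_index(w_native, w_foreign)
        assert est.la == pytest.approx(expected, abs=5e-4)

    @given(w=positive_fitness)
    @settings(max_examples=50, derandomize=True)
    def test_equal_fitness_gives_zero(self, w):
        assert local_adaptation_index(w, w).la == pytest.approx(0.0, abs=1e-12)

    @given(w=positive_fitness)
    @settings(max_examples=50, derandomize=True)
    def test_foreign_extinction_hits_upper_bound(self, w):
        assert local_adaptation_index(w, 0.0).la == pytest.approx(2.0)

    @given(a=fitness_values, b=fitness_values)
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry_and_bounds(self, a, b):
        fwd = local_adaptation_index(a, b)
        rev = local_adaptation_index(b, a)
        assert fwd.defined == rev.defined
        if fwd.defined:
            assert fwd.la == pytest.approx(-rev.la, abs=1e-9)
            assert -2.0 - 1e-12 <= fwd.la <= 2.0 + 1e-12

    @given(a=positive_fitness, b=fitness_values, k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, a, b, k):
        base = local_adaptation_index(a, b).la
        scaled = local_adaptation_index(k * a, k * b).la
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_both_zero_is_undefined_not_zero(self):
        est = local_adaptation_index(0.0, 0.0)
        assert not est.defined
        assert math.isnan(est.la)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            local_adaptation_index(-0.1, 0.5)


class TestTraitAverage:
    def test_four_trait_average_away_at_five_ppt(self):
        pairs = [(0.14, 0.24), (12.0, 18.5), (0.40, 0.61), (1.00, 2.50)]
        ests = [local_adaptation_index(a, b, trait=f"t{i}") for i, (a, b) in enumerate(pairs)]
        assert trait_average_la(ests) == pytest.approx(-0.5564, abs=5e-4)

    def test_single_estimate_passes_through(self):
        est = local_adaptation_index(2.0, 1.0, trait="x")
        assert trait_average_la([est]) == pytest.approx(est.la)

    def test_symmetric_values_cancel(self):
        ests = [
            local_adaptation_index(1.0, 3.0, trait="a"),  # -1
            local_adaptation_index(3.0, 1.0, trait="b"),  # +1
        ]
        assert trait_average_la(ests) == pytest.approx(0.0)

    def test_explicit_trait_exclusion(self):
        ests = [
            local_adaptation_index(2.0, 1.0, trait="survival"),
            local_adaptation_index(1.0, 1.0, trait="fecundity"),
        ]
        assert trait_average_la(ests, exclude={"survival"}) == pytest.approx(0.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            trait_average_la([])


class TestMaladaptationMagnitude:
    def test_published_survival_pair(self):
        est = maladaptation_magnitude(0.49, 0.31)
        assert est.ma == pytest.approx(0.3673, abs=5e-4)

    @given(w=positive_fitness)
    @settings(max_examples=50, derandomize=True)
    def test_matched_fitness_gives_zero(self, w):
        assert maladaptation_magnitude(w, w).ma == pytest.approx(0.0, abs=1e-12)

    @given(w=positive_fitness)
    @settings(max_examples=50, derandomize=True)
    def test_extinct_derived_population_gives_one(self, w):
        assert maladaptation_magnitude(w, 0.0).ma == pytest.approx(1.0)

    @given(a=positive_fitness, b=fitness_values, k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True)
    def test_joint_scale_invariance_and_upper_bound(self, a, b, k):
        base = maladaptation_magnitude(a, b)
        scaled = maladaptation_magnitude(k * a, k * b)
        assert scaled.ma == pytest.approx(base.ma, rel=1e-9, abs=1e-9)
        assert base.ma <= 1.0

    def test_realized_above_ideal_flagged_not_clipped(self):
        est = maladaptation_magnitude(1.0, 1.5)
        assert est.ma == pytest.approx(-0.5)
        assert est.exceeds_ideal

    def test_zero_ideal_rejected(self):
        with pytest.raises(ValueError):
            maladaptation_magnitude(0.0, 0.5)


class TestTradeoffQuadrants:
    @pytest.mark.parametrize(
        "la_home,la_foreign,quadrant",
        [
            (0.33, -0.48, "tradeoff_home"),
            (1.06, 0.21, "no_tradeoff_both"),
            (-0.5, 0.5, "inverse_tradeoff"),
            (-0.5, -0.5, "no_tradeoff_neither"),
            (0.0, 0.0, "boundary"),
            (1e-12, 0.5, "boundary"),
        ],
    )
    def test_sign_classification(self, la_home, la_foreign, quadrant):
        assert classify_tradeoff(la_home, la_foreign).quadrant == quadrant


class TestAdaptationReport:
    def test_report_recovers_published_home_values(self, published_means):
        rep = adaptation_report(published_means)
        la = rep["la"].set_index(["population", "site", "trait"])
        assert la.loc[("FW", 0.0, "n_immatures"), "la"] == pytest.approx(1.1111, abs=5e-4)
        assert la.loc[("BW", 1.0, "survival"), "la"] == pytest.approx(0.48, abs=5e-4)

    def test_home_site_tradeoffs_match_survival_pattern(self, published_means):
        rep = adaptation_report(published_means)
        t = rep["tradeoff"].set_index(["population", "foreign_site", "trait"])
        # freshwater population: home advantage vs deficit at 1 ppt for survival
        assert t.loc[("FW", 1.0, "survival"), "quadrant"] == "tradeoff_home"
        # but adapted at both sites for fecundity
        assert t.loc[("FW", 1.0, "fecundity"), "quadrant"] == "no_tradeoff_both"

    def test_empty_summaries_give_empty_report(self, published_means):
        empty = published_means.head(0)
        rep = adaptation_report(empty)
        assert rep["la"].empty and rep["ma"].empty

    def test_missing_cell_skipped_with_warning(self, published_means):
        trimmed = published_means[
            ~((published_means["population"] == "BW") & (published_means["treatment"] == 3))
        ]
        with pytest.warns(UserWarning, match="missing cell"):
            rep = adaptation_report(trimmed)
        assert 3.0 not in set(rep["la"]["site"])
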