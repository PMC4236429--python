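"""Pathogen/self targeting ratios, MDI and discrimination ability."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from probimmune import (
    ModelParams,
    approx_correct_targeting_ratio,
    classify_region,
    correct_targeting_ratio,
    discrimination_ability,
    discrimination_complement,
    fold_change_targeting_prob,
    log_correct_targeting_ratio,
    lower_bound_ratio,
    minimum_detectable_increment,
    raised_self_targeting_ratio,
    targeting_probability,
)


class TestCorrectTargetingRatio:
    def test_matches_direct_evaluation_at_physiological_corner(self):
        # p = a* = 5e-3, t0 = 1e4: R = (5e-3 e^50) / (0.995 * 5e-3) ~ 5.2e21
        expected = 5e-3 * math.exp(50) / (0.995 * 5e-3)
        assert correct_targeting_ratio(5e-3, 5e-3, 10**4) == pytest.approx(
            expected, rel=1e-9
        )
        assert correct_targeting_ratio(5e-3, 5e-3, 10**4) > 1e20

    def test_subthreshold_pathogen_is_invisible(self):
        # p < a*: the adaptive system cannot see the pathogen, R = 0
        assert correct_targeting_ratio(1e-3, 5e-3, 1000) == 0.0
        assert log_correct_targeting_ratio(1e-3, 5e-3, 1000) == -math.inf

    def test_diverges_as_threshold_vanishes(self):
        # fixed p, shrinking a*: R -> p/((1-p) a*) -> inf
        t0 = 10
        rs = [correct_targeting_ratio(0.5, a, t0) for a in (1e-2, 1e-4, 1e-6)]
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 1e5

    def test_exact_form_recovers_compact_m1_expression(self):
        # R = p e^{a* t0} / ((1-p) a*) exactly at m = 1
        p, a_star, t0 = 0.3, 2e-3, 2000
        expected = p * math.exp(a_star * t0) / ((1 - p) * a_star)
        assert correct_targeting_ratio(p, a_star, t0) == pytest.approx(expected, rel=1e-9)

    def test_truncated_form_close_to_exact_for_small_a_star(self):
        p, a_star, t0 = 0.05, 1e-4, 10**5
        exact = correct_targeting_ratio(p, a_star, t0)
        approx = approx_correct_targeting_ratio(p, a_star, t0)
        assert approx == pytest.approx(exact, rel=1e-3)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_rejects_degenerate_pathogen_abundance(self, p):
        with pytest.raises(ValueError):
            correct_targeting_ratio(p, 5e-3, 1000)


class TestLowerBoundRatio:
    def test_physiological_corner(self):
        assert lower_bound_ratio(200, 0.05, 5) == pytest.approx(math.exp(50), rel=1e-12)

    def test_vanishing_scan_fraction_limit(self):
        assert lower_bound_ratio(200, 1e-12, 5) == pytest.approx(1.0)

    def test_agrees_with_exact_quotient_up_to_one_minus_p(self):
        # a* t0 = K s n* when t0 = KNs and a* = n*/N; the exact quotient at
        # p = a* differs from e^{Ksn*} only by the (1-p) and a*-prefactor
        K, N, s, n_star = 200, 5000, 0.05, 5
        a_star, t0 = n_star / N, round(K * N * s)
        exact = correct_targeting_ratio(a_star, a_star, t0)
        bound = lower_bound_ratio(K, s, n_star)
        assert exact * (1 - a_star) == pytest.approx(bound, rel=1e-9)


class TestRaisedSelfRatio:
    def test_bystander_worked_example_rounds_to_three(self):
        # self antigen raised from a^max to a*, pathogen at p = a*:
        # ratio = e/(1-a*) ~ 2.73; round-half-even to nearest integer = 3
        t0, a_star = 1000, 5e-3
        ratio = raised_self_targeting_ratio(a_star, 1 / t0, a_star, t0)
        assert ratio == pytest.approx(math.e / (1 - a_star), rel=1e-9)
        assert round(ratio) == 3

    def test_reduces_to_correct_targeting_ratio(self):
        p, a_star, t0 = 0.05, 4e-3, 500
        assert raised_self_targeting_ratio(p, a_star, a_star, t0) == pytest.approx(
            correct_targeting_ratio(p, a_star, t0), rel=1e-12
        )

    def test_never_tolerated_limit(self):
        # basal -> 0 means f -> 0; with a_new = p the ratio -> 1/(1-p)
        p = 0.2
        ratio = raised_self_targeting_ratio(p, 0.0, p, 1000)
        assert ratio == pytest.approx(1 / (1 - p), rel=1e-12)

    def test_subthreshold_raise_stays_invisible(self):
        assert raised_self_targeting_ratio(
            0.05, 1e-4, 2e-3, 1000, a_star=5e-3
        ) == math.inf


class TestFoldChangeTargeting:
    def test_below_threshold_is_silent(self, params):
        assert fold_change_targeting_prob(1e-4, 2.0, params) == 0.0

    def test_unit_fold_recovers_targeting_probability(self, params):
        for a in (1e-4, 5e-3, 2e-2):
            assert fold_change_targeting_prob(a, 1.0, params) == pytest.approx(
                targeting_probability(a, params), rel=1e-12
            )

    def test_tumor_construction_point(self, params):
        # antigen at a^max = 1e-3 raised 5-fold reaches a* = 5e-3 and is
        # targeted with probability a* e^{-1}
        prob = fold_change_targeting_prob(1e-3, 5.0, params)
        assert prob == pytest.approx(5e-3 * math.exp(-1), rel=1e-12)

    def test_rejects_superunit_abundance(self, params):
        with pytest.raises(ValueError):
            fold_change_targeting_prob(0.5, 3.0, params)


class TestMDI:
    def test_range_endpoints(self):
        assert minimum_detectable_increment(K=200, s=0.05, n_star=5) == pytest.approx(50)
        assert minimum_detectable_increment(K=1000, s=0.05, n_star=10) == pytest.approx(500)

    def test_parameterizations_agree_by_algebra(self):
        # a* t0 = (n*/N)(K N s) = K s n*
        prm = ModelParams(N=2000, n_star=10, K=1000, s=0.05)
        assert minimum_detectable_increment(prm) == pytest.approx(
            prm.a_star * prm.t0
        ) == pytest.approx(500)

    def test_inconsistent_parameterizations_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            minimum_detectable_increment(a_star=5e-3, t0=1000, K=200, s=0.05, n_star=5)

    def test_requires_a_complete_parameter_set(self):
        with pytest.raises(ValueError):
            minimum_detectable_increment(a_star=5e-3)


class TestDiscriminationAbility:
    def test_unit_increment_gives_zero(self):
        assert discrimination_ability(1.0) == 0.0

    def test_near_perfect_at_mdi_ten(self):
        assert discrimination_ability(10.0) == pytest.approx(0.99975, abs=5e-6)

    def test_complement_is_tiny_at_mdi_fifty(self):
        assert discrimination_complement(50.0) == pytest.approx(1.05e-21, rel=1e-2)

    def test_quotient_form_exact_at_m1(self):
        from probimmune.targeting import _delta_quotient

        for mdi in (1.5, 5.0, 20.0, 100.0):
            d = _delta_quotient(mdi, 1)
            assert (d - 1) / (d + 1) == pytest.approx(
                discrimination_ability(mdi), rel=1e-12
            )

    def test_rejects_sub_unit_increment(self):
        with pytest.raises(ValueError):
            discrimination_ability(0.5)

    @pytest.mark.parametrize("m", [2, 5])
    def test_multiclone_delta_in_range_and_increasing(self, m):
        # below MDI ~ 30 the complement stays above float resolution, so
        # strict growth is visible on delta itself
        grid = np.linspace(1.0, 25.0, 40)
        vals = [discrimination_ability(x, m) for x in grid]
        assert all(0 <= v < 1 for v in vals)
        assert np.all(np.diff(vals) > 0)


def _delta_first_principles(a_star: float, t0: int, m: int = 1) -> float:
    """Definition-level discrimination ability, built from the targeting
    probabilities of (i) the antigen at a^max = 1/t0 raised by the MDI and
    (ii) the antigen sitting at a* — an independent construction of the
    closed form."""
    prm = ModelParams(t0=t0, m=m)
    mdi = minimum_detectable_increment(a_star=a_star, t0=t0)
    # nudge k by one part in 1e12 so float rounding cannot push k*a_max
    # below the sharp threshold branch
    p_raised = fold_change_targeting_prob(1.0 / t0, mdi * (1 + 1e-12), prm, a_star=a_star)
    p_chance = fold_change_targeting_prob(a_star, 1.0, prm, a_star=a_star)
    return (p_raised - p_chance) / (p_raised + p_chance)


@pytest.mark.parametrize("a_star, t0", [(1e-3, 5000), (5e-4, 10**4), (1e-3, 2000)])
def test_first_principles_delta_matches_closed_form(a_star, t0):
    mdi = a_star * t0
    assert _delta_first_principles(a_star, t0) == pytest.approx(
        discrimination_ability(mdi), rel=1e-6
    )


def test_delta_depends_only_on_the_product(rng):
    # random (a*, t0) pairs at fixed MDI = a* t0 give the same delta via the
    # definition-level construction
    mdi = 8.0
    vals = []
    for _ in range(10):
        a_star = 10 ** rng.uniform(-4, -3)
        t0 = round(mdi / a_star)
        vals.append(_delta_first_principles(mdi / t0, t0))
    assert np.ptp(vals) < 1e-6


@given(
    st.floats(min_value=1.0, max_value=500.0),
    st.floats(min_value=1.0, max_value=500.0),
)
def test_delta_strictly_increasing_in_mdi(m1, m2):
    # mathematically delta lies in [0, 1); in floats it saturates at 1 for
    # MDI beyond ~37, so strictness is asserted on the stable complement
    lo, hi = sorted((m1, m2))
    assert 0.0 <= discrimination_ability(lo) <= 1.0
    if hi - lo > 1e-9:
        assert discrimination_complement(lo) > discrimination_complement(hi)


@given(st.floats(min_value=0.006, max_value=0.99), st.floats(min_value=0.006, max_value=0.99))
def test_ratio_strictly_increasing_in_pathogen_abundance(p1, p2):
    lo, hi = sorted((p1, p2))
    a_star, t0 = 5e-3, 1000
    if hi - lo > 1e-9:
        assert log_correct_targeting_ratio(lo, a_star, t0) < log_correct_targeting_ratio(
            hi, a_star, t0
        )


class TestRegions:
    @pytest.mark.parametrize("mdi, region", [(1.0, 1), (3.0, 2), (10.0, 2), (100, 3)])
    def test_default_boundaries(self, mdi, region):
        assert classify_region(mdi) == region

    def test_rejects_unordered_boundaries(self):
        with pytest.raises(ValueError):
            classify_region(5.0, boundaries=(20, 3))
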