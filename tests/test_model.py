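"""Closed-form model: characteristic root, antenna size, lifetime, k_a."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetsearch.model import (
    AssayCondition,
    NonspecificParams,
    antenna_size,
    antenna_size_midpoint,
    decompose,
    k_a_full,
    lifetime_tau_N,
    site_count,
    sliding_length,
    y_of_lambda,
)


class TestSiteCount:
    @pytest.mark.parametrize(
        "length,B,expected",
        [(113, 9, 105), (28, 9, 20), (9, 9, 1), (33, 9, 25), (143, 9, 135)],
    )
    def test_examples(self, length, B, expected):
        assert site_count(length, B) == expected

    def test_duplex_shorter_than_footprint_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            site_count(8, 9)


class TestCharacteristicRoot:
    def test_closed_form_at_unit_sliding_length(self):
        assert y_of_lambda(1.0) == pytest.approx((3 - math.sqrt(5)) / 2, rel=1e-12)

    def test_approaches_one_for_long_sliding(self):
        y = y_of_lambda(1e8)
        assert 0 < 1 - y < 1e-7

    def test_short_sliding_satisfies_reciprocal_sum(self):
        lam = 0.1
        y = y_of_lambda(lam)
        assert y + 1 / y == pytest.approx(2 + lam**-2, rel=1e-12)

    @given(st.floats(min_value=1e-2, max_value=1e6))
    @settings(derandomize=True, max_examples=200)
    def test_quadratic_residual_small(self, lam):
        y = y_of_lambda(lam)
        assert abs(y * y - (2 + lam**-2) * y + 1) <= 1e-10

    @pytest.mark.parametrize("lam", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_sliding_length_rejected(self, lam):
        with pytest.raises(ValueError):
            y_of_lambda(lam)


class TestAntennaSize:
    def test_no_sliding_limit_is_target_alone(self):
        assert antenna_size(1e-3, 105, 2) == pytest.approx(1.0, abs=1e-5)

    def test_infinite_sliding_limit_is_whole_duplex(self):
        assert antenna_size(1e6, 105, 2) == pytest.approx(105.0, abs=1e-3)

    def test_single_site_duplex(self):
        assert antenna_size(38.0, 1, 1) == 1.0

    @given(
        lam=st.floats(min_value=0.01, max_value=1e4),
        L=st.integers(min_value=1, max_value=10_000),
    )
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_reflection_symmetry(self, lam, L):
        m = 1 + (L * 7919) % L  # deterministic position in 1..L
        S = antenna_size(lam, L, m)
        assert 1.0 - 1e-9 <= S <= L + 1e-9
        S_mirror = antenna_size(lam, L, L + 1 - m)
        assert S == pytest.approx(S_mirror, rel=1e-12)

    def test_upper_bound_coth_supremum(self):
        # the exact supremum of S over L is coth(u/2), which equals
        # 2*lambda*(1 + O(lambda^-2)); the familiar "S < 2*lambda"
        # description is its large-lambda asymptote
        from targetsearch.model import _u_of_lambda

        for lam in (0.5, 1.0, 2.0, 10.0, 38.0, 122.0):
            sup = 1.0 / math.tanh(0.5 * _u_of_lambda(lam))
            assert sup <= 2 * lam * (1 + 1 / (8 * lam * lam))
            for L in (10, 25, 105, 135):
                for m in (1, 2, (L + 1) // 2):
                    assert antenna_size(lam, L, m) <= sup * (1 + 1e-12)

    def test_monotone_in_duplex_length(self):
        sizes = [antenna_size(38.0, L, 2) for L in range(2, 400)]
        assert np.all(np.diff(sizes) >= -1e-12)

    def test_numerically_stable_extremes(self):
        # overflow-prone corner: tiny sliding length, long duplex
        assert antenna_size(1e-2, 10_000, 5_000) == pytest.approx(1.0, rel=1e-3)
        assert math.isfinite(antenna_size(1e-2, 10_000, 1))

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="position"):
            antenna_size(10.0, 50, 51)


class TestMidpointApproximation:
    def test_reduces_to_L_for_long_sliding(self):
        assert antenna_size_midpoint(1e6, 105) == pytest.approx(105.0, rel=1e-3)

    def test_reduces_to_two_lambda_for_long_duplex(self):
        assert antenna_size_midpoint(5.0, 10_000) == pytest.approx(10.0, rel=1e-3)

    def test_close_to_exact_form_at_midpoint(self):
        # mid-target exact antenna vs the reduced expression across a grid
        worst = 0.0
        for lam in (2.0, 10.0, 38.0, 122.0):
            for L in (11, 25, 105, 135):
                m = (L + 1) // 2
                exact = antenna_size(lam, L, m)
                approx = antenna_size_midpoint(lam, L)
                worst = max(worst, abs(approx - exact) / exact)
        assert worst < 0.05  # documented grid-wide bound; see docs/methods.md


class TestLifetime:
    def test_dissociation_only(self, cond_probe113):
        p = NonspecificParams(D1=1e6, k_off_N=920.0, K_d_N=16e-6, k_IT_N=0.0)
        assert lifetime_tau_N(p, cond_probe113) == pytest.approx(1 / 920, rel=1e-12)

    def test_transfer_only_single_channel(self, cond_probe113):
        conc = 2 * (105 * cond_probe113.D_tot + 20 * cond_probe113.C_tot)
        p = NonspecificParams(D1=1e6, k_off_N=0.0, K_d_N=16e-6, k_IT_N=1e3 / conc)
        assert lifetime_tau_N(p, cond_probe113) == pytest.approx(1e-3, rel=1e-12)

    def test_doubling_competitor_halves_lifetime(self):
        # transfer-dominated regime with negligible probe contribution
        p = NonspecificParams(D1=1e6, k_off_N=0.0, K_d_N=16e-6, k_IT_N=1e8)
        c1 = AssayCondition(113, 28, D_tot=1e-12, C_tot=2e-6)
        c2 = replace(c1, C_tot=4e-6)
        ratio = lifetime_tau_N(p, c1) / lifetime_tau_N(p, c2)
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_no_decay_channel_rejected(self, cond_probe113):
        p = NonspecificParams(D1=1e6, k_off_N=0.0, K_d_N=16e-6, k_IT_N=0.0)
        with pytest.raises(ValueError, match="decay"):
            lifetime_tau_N(p, cond_probe113)


class TestRateConstant:
    def test_intrinsic_binding_limit(self):
        # no antenna, no pools: k_a collapses to k_on,N = k_off,N / K_d,N
        p = NonspecificParams(D1=1e-10, k_off_N=500.0, K_d_N=1e-5, k_IT_N=0.0)
        c = AssayCondition(9, 28, D_tot=1e-15, C_tot=0.0, target_pos_m=1)
        assert k_a_full(p, c) == pytest.approx(p.k_on_N, rel=1e-6)

    def test_strictly_decreasing_in_competitor(self, params_150mM, cond_probe113):
        p = replace(params_150mM, k_IT_N=0.0)
        kas = [
            k_a_full(p, replace(cond_probe113, C_tot=c))
            for c in np.linspace(1e-7, 16e-6, 40)
        ]
        assert np.all(np.diff(kas) < 0)

    @given(
        logD1=st.floats(min_value=3, max_value=8),
        logkoff=st.floats(min_value=-1, max_value=4),
        logKd=st.floats(min_value=-7, max_value=-4),
        logkit=st.floats(min_value=5, max_value=9),
        phi=st.sampled_from([1, 2]),
    )
    @settings(derandomize=True, max_examples=200)
    def test_product_form_identity(self, logD1, logkoff, logKd, logkit, phi):
        # the direct closed form and the rho*eta*S*k_on,N factorisation
        # are the same algebraic object
        p = NonspecificParams(
            D1=10**logD1, k_off_N=10**logkoff, K_d_N=10**logKd,
            k_IT_N=10**logkit, phi=phi,
        )
        c = AssayCondition(113, 28, D_tot=2.5e-9, C_tot=2e-6)
        d = decompose(p, c)
        assert d.k_a == pytest.approx(k_a_full(p, c), rel=1e-12)


class TestDecomposition:
    def test_no_transfer_means_no_enhancement(self, cond_probe113):
        p = NonspecificParams(D1=1e6, k_off_N=920.0, K_d_N=16e-6, k_IT_N=0.0)
        assert decompose(p, cond_probe113).eta == 1.0

    def test_no_dna_pool_means_no_trapping(self, params_150mM):
        c = AssayCondition(113, 28, D_tot=0.0, C_tot=0.0)
        with pytest.raises(ValueError):
            # zero pool also kills the transfer channel when k_off_N = 0
            lifetime_tau_N(
                NonspecificParams(D1=1e6, k_off_N=0.0, K_d_N=1e-6, k_IT_N=1e7), c
            )
        assert decompose(params_150mM, c).rho == 1.0

    def test_untrapped_fraction_hand_evaluation(self, cond_probe113):
        p = NonspecificParams(D1=2.5e6, k_off_N=920.0, K_d_N=16e-6, k_IT_N=1e7)
        d = decompose(p, cond_probe113)
        expected = 16e-6 / (
            16e-6 + (2 * 105 - d.S) * 2.5e-9 + 2 * 20 * 2e-6
        )
        assert d.rho == pytest.approx(expected, rel=1e-12)

    def test_invariant_ranges(self, params_150mM, cond_probe113):
        d = decompose(params_150mM, cond_probe113)
        assert 0 < d.y < 1
        assert 0 < d.rho <= 1
        assert d.eta >= 1
        assert 1 <= d.S <= cond_probe113.L
        assert d.tau_N > 0 and d.k_a > 0

    def test_lambda_recomputed_per_condition(self, params_150mM, cond_probe113):
        # tau_N depends on C_tot through transfer, so lambda must too
        lam_lo = sliding_length(params_150mM, replace(cond_probe113, C_tot=5e-7))
        lam_hi = sliding_length(params_150mM, replace(cond_probe113, C_tot=16e-6))
        assert lam_lo > lam_hi

    def test_requires_dissociation_rate(self, cond_probe113):
        p = NonspecificParams(D1=1e6, k_off_N=0.0, K_d_N=16e-6, k_IT_N=1e7)
        with pytest.raises(ValueError, match="k_off_N"):
            decompose(p, cond_probe113)


class TestValidation:
    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            NonspecificParams(D1=-1, k_off_N=1, K_d_N=1e-6)
        with pytest.raises(ValueError):
            NonspecificParams(D1=1, k_off_N=1, K_d_N=1e-6, phi=3)

    def test_bad_condition_rejected(self):
        with pytest.raises(ValueError):
            AssayCondition(8, 28, D_tot=1e-9, C_tot=0.0)  # probe < footprint
        with pytest.raises(ValueError):
            AssayCondition(113, 28, D_tot=1e-9, C_tot=0.0, target_pos_m=106)
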