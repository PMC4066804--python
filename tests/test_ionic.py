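"""Ionic-strength power laws, decomposition profiles and the optimum."""

import math
import warnings

import numpy as np
import pytest

from targetsearch.ionic import (
    PowerLaw,
    decomposition_profile,
    eval_power_law,
    find_optimum,
    fit_power_law,
)
from targetsearch.model import AssayCondition, decompose
from targetsearch.synth import default_power_laws

KOFF_POINTS = [(40.0, 0.20), (150.0, 920.0)]
KD_POINTS = [
    (40.0, 1.4e-6), (60.0, 3.6e-6), (80.0, 4.6e-6),
    (110.0, 9.6e-6), (150.0, 16e-6),
]


def _flat(quantity, value, domain=(40.0, 400.0)):
    return PowerLaw(quantity, 0.0, math.log10(value), domain)


@pytest.fixture
def cond():
    return AssayCondition(113, 28, D_tot=2.5e-9, C_tot=2e-6)


class TestPowerLawFit:
    def test_two_point_dissociation_slope(self):
        law = fit_power_law(KOFF_POINTS, "k_off_N")
        assert law.a == pytest.approx(
            math.log10(920 / 0.20) / math.log10(150 / 40), rel=1e-12
        )

    def test_two_point_law_interpolates_exactly(self):
        law = fit_power_law(KOFF_POINTS, "k_off_N")
        assert eval_power_law(law, 40.0) == pytest.approx(0.20, rel=1e-10)
        assert eval_power_law(law, 150.0) == pytest.approx(920.0, rel=1e-10)

    def test_five_point_affinity_regression(self):
        law = fit_power_law(KD_POINTS, "K_d_N")
        assert law.a > 0  # weaker nonspecific binding at higher salt
        for x, v in KD_POINTS:
            assert 0.5 < eval_power_law(law, x) / v < 2.0

    def test_flat_values_give_zero_slope(self):
        law = fit_power_law([(40, 5.0), (100, 5.0), (400, 5.0)])
        assert law.a == pytest.approx(0.0, abs=1e-14)

    def test_insufficient_or_invalid_points_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([(40.0, 1.0)])
        with pytest.raises(ValueError):
            fit_power_law([(40.0, 1.0), (150.0, -2.0)])


class TestPowerLawEval:
    def test_constant_law(self):
        law = _flat("D1", 2.5e6)
        assert eval_power_law(law, 77.7) == pytest.approx(2.5e6, rel=1e-12)

    def test_extrapolation_warns(self):
        law = fit_power_law(KOFF_POINTS)
        with pytest.warns(UserWarning, match="extrapolating"):
            eval_power_law(law, 400.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            eval_power_law(_flat("D1", 1.0), 0.0)


class TestDecompositionProfile:
    def test_flat_laws_give_constant_profile(self, cond):
        laws = {
            "k_off_N": _flat("k_off_N", 920.0),
            "k_IT_N": _flat("k_IT_N", 1e7),
            "D1": _flat("D1", 2.5e6),
            "K_d_N": _flat("K_d_N", 16e-6),
        }
        prof = decomposition_profile(laws, cond, np.geomspace(40, 400, 7))
        ka = prof.k_a
        assert np.allclose(ka, ka[0], rtol=1e-12)

    def test_measured_trend_directions(self, cond):
        # laws through the measured endpoints: antenna and transfer
        # enhancements fall with salt, the untrapped fraction rises
        laws = default_power_laws(cond)
        prof = decomposition_profile(laws, cond, np.geomspace(40, 150, 25))
        S = np.array([d.S for d in prof.decompositions])
        eta = np.array([d.eta for d in prof.decompositions])
        rho = np.array([d.rho for d in prof.decompositions])
        assert np.all(np.diff(S) < 0)
        assert np.all(np.diff(eta) < 0)
        assert np.all(np.diff(rho) > 0)

    def test_invariants_hold_at_every_grid_point(self, cond):
        prof = decomposition_profile(
            default_power_laws(cond), cond, np.geomspace(40, 150, 25)
        )
        for d in prof.decompositions:
            assert 0 < d.rho <= 1
            assert d.eta >= 1
            assert 1 <= d.S <= cond.L

    def test_single_point_grid_equals_direct_call(self, cond):
        laws = default_power_laws(cond)
        prof = decomposition_profile(laws, cond, [150.0])
        from targetsearch.ionic import _params_at

        direct = decompose(_params_at(laws, 150.0, 2), cond)
        assert prof.decompositions[0] == direct

    def test_missing_law_rejected(self, cond):
        laws = default_power_laws(cond)
        laws.pop("D1")
        with pytest.raises(ValueError, match="D1"):
            decomposition_profile(laws, cond, [100.0])


def _opposing_trend_laws():
    """rho rises (K_d,N up fast) while k_on,N falls: interior optimum."""
    return {
        "k_off_N": PowerLaw("k_off_N", 1.0, math.log10(920) - 1.0 * math.log10(150), (40, 400)),
        "K_d_N": PowerLaw("K_d_N", 4.0, math.log10(2.7e-5) - 4.0 * math.log10(150), (40, 400)),
        "k_IT_N": _flat("k_IT_N", 1e7),
        "D1": _flat("D1", 2.5e6),
    }


class TestOptimum:
    def test_monotone_profile_flags_boundary(self, cond):
        # both decay channels fall as KCl^-2 at flat D1 and K_d,N:
        # 1/tau_N falls faster than the antenna grows, so k_a decreases
        laws = {
            "k_off_N": PowerLaw("k_off_N", -2.0, math.log10(920.0) + 2 * math.log10(150), (40, 400)),
            "k_IT_N": PowerLaw("k_IT_N", -2.0, math.log10(1e7) + 2 * math.log10(150), (40, 400)),
            "D1": _flat("D1", 2.5e6),
            "K_d_N": _flat("K_d_N", 16e-6),
        }
        prof = decomposition_profile(laws, cond, np.geomspace(40, 400, 9))
        opt = find_optimum(prof)
        assert opt.on_boundary and opt.KCl_mM == pytest.approx(40.0)

    def test_interior_maximum_matches_dense_grid(self, cond):
        laws = _opposing_trend_laws()
        prof = decomposition_profile(laws, cond, np.geomspace(40, 400, 25))
        opt = find_optimum(prof)
        assert not opt.on_boundary
        dense = np.geomspace(40, 400, 10_001)
        dense_prof = decomposition_profile(laws, cond, dense)
        x_star = dense[np.argmax(dense_prof.k_a)]
        step = math.log(dense[1] / dense[0])
        assert abs(math.log(opt.KCl_mM / x_star)) < 2 * step

    def test_refinement_never_below_grid_best(self, cond):
        laws = _opposing_trend_laws()
        prof = decomposition_profile(laws, cond, np.geomspace(40, 400, 25))
        opt = find_optimum(prof)
        assert opt.k_a >= prof.k_a.max() * (1 - 1e-12)

    def test_randomized_law_sets_agree_with_dense_argmax(self, cond, rng):
        # golden-section refinement vs brute force over random law sets
        grid = np.geomspace(40, 400, 21)
        dense = np.geomspace(40, 400, 10_001)
        step = math.log(dense[1] / dense[0])
        for _ in range(50):
            a_off = rng.uniform(0, 3)
            a_kd = rng.uniform(1, 5)
            laws = {
                "k_off_N": PowerLaw("k_off_N", a_off,
                                    math.log10(920) - a_off * math.log10(150),
                                    (40, 400)),
                "K_d_N": PowerLaw("K_d_N", a_kd,
                                  math.log10(16e-6) - a_kd * math.log10(150),
                                  (40, 400)),
                "k_IT_N": PowerLaw("k_IT_N", rng.uniform(-1, 0), 7.0, (40, 400)),
                "D1": PowerLaw("D1", rng.uniform(-2, 0), 6.5, (40, 400)),
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof = decomposition_profile(laws, cond, grid)
                opt = find_optimum(prof)
                ka_dense = decomposition_profile(laws, cond, dense).k_a
            x_star = dense[np.argmax(ka_dense)]
            if opt.on_boundary:
                assert abs(math.log(opt.KCl_mM / x_star)) <= math.log(grid[1] / grid[0]) + 1e-9
            else:
                assert abs(math.log(opt.KCl_mM / x_star)) < 2 * step

    def test_too_few_grid_points_rejected(self, cond):
        prof = decomposition_profile(
            default_power_laws(cond), cond, [60.0, 80.0, 100.0]
        )
        with pytest.raises(ValueError, match="5 grid"):
            find_optimum(prof)
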