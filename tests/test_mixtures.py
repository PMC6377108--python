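"""Mixture DRFs: effective doses, inclusion-exclusion, reductions, J-shape."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emergentdrf import (
    CommonModeModel,
    CommonModeParams,
    DissimilarModeModel,
    DissimilarModeParams,
    FrechetParams,
    common_mode_effective_dose,
    common_mode_response,
    dissimilar_effective_doses,
    frechet_response,
    independent_union_response,
    nested_common_mode_dose,
)
from conftest import BENZENE_TOLUENE_CM, BENZENE_TOLUENE_DM, union_inclusion_exclusion


class TestCommonModeEffectiveDose:
    def test_zero_doses_zero(self):
        p = CommonModeParams(xi=(1.0, 2.0), eta=1.0)
        assert common_mode_effective_dose([0.0, 0.0], p) == 0.0

    def test_single_stressor_reduction(self):
        p = CommonModeParams(xi=(2.5,), eta=1.3, d0=0.4)
        assert common_mode_effective_dose([2.0], p) == pytest.approx(2.0 / 2.5 - 0.4)
        assert common_mode_effective_dose([0.5], p) == 0.0  # clipped at 0

    def test_benzene_200_toluene_0_interaction_vanishes(self):
        # with zero toluene the antagonistic term contributes nothing
        eff = common_mode_effective_dose([200.0, 0.0], BENZENE_TOLUENE_CM)
        assert eff == pytest.approx(200.0 / 3.0 - 4.2, rel=1e-12)

    def test_geometric_kernel_value(self):
        p = CommonModeParams(xi=(1.0, 1.0), eta=1.0, interactions={(0, 1): 0.5})
        # sqrt(4*9) = 6 -> 4 + 9 + 0.5*6
        assert common_mode_effective_dose([4.0, 9.0], p) == pytest.approx(16.0)

    def test_product_kernel_switch(self):
        p = CommonModeParams(
            xi=(1.0, 1.0), eta=1.0, interactions={(0, 1): 0.5}, kernel="product"
        )
        assert common_mode_effective_dose([4.0, 9.0], p) == pytest.approx(4 + 9 + 0.5 * 36)

    def test_background_stress_adds(self):
        p = CommonModeParams(xi=(1.0,), eta=1.0, d_b=0.7)
        assert common_mode_effective_dose([2.0], p) == pytest.approx(2.7)

    def test_dimension_mismatch(self):
        p = CommonModeParams(xi=(1.0, 2.0), eta=1.0)
        with pytest.raises(ValueError):
            common_mode_effective_dose([1.0], p)


class TestCommonModeResponse:
    def test_unit_effective_dose_gives_exp_minus_one(self):
        for eta in (0.5, 1.0, 4.0):
            p = CommonModeParams(xi=(1.0,), eta=eta)
            assert common_mode_response([1.0], p) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_reduces_to_frechet_on_grid(self):
        # J=1 common mode with threshold d0 (scaled axis) equals the
        # single-stressor Frechet with dose threshold d0*xi
        xi, eta, d0s = 2.0, 1.7, 0.6
        p = CommonModeParams(xi=(xi,), eta=eta, d0=d0s)
        fp = FrechetParams(xi=xi, eta=eta, d0=d0s * xi)
        d = np.linspace(0, 10, 101)
        np.testing.assert_allclose(
            common_mode_response(d[:, None], p), frechet_response(d, fp), rtol=0, atol=0
        )

    def test_monotone_when_interactions_nonnegative(self):
        p = CommonModeParams(xi=(1.0, 3.0), eta=2.0, interactions={(0, 1): 0.2})
        t = np.linspace(0, 5, 50)
        for other in (0.0, 1.0, 4.0):
            D = np.column_stack([t, np.full_like(t, other)])
            assert np.all(np.diff(common_mode_response(D, p)) >= -1e-15)

    def test_jshape_from_antagonism(self):
        # fixed high benzene dose; response dips then recovers in toluene
        t = np.linspace(0.0, 1000.0, 2001)
        D = np.column_stack([np.full_like(t, 200.0), t])
        r = common_mode_response(D, BENZENE_TOLUENE_CM)
        i_min = int(np.argmin(r))
        assert 0 < i_min < len(t) - 1
        assert r[i_min] < r[0] and r[-1] > r[i_min]

    def test_permutation_symmetry(self):
        p = CommonModeParams(
            xi=(1.0, 3.0, 0.5), eta=1.4, d0=0.2, interactions={(0, 2): -0.05, (1, 2): 0.1}
        )
        p_swapped = CommonModeParams(  # swap stressors 0 and 2
            xi=(0.5, 3.0, 1.0), eta=1.4, d0=0.2, interactions={(0, 2): -0.05, (0, 1): 0.1}
        )
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 4, size=(20, 3))
        np.testing.assert_allclose(
            common_mode_response(D, p), common_mode_response(D[:, [2, 1, 0]], p_swapped)
        )

    def test_interaction_nullity(self):
        p0 = CommonModeParams(xi=(1.0, 2.0), eta=1.0)
        p_zero = CommonModeParams(xi=(1.0, 2.0), eta=1.0, interactions={(0, 1): 0.0})
        rng = np.random.default_rng(1)
        D = rng.uniform(0, 5, size=(30, 2))
        np.testing.assert_array_equal(
            common_mode_response(D, p0), common_mode_response(D, p_zero)
        )
        # zero co-dose kills the pair term regardless of the coefficient
        p_int = CommonModeParams(xi=(1.0, 2.0), eta=1.0, interactions={(0, 1): 3.3})
        D0 = np.column_stack([np.linspace(0, 5, 11), np.zeros(11)])
        np.testing.assert_array_equal(
            common_mode_response(D0, p_int), common_mode_response(D0, p0)
        )

    def test_loglinear_glm_form_at_eta_one(self):
        # with eta = 1 and no interactions, -1/ln F is affine in dose
        p = CommonModeParams(xi=(2.0, 5.0), eta=1.0, d0=0.3)
        rng = np.random.default_rng(2)
        D = rng.uniform(0.5, 6, size=(40, 2))
        F = common_mode_response(D, p)
        lin = -1.0 / np.log(F)
        X = np.column_stack([D, np.ones(len(D))])
        coef, *_ = np.linalg.lstsq(X, lin, rcond=None)
        np.testing.assert_allclose(coef, [1 / 2.0, 1 / 5.0, -0.3], rtol=1e-9)
        glm = np.exp(-1.0 / (D @ [1 / 2.0, 1 / 5.0] - 0.3))
        np.testing.assert_allclose(F, glm, rtol=1e-12)


class TestDissimilarMode:
    def test_threshold_dose_gives_zero_effective(self):
        eff = dissimilar_effective_doses([10.0, 125.0], BENZENE_TOLUENE_DM)
        np.testing.assert_array_equal(eff, [0.0, 0.0])

    def test_no_interaction_reduction(self):
        eff = dissimilar_effective_doses([142.0, 0.0], BENZENE_TOLUENE_DM)
        np.testing.assert_allclose(eff, [(142.0 - 10.0) / 6.0, 0.0])

    def test_interaction_threshold_gates_pair_term(self):
        p = DissimilarModeParams(
            per_stressor=(dict(xi=1.0, eta=1.0), dict(xi=1.0, eta=1.0)),
            interactions={(0, 1): 0.5},
            interaction_thresholds={(0, 1): 3.0},
            kernel="product",
        )
        # kernel d1*d2 = 2 below threshold 3 -> no interaction
        np.testing.assert_allclose(dissimilar_effective_doses([1.0, 2.0], p), [1.0, 2.0])
        # kernel 8 above threshold -> each pathway gains 0.5*(8-3)
        np.testing.assert_allclose(dissimilar_effective_doses([2.0, 4.0], p), [4.5, 6.5])

    def test_reduces_to_frechet_at_single_pathway(self):
        p = DissimilarModeParams(per_stressor=(dict(xi=2.0, eta=1.5, d0=0.3),))
        m = DissimilarModeModel(p)
        d = np.linspace(0, 8, 81)
        np.testing.assert_allclose(
            m.response(d[:, None]), frechet_response(d, FrechetParams(2.0, 1.5, 0.3))
        )

    def test_response_symmetry_under_relabelling(self):
        m = DissimilarModeModel(BENZENE_TOLUENE_DM)
        swapped = DissimilarModeModel(
            DissimilarModeParams(
                per_stressor=(dict(xi=30.0, eta=1.0, d0=125.0), dict(xi=6.0, eta=1.0, d0=10.0)),
                interactions={(0, 1): 0.0},
            )
        )
        rng = np.random.default_rng(3)
        D = rng.uniform(0, 300, size=(25, 2))
        np.testing.assert_allclose(m.response(D), swapped.response(D[:, ::-1]))


class TestIndependentUnion:
    def test_all_zero_effective_doses(self):
        assert independent_union_response([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]) == 0.0

    def test_sure_pathway_dominates(self):
        assert independent_union_response([1e12, 0.5], [1.0, 2.0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("I", [1, 2, 3, 4])
    def test_matches_subset_enumeration_oracle(self, I):
        rng = np.random.default_rng(10 + I)
        for _ in range(20):
            dp = rng.uniform(0, 3, size=I)
            etas = rng.uniform(0.3, 4, size=I)
            probs = [frechet_response(x, FrechetParams(1.0, e)) for x, e in zip(dp, etas)]
            expected = union_inclusion_exclusion(probs)
            got = independent_union_response(dp, etas)
            assert abs(got - expected) < 1e-12

    def test_two_pathway_closed_form(self):
        f1 = frechet_response(1.3, FrechetParams(1.0, 2.0))
        f2 = frechet_response(0.8, FrechetParams(1.0, 0.7))
        got = independent_union_response([1.3, 0.8], [2.0, 0.7])
        assert got == pytest.approx(f1 + f2 - f1 * f2, rel=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            independent_union_response([1.0, 2.0], [1.0])


class TestNestedCommonMode:
    def test_unit_scales_plain_dose_addition(self):
        p = CommonModeParams(xi=(1.0, 1.0), eta=1.0)
        assert nested_common_mode_dose([1.5, 2.5], p) == pytest.approx(4.0)

    def test_single_substressor(self):
        p = CommonModeParams(xi=(4.0,), eta=1.0, d0=0.25)
        assert nested_common_mode_dose([2.0], p) == pytest.approx(0.25)
        assert nested_common_mode_dose([0.0], p) == 0.0

    def test_nested_dose_feeds_outer_dissimilar_model(self):
        sub = CommonModeParams(xi=(1.0, 2.0), eta=1.0)
        collapsed = nested_common_mode_dose([2.0, 2.0], sub)  # 3.0
        outer = DissimilarModeParams(
            per_stressor=(dict(xi=1.0, eta=1.0), dict(xi=1.0, eta=2.0))
        )
        m = DissimilarModeModel(outer)
        assert m.response(np.array([collapsed, 0.5])) == pytest.approx(
            independent_union_response([3.0, 0.5], [1.0, 2.0])
        )


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    d1=st.floats(0, 50),
    d2=st.floats(0, 50),
    xi1=st.floats(0.1, 20),
    xi2=st.floats(0.1, 20),
    eta=st.floats(0.2, 10),
)
def test_common_mode_response_is_probability(d1, d2, xi1, xi2, eta):
    p = CommonModeParams(xi=(xi1, xi2), eta=eta, interactions={(0, 1): -0.01})
    r = common_mode_response([d1, d2], p)
    assert 0.0 <= r <= 1.0
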