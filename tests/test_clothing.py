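"""Unit and property tests for the dynamic clothing corrections."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from phstrain.clothing import (
    Algorithm,
    Category,
    ClothingEnsemble,
    IA_STATIC_CLO,
    Kinematics,
    category_for_icl,
    correction_factors,
    dynamic_clothing,
    dynamic_evaporative_resistance,
    dynamic_insulation,
    fcl_ratio,
)


def make_ens(icl, imt=0.38, rt=0.05, pr=1.0):
    return ClothingEnsemble(icl=icl, rt_static=rt, imt=imt, pr=pr)


class TestFclRatio:
    @pytest.mark.parametrize(
        "icl, expected",
        [(1.0, 1.3), (0.0, 1.0), (2.01, 1.603)],
    )
    def test_values(self, icl, expected):
        assert fcl_ratio(icl) == pytest.approx(expected, abs=1e-12)

    def test_negative_icl_rejected(self):
        with pytest.raises(ValueError):
            fcl_ratio(-0.1)


class TestCategory:
    @pytest.mark.parametrize(
        "icl, cat",
        [(0.2, Category.LC), (0.59, Category.LC), (0.6, Category.NC),
         (1.08, Category.NC), (1.4, Category.NC), (1.41, Category.SC),
         (2.01, Category.SC)],
    )
    def test_cutpoints(self, icl, cat):
        assert category_for_icl(icl) is cat

    def test_ensemble_derives_category(self):
        assert make_ens(0.48).category is Category.LC
        assert make_ens(2.01).category is Category.SC

    @pytest.mark.parametrize(
        "kwargs",
        [dict(icl=-1, rt_static=0.05, imt=0.4),
         dict(icl=1, rt_static=0.05, imt=0.0),
         dict(icl=1, rt_static=0.05, imt=1.2),
         dict(icl=1, rt_static=-0.1, imt=0.4),
         dict(icl=1, rt_static=0.05, imt=0.4, pr=0.5)],
    )
    def test_invalid_ensembles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClothingEnsemble(**kwargs)


class TestCorrectionFactors:
    def test_iso9920_still_air_reference(self):
        corr_tot, corr_a, clamped = correction_factors(
            "ISO9920_NC", Kinematics(va=0.15, vw=0.0, var=0.15)
        )
        assert corr_tot == pytest.approx(1.0, abs=1e-12)
        assert corr_a == pytest.approx(1.0, abs=1e-12)
        assert not clamped

    def test_iso7933_hand_value(self):
        # e^(0.043 − 0.398·0.33 + 0.066·0.33² − 0.378·1.25 + 0.094·1.25²)
        corr_tot, _, _ = correction_factors(
            "ISO7933_NC", Kinematics(va=0.33, vw=1.25, var=0.33)
        )
        assert corr_tot == pytest.approx(0.666, abs=5e-4)

    def test_iso9920_sc_reference_point(self):
        corr_tot, _, _ = correction_factors(
            "ISO9920_SC", Kinematics(va=0.4, vw=0.0, var=0.4), pr=1.0
        )
        assert corr_tot == pytest.approx(1.0, abs=1e-12)

    def test_sc_requires_pr(self):
        with pytest.raises(ValueError, match="pr"):
            correction_factors("ISO9920_SC", Kinematics(va=0.5, vw=0.5, var=0.5))

    def test_out_of_range_inputs_clamped_and_flagged(self):
        in_range, _, flag_in = correction_factors(
            "ISO9920_NC", Kinematics(va=1.0, vw=1.2, var=1.0)
        )
        clamped, _, flag_out = correction_factors(
            "ISO9920_NC", Kinematics(va=1.0, vw=1.25, var=1.0)
        )
        assert not flag_in and flag_out
        assert clamped == pytest.approx(in_range)  # vw clamped to 1.2

    @given(
        var=st.floats(0.15, 3.0),
        vw=st.floats(0.0, 1.2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_iso9920_factors_at_most_one_in_range(self, var, vw):
        corr_tot, corr_a, _ = correction_factors(
            "ISO9920_NC", Kinematics(va=var, vw=vw, var=var)
        )
        assert corr_tot <= 1.0 + 1e-12
        assert corr_a <= 1.0 + 1e-12

    @given(var=st.floats(0.15, 3.0), vw=st.floats(0.0, 1.19))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_iso9920_nc_nonincreasing_in_walking_speed(self, var, vw):
        # corr_tot's exponent falls in vw over the whole validity range
        # (stationary point 0.492/0.352 ≈ 1.40 m/s); corr_a's turns at
        # 0.462/0.402 ≈ 1.149 m/s, so monotonicity is asserted up to there
        kin_lo = Kinematics(va=var, vw=vw, var=var)
        kin_hi = Kinematics(va=var, vw=min(vw + 0.01, 1.2), var=var)
        lo = correction_factors("ISO9920_NC", kin_lo)
        hi = correction_factors("ISO9920_NC", kin_hi)
        assert hi[0] <= lo[0] + 1e-12
        if vw + 0.01 <= 1.149:
            assert hi[1] <= lo[1] + 1e-12


# independently coded plain-arithmetic oracles (no shared code with the package)
def _oracle(variant, var, vw, pr=1.0):
    e = math.exp
    if variant == "ISO7933_NC":
        return (
            e(0.043 - 0.398 * var + 0.066 * var * var - 0.378 * vw + 0.094 * vw * vw),
            e(-0.472 * var + 0.047 * var * var - 0.342 * vw + 0.117 * vw * vw),
        )
    if variant == "ISO9920_NC":
        d = var - 0.15
        return (
            e(-0.281 * d + 0.044 * d * d - 0.492 * vw + 0.176 * vw * vw),
            e(-0.533 * d + 0.069 * d * d - 0.462 * vw + 0.201 * vw * vw),
        )
    if variant == "ISO9920_SC":
        d = var - 0.4
        return (e(-0.0512 * d + 0.000794 * d * d - 0.0639 * vw) * pr**0.144, None)
    if variant == "LU":
        d = var - 0.15
        return (e(-0.393 * d + 0.0393 * d * d - 0.0728 * vw + 0.053 * vw * vw), None)
    raise AssertionError(variant)


@pytest.mark.parametrize(
    "variant, var_range",
    [("ISO7933_NC", (0.0, 3.0)), ("ISO9920_NC", (0.15, 3.5)),
     ("ISO9920_SC", (0.4, 18.0)), ("LU", (0.15, 5.2))],
)
def test_exponential_formulas_match_independent_oracle(variant, var_range):
    """100 random in-range inputs agree with a separate arithmetic coding."""
    import random

    rng = random.Random(20200905)
    for _ in range(100):
        var = rng.uniform(*var_range)
        vw = rng.uniform(0.0, 1.2)
        pr = rng.uniform(1.0, 1000.0)
        kin = Kinematics(va=var, vw=vw, var=var)
        want_tot, want_a = _oracle(variant, var, vw, pr)
        if variant == "LU":
            ens = make_ens(0.3)
            dyn = dynamic_insulation(ens, kin, Algorithm.LU)
            assert dyn.corr_tot == pytest.approx(want_tot, abs=1e-12)
        else:
            got_tot, got_a, _ = correction_factors(variant, kin, pr=pr)
            assert got_tot == pytest.approx(want_tot, abs=1e-12)
            if want_a is not None:
                assert got_a == pytest.approx(want_a, abs=1e-12)


class TestDynamicInsulation:
    def test_static_total_insulation(self):
        # Itot = Icl + Ia/fcl at 1 clo
        assert make_ens(1.0).itot_static == pytest.approx(1.0 + 0.716 / 1.3, abs=1e-12)

    def test_lu_rejected_outside_light_clothing(self):
        with pytest.raises(ValueError, match="light clothing"):
            dynamic_insulation(make_ens(1.0), Kinematics(va=0.5, vw=0.5), Algorithm.LU)

    def test_iso7933_blends_factors_below_06_clo(self):
        kin = Kinematics(va=0.5, vw=0.4, var=0.5)
        dyn = dynamic_insulation(make_ens(0.3), kin, Algorithm.ISO7933)
        tot, a, _ = correction_factors("ISO7933_NC", kin)
        blended = ((0.6 - 0.3) * a + 0.3 * tot) / 0.6
        assert dyn.corr_tot == pytest.approx(blended, abs=1e-12)

    def test_iso9920_lc_interpolates_towards_boundary_layer(self):
        kin = Kinematics(va=0.5, vw=0.4, var=0.5)
        dyn = dynamic_insulation(make_ens(0.2), kin, Algorithm.ISO9920)
        _, corr_a, _ = correction_factors("ISO9920_NC", kin)
        ia_dyn = corr_a * IA_STATIC_CLO
        # interpolation pulls the total 2/3 of the way to the dynamic air layer
        assert dyn.itot_dyn < make_ens(0.2).itot_static
        assert dyn.ia_dyn == pytest.approx(ia_dyn, abs=1e-12)

    @given(
        icl=st.floats(0.1, 2.2),
        va=st.floats(0.0, 3.5),
        vw=st.floats(0.0, 1.5),
        algo=st.sampled_from([Algorithm.ISO7933, Algorithm.ISO9920, Algorithm.LU]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_insulation_split_consistency(self, icl, va, vw, algo):
        """Icl,dyn·fcl... the split always recombines: Icl,dyn + Ia,dyn/fcl = Itot,dyn."""
        ens = make_ens(icl)
        if algo is Algorithm.LU and ens.category is not Category.LC:
            return
        dyn = dynamic_insulation(ens, Kinematics(va=va, vw=vw), algo)
        assert dyn.icl_dyn + dyn.ia_dyn / ens.fcl == pytest.approx(
            dyn.itot_dyn, abs=1e-12
        )
        assert dyn.itot_dyn > 0 and dyn.ia_dyn > 0


class TestDynamicEvaporativeResistance:
    def test_still_air_identities(self):
        # Corr_E(1) = 2.6 − 6.5 + 4.9 = 1 and the single-factor polynomial at 1 is 1
        ens = make_ens(1.0, imt=0.38, rt=0.05)
        kin = Kinematics(va=0.15, vw=0.0, var=0.15)
        dyn = dynamic_insulation(ens, kin, Algorithm.ISO9920)
        assert dyn.corr_tot == pytest.approx(1.0, abs=1e-12)
        rt_dyn, imt_dyn = dynamic_evaporative_resistance(ens, dyn, Algorithm.ISO9920)
        assert rt_dyn == pytest.approx(0.05, abs=1e-12)
        # ISO 7933 route at its own corr_tot = 1: imt unchanged
        dyn7933 = dynamic_insulation(ens, Kinematics(va=0.1096, vw=0.0, var=0.1096),
                                     Algorithm.ISO7933)
        _, imt_dyn = dynamic_evaporative_resistance(ens, dyn7933, Algorithm.ISO7933)
        assert imt_dyn == pytest.approx(0.38 * (2.6 * dyn7933.corr_tot**2
                                                - 6.5 * dyn7933.corr_tot + 4.9), abs=1e-9)

    def test_imt_dyn_capped(self):
        # strong pumping raises Corr_E; the dynamic index must stay at 0.9
        ens = make_ens(1.0, imt=0.8)
        kin = Kinematics(va=3.0, vw=1.2)
        dyn = dynamic_insulation(ens, kin, Algorithm.ISO7933)
        rt_dyn, imt_dyn = dynamic_evaporative_resistance(ens, dyn, Algorithm.ISO7933)
        assert imt_dyn == pytest.approx(0.9)
        assert rt_dyn == pytest.approx(dyn.itot_dyn * 0.155 / (0.9 * 16.7))

    def test_lewis_relation_links_iso9920_outputs(self):
        ens = make_ens(1.0)
        kin = Kinematics(va=1.0, vw=0.8)
        dyn = dynamic_insulation(ens, kin, Algorithm.ISO9920)
        rt_dyn, imt_dyn = dynamic_evaporative_resistance(ens, dyn, Algorithm.ISO9920)
        assert imt_dyn * 16.7 * rt_dyn == pytest.approx(dyn.itot_dyn * 0.155, rel=1e-12)
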