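"""CBS extrapolation: closed forms, exact recovery, linearity."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from redoxbench import (
    ComponentEnergy,
    ExtrapolationParams,
    HfCbsMode,
    Quantity,
    Unit,
    hartree,
    hf_exponential_cbs,
    scheme1_cbs,
    scheme2_cbs,
    two_point_power_cbs,
)
from redoxbench.extrapolation import ExtrapolationError


class TestTwoPointPowerLaw:
    def test_constant_series_is_its_own_limit(self):
        got = two_point_power_cbs(hartree(-1.0), hartree(-1.0), 2, 3, 4.93)
        assert got.value == pytest.approx(-1.0, abs=1e-12)

    def test_inverse_cube_tz_qz_closed_form(self):
        # solve E(X) = E_CBS + A X^-3 at X=3,4 by hand:
        # E_CBS = (64*(-0.95) - 27*(-0.9)) / 37 = -0.986486...
        got = two_point_power_cbs(hartree(-0.9), hartree(-0.95), 3, 4, 3.0)
        assert got.value == pytest.approx((64 * -0.95 - 27 * -0.9) / 37,
                                          abs=1e-12)
        assert got.value == pytest.approx(-0.986486, abs=5e-7)

    def test_planted_power_law_recovered_exactly(self):
        cbs, amp, p = -2.0, 0.5, 2.13
        series = {x: cbs + amp * x ** (-p) for x in (2, 3)}
        got = two_point_power_cbs(hartree(series[2]), hartree(series[3]),
                                  2, 3, p)
        assert got.value == pytest.approx(cbs, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        cbs=st.floats(-2000, 0), amp=st.floats(-5, 5),
        p=st.floats(0.5, 8), x_lo=st.integers(2, 4),
    )
    def test_recovery_property(self, cbs, amp, p, x_lo):
        x_hi = x_lo + 1
        e = {x: cbs + amp * x ** (-p) for x in (x_lo, x_hi)}
        got = two_point_power_cbs(hartree(e[x_lo]), hartree(e[x_hi]),
                                  x_lo, x_hi, p)
        assert got.value == pytest.approx(cbs, abs=1e-8 + 1e-10 * abs(cbs))

    def test_degenerate_cardinals_rejected(self):
        with pytest.raises(ExtrapolationError):
            two_point_power_cbs(hartree(-1.0), hartree(-1.1), 3, 3, 3.0)
        with pytest.raises(ExtrapolationError):
            two_point_power_cbs(hartree(-1.0), hartree(-1.1), 2, 3, -1.0)

    def test_weights_sum_to_one(self):
        # extrapolating the constant-1 series returns exactly 1 for any p
        for p in (0.5, 2.13, 3.0, 4.93):
            got = two_point_power_cbs(hartree(1.0), hartree(1.0), 2, 3, p)
            assert got.value == 1.0


class TestSchemeOne:
    def test_tz_hf_coefficient_value(self):
        # 3^4.93 / (3^4.93 - 2^4.93) = 225.1767/(225.1767 - 30.5154),
        # evaluated with an independent high-precision route (sympy)
        import sympy

        oracle = float(sympy.N(sympy.Rational(3) ** sympy.Rational(493, 100) /
                               (sympy.Rational(3) ** sympy.Rational(493, 100)
                                - sympy.Rational(2) ** sympy.Rational(493, 100)),
                               20))
        coeff = 3 ** 4.93 / (3 ** 4.93 - 2 ** 4.93)
        assert coeff == pytest.approx(oracle, abs=1e-12)
        assert coeff == pytest.approx(1.156709, abs=5e-7)
        # scheme1 applied to (0, 1) HF series returns exactly that weight
        e_dz = ComponentEnergy(hf=hartree(0.0), corr=hartree(0.0))
        e_tz = ComponentEnergy(hf=hartree(1.0), corr=hartree(0.0))
        got = scheme1_cbs(e_dz, e_tz)
        assert got.cbs_hf.value == pytest.approx(coeff, abs=1e-12)

    def test_planted_components_recovered(self):
        # HF follows X^-4.93, correlation X^-2.13: scheme I's exact regime
        hf_cbs, corr_cbs = -1260.0, -2.4
        comps = {
            x: ComponentEnergy(
                hf=hartree(hf_cbs + 0.05 * x ** -4.93),
                corr=hartree(corr_cbs + 0.1 * x ** -2.13),
            ) for x in (2, 3)
        }
        got = scheme1_cbs(comps[2], comps[3])
        assert got.cbs_hf.value == pytest.approx(hf_cbs, abs=1e-10)
        assert got.cbs_corr.value == pytest.approx(corr_cbs, abs=1e-10)
        assert got.cbs_total.value == pytest.approx(hf_cbs + corr_cbs,
                                                    abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.tuples(st.floats(-100, 0), st.floats(-100, 0),
                    st.floats(-5, 0), st.floats(-5, 0)),
        b=st.tuples(st.floats(-100, 0), st.floats(-100, 0),
                    st.floats(-5, 0), st.floats(-5, 0)),
    )
    def test_linearity_of_scheme1(self, a, b):
        """Extrapolating a difference equals differencing extrapolations."""
        def comp(hf_dz, hf_tz, c_dz, c_tz):
            return (ComponentEnergy(hf=hartree(hf_dz), corr=hartree(c_dz)),
                    ComponentEnergy(hf=hartree(hf_tz), corr=hartree(c_tz)))

        ea_dz, ea_tz = comp(*a)
        eb_dz, eb_tz = comp(*b)
        diff_dz = ComponentEnergy(hf=ea_dz.hf - eb_dz.hf,
                                  corr=ea_dz.corr - eb_dz.corr)
        diff_tz = ComponentEnergy(hf=ea_tz.hf - eb_tz.hf,
                                  corr=ea_tz.corr - eb_tz.corr)
        of_diff = scheme1_cbs(diff_dz, diff_tz).cbs_total.value
        diff_of = (scheme1_cbs(ea_dz, ea_tz).cbs_total
                   - scheme1_cbs(eb_dz, eb_tz).cbs_total).value
        assert of_diff == pytest.approx(diff_of, abs=1e-7)


class TestExponentialHf:
    def test_planted_exponential_recovered(self):
        # E(X) = -100 + exp(-X)
        vals = [-100 + math.exp(-x) for x in (2, 3, 4)]
        got = hf_exponential_cbs(*(hartree(v) for v in vals))
        assert got.value == pytest.approx(-100.0, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        cbs=st.floats(-2000, 0), amp=st.floats(0.001, 5),
        decay=st.floats(0.2, 3),
    )
    def test_recovery_property(self, cbs, amp, decay):
        vals = [cbs + amp * math.exp(-decay * x) for x in (2, 3, 4)]
        got = hf_exponential_cbs(*(hartree(v) for v in vals))
        assert got.value == pytest.approx(cbs, abs=1e-8 + 1e-10 * abs(cbs))

    def test_constant_series_rejected(self):
        with pytest.raises(ExtrapolationError):
            hf_exponential_cbs(hartree(-1.0), hartree(-1.0), hartree(-1.0))

    def test_linear_decay_rejected(self):
        # d1 == d2: no exponential interpolant, denominator would vanish
        with pytest.raises(ExtrapolationError, match="not contracting"):
            hf_exponential_cbs(hartree(-1.0), hartree(-1.1), hartree(-1.2))

    def test_non_monotone_rejected(self):
        with pytest.raises(ExtrapolationError, match="not monotone"):
            hf_exponential_cbs(hartree(-1.0), hartree(-1.2), hartree(-1.1))

    def test_not_linear_documented(self):
        """The three-point exponential fit is nonlinear: fitting a sum of
        two exponential series differs from summing the fits."""
        s1 = [math.exp(-0.5 * x) for x in (2, 3, 4)]
        s2 = [2.0 * math.exp(-2.0 * x) for x in (2, 3, 4)]
        fit_sum = hf_exponential_cbs(
            *(hartree(a + b) for a, b in zip(s1, s2))).value
        sum_fit = (hf_exponential_cbs(*(hartree(v) for v in s1)).value
                   + hf_exponential_cbs(*(hartree(v) for v in s2)).value)
        assert abs(fit_sum - sum_fit) > 1e-6


class TestSchemeTwo:
    def test_correlation_part_matches_inverse_cube(self):
        mk = lambda hf, c: ComponentEnergy(hf=hartree(hf), corr=hartree(c))
        got = scheme2_cbs(mk(-100.0, -0.8), mk(-100.01, -0.9),
                          mk(-100.011, -0.95))
        assert got.cbs_corr.value == pytest.approx((64 * -0.95 - 27 * -0.9) / 37,
                                                   abs=1e-12)

    def test_planted_components_recovered(self):
        hf_cbs, corr_cbs, b = -1260.0, -2.4, 1.4
        comps = {
            x: ComponentEnergy(
                hf=hartree(hf_cbs + 0.05 * math.exp(-b * x)),
                corr=hartree(corr_cbs + 0.1 * x ** -3.0),
            ) for x in (2, 3, 4)
        }
        got = scheme2_cbs(comps[2], comps[3], comps[4])
        assert got.cbs_hf.value == pytest.approx(hf_cbs, abs=1e-10)
        assert got.cbs_corr.value == pytest.approx(corr_cbs, abs=1e-10)

    def test_eq2_hf_mode_reuses_power_law(self):
        params = ExtrapolationParams(hf_cbs_mode=HfCbsMode.EQ2)
        mk = lambda hf, c: ComponentEnergy(hf=hartree(hf), corr=hartree(c))
        comps = {x: mk(-100 + 0.05 * x ** -4.93, -1 + 0.1 * x ** -3.0)
                 for x in (2, 3, 4)}
        got = scheme2_cbs(comps[2], comps[3], comps[4], params)
        # power-law HF input: eq2 mode recovers the limit exactly
        assert got.cbs_hf.value == pytest.approx(-100.0, abs=1e-10)

    def test_power_law_hf_through_exponential_fit_mismatch(self):
        """A power-law HF series fed to the exponential fit lands off the
        true limit by exactly the closed-form mismatch."""
        cbs, amp, p = -100.0, 0.05, 4.93
        vals = [cbs + amp * x ** (-p) for x in (2, 3, 4)]
        got = hf_exponential_cbs(*(hartree(v) for v in vals)).value
        d1, d2 = vals[0] - vals[1], vals[1] - vals[2]
        expected = vals[2] - d2 * d2 / (d1 - d2)  # independent evaluation
        assert got == pytest.approx(expected, abs=1e-12)
        assert abs(got - cbs) > 1e-6  # and it is genuinely off the limit

    def test_scheme2_linearity_of_correlation_part(self):
        mk = lambda c: ComponentEnergy(hf=hartree(-1.0), corr=hartree(c))
        a = {x: -0.9 + 0.1 * x ** -3.0 for x in (2, 3, 4)}
        b = {x: -0.5 + 0.03 * x ** -3.0 for x in (2, 3, 4)}
        corr_of_diff = scheme2_cbs(
            mk(a[2] - b[2]), mk(a[3] - b[3]), mk(a[4] - b[4]),
            ExtrapolationParams(hf_cbs_mode=HfCbsMode.EQ2),
        ).cbs_corr.value
        diff_of_corr = (
            scheme2_cbs(mk(a[2]), mk(a[3]), mk(a[4]),
                        ExtrapolationParams(hf_cbs_mode=HfCbsMode.EQ2)).cbs_corr
            - scheme2_cbs(mk(b[2]), mk(b[3]), mk(b[4]),
                          ExtrapolationParams(hf_cbs_mode=HfCbsMode.EQ2)).cbs_corr
        ).value
        assert corr_of_diff == pytest.approx(diff_of_corr, abs=1e-10)


def test_cbs_lies_below_largest_basis_for_decreasing_series():
    """For a monotonically decreasing reduction-energy series, both schemes
    extrapolate below the largest-basis value (the published CBS-minus-QZ
    columns are uniformly negative)."""
    mk = lambda hf, c: ComponentEnergy(hf=hartree(hf), corr=hartree(c))
    # series matching each scheme's assumed decay, decreasing toward the
    # limit with basis-set increments of a few millihartree per step
    s1_comps = {x: mk(-0.95 + 0.05 * x ** -4.93, -0.01 + 0.01 * x ** -2.13)
                for x in (2, 3, 4)}
    s2_comps = {x: mk(-0.95 + 0.05 * math.exp(-1.4 * x),
                      -0.01 + 0.01 * x ** -3.0) for x in (2, 3, 4)}
    s1 = scheme1_cbs(s1_comps[2], s1_comps[3]).cbs_total.value
    s2 = scheme2_cbs(s2_comps[2], s2_comps[3], s2_comps[4]).cbs_total.value
    assert s1 < s1_comps[4].total.value
    assert s2 < s2_comps[4].total.value
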