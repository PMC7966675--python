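"""Attributable fractions, prevention, PM2.5 burden, vectorial capacity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from climhealth.burden import (
    ExposureResponse,
    VectorParams,
    apply_prevention,
    attributable_fraction,
    heatwave_attributable_deaths,
    pm25_attributable_deaths,
    prevented_fraction,
    vectorial_capacity,
    vc_percent_change,
)


class TestAttributableFraction:
    @pytest.mark.parametrize(
        "rr,expected",
        [(1.0, 0.0), (2.0, 0.5), (1.104, (1.104 - 1) / 1.104)],
    )
    def test_identity(self, rr, expected):
        assert attributable_fraction(rr) == pytest.approx(expected, abs=1e-12)

    def test_elderly_excess_risk_value(self):
        # a 10.4% higher risk of dying on heatwave days -> AF ≈ 0.0942
        assert attributable_fraction(1.104) == pytest.approx(0.0942, abs=5e-4)

    def test_protective_rr_floored(self):
        assert attributable_fraction(0.8) == 0.0

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.0)

    @given(rr=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None)
    def test_af_always_in_unit_interval(self, rr):
        af = attributable_fraction(rr)
        assert 0.0 <= af < 1.0


class TestHeatwaveDeaths:
    def test_null_rr_yields_zero(self):
        res = heatwave_attributable_deaths(100.0, 10, 1.0)
        assert res.total_deaths == 0.0

    def test_hand_computation(self):
        # 10 heatwave days × 100 deaths/day × (0.10/1.10)
        res = heatwave_attributable_deaths(100.0, 10, 1.10)
        assert res.total_deaths == pytest.approx(10 * 100 * (0.10 / 1.10))

    def test_linear_in_baseline(self):
        a = heatwave_attributable_deaths(100.0, 10, 1.2).total_deaths
        b = heatwave_attributable_deaths(200.0, 10, 1.2).total_deaths
        assert b == pytest.approx(2 * a)

    def test_never_exceeds_baseline(self):
        res = heatwave_attributable_deaths(100.0, 10, 5.0)
        assert res.total_deaths <= res.table["baseline_deaths"].sum()

    def test_location_fallback_warns(self, caplog):
        er = ExposureResponse(rr=1.2, by_location={"north": 1.5})
        res = heatwave_attributable_deaths(
            {"north": 10.0, "south": 10.0}, {"north": 5, "south": 5}, er
        )
        t = res.table.set_index("region")
        assert t.loc["north", "af"] == pytest.approx(0.5 / 1.5)
        assert t.loc["south", "af"] == pytest.approx(0.2 / 1.2)


class TestPrevention:
    @pytest.mark.parametrize("p,e,pf", [(0.0, 0.9, 0.0), (1.0, 1.0, 1.0), (0.9, 0.5, 0.45)])
    def test_product_model(self, p, e, pf):
        assert prevented_fraction(p, e) == pytest.approx(pf)

    def test_apply_prevention_identity_at_zero(self):
        assert apply_prevention(123.0, 0.0) == 123.0

    def test_full_prevention(self):
        assert apply_prevention(123.0, 1.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            prevented_fraction(1.2, 0.5)


class TestPM25:
    @staticmethod
    def curve(c):
        # piecewise-linear RR: 1 at 10 µg/m³ rising to 1.25 at 50
        return float(np.interp(c, [10.0, 50.0], [1.0, 1.25]))

    def test_reference_concentration(self):
        res = pm25_attributable_deaths(10.0, self.curve, 1000.0, reference_concentration=10.0)
        assert res.total_deaths == 0.0

    def test_af_at_curve_top(self):
        res = pm25_attributable_deaths(50.0, self.curve, 1000.0, reference_concentration=10.0)
        assert res.total_deaths == pytest.approx(0.2 * 1000.0)

    def test_monotone_in_concentration(self):
        deaths = [
            pm25_attributable_deaths(c, self.curve, 1000.0, 10.0).total_deaths
            for c in (10, 20, 30, 40, 50)
        ]
        assert all(a <= b for a, b in zip(deaths, deaths[1:]))


class TestVectorialCapacity:
    def test_zero_transmission_probability(self):
        vc, mean = vectorial_capacity([20, 25, 30], VectorParams(b_m=0.0))
        assert np.all(vc == 0.0) and mean == 0.0

    def test_constant_parameter_closed_form(self):
        # m·a²·b_m·b_h·e^{−μn}/μ = 1·0.04·0.25·e^{−1}/0.1
        _, mean = vectorial_capacity(
            [20.0], VectorParams(a=0.2, b_h=0.5, b_m=0.5, mu=0.1, n=10.0, m=1.0)
        )
        assert mean == pytest.approx(0.04 * 0.25 * np.exp(-1) / 0.1, rel=1e-12)
        assert mean == pytest.approx(0.0368, abs=1e-4)

    def test_single_interior_maximum_on_grid(self):
        t = np.linspace(14.0, 32.0, 400)
        vc, _ = vectorial_capacity(t, "aegypti")
        peak = int(np.argmax(vc))
        assert 0 < peak < len(t) - 1
        # unimodal: nondecreasing to the peak, nonincreasing after
        assert np.all(np.diff(vc[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(vc[peak:]) <= 1e-12)

    def test_homogeneity_in_m_and_a(self):
        base = VectorParams(a=0.2, b_h=0.5, b_m=0.5, mu=0.1, n=10.0, m=1.0)
        _, v0 = vectorial_capacity([20.0], base)
        _, v_m = vectorial_capacity(
            [20.0], VectorParams(a=0.2, b_h=0.5, b_m=0.5, mu=0.1, n=10.0, m=3.0)
        )
        _, v_a = vectorial_capacity(
            [20.0], VectorParams(a=0.4, b_h=0.5, b_m=0.5, mu=0.1, n=10.0, m=1.0)
        )
        assert v_m == pytest.approx(3 * v0)  # degree 1 in m
        assert v_a == pytest.approx(4 * v0)  # degree 2 in a

    def test_nonpositive_mortality_raises(self):
        with pytest.raises(ValueError, match="mu <= 0"):
            vectorial_capacity([20.0], VectorParams(mu=lambda t: np.zeros_like(t)))

    def test_warming_raises_vc_below_optimum(self):
        rng = np.random.default_rng(3)
        cool = rng.normal(22.0, 1.0, size=365)
        warm = cool + 1.0  # still below the VC-optimal temperature
        _, vc_cool = vectorial_capacity(cool, "aegypti")
        _, vc_warm = vectorial_capacity(warm, "aegypti")
        assert vc_warm >= vc_cool


class TestPercentChange:
    def test_no_change(self):
        assert vc_percent_change(1.5, 1.5) == 0.0

    def test_37_percent_arithmetic(self):
        assert vc_percent_change(1.0, 1.37) == pytest.approx(37.0)

    def test_halving(self):
        assert vc_percent_change(2.0, 1.0) == -50.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            vc_percent_change(0.0, 1.0)
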