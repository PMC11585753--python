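"""Model registry: forms, derivatives, derived-quantity rules, identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import growthcurves as gc
from growthcurves._exceptions import ModelDomainError

from conftest import CANONICAL_PARAMS, finite_diff_d1, finite_diff_d2

TWO_PI = 2 * math.pi

EXPECTED_P = {
    "monomolecular": 3, "bridges": 4, "janoschek": 4, "logistic": 3,
    "von_bertalanffy": 3, "richards": 4, "schumacher": 3, "morgan": 3,
    "chanter": 4, "weibull": 4, "sinusoidal": 4,
}


class TestRegistry:
    def test_eleven_models_with_expected_parameter_counts(self):
        specs = gc.list_models()
        assert [s.name for s in specs] == list(gc.MODEL_NAMES)
        assert {s.name: s.p for s in specs} == EXPECTED_P

    def test_sinusoidal_parameter_symbols(self):
        assert gc.get_model("sinusoidal").parameter_symbols == ("y0", "a", "b", "c")

    def test_parameter_vector_rejects_missing_extra_and_nonfinite(self):
        spec = gc.get_model("logistic")
        with pytest.raises(ValueError):
            spec.make_params({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            spec.make_params({"a": 1.0, "b": 2.0, "k": 0.1, "zz": 0.0})
        with pytest.raises(ValueError):
            spec.make_params({"a": 1.0, "b": float("nan"), "k": 0.1})

    def test_unknown_model_name(self):
        with pytest.raises(KeyError):
            gc.get_model("gompertz")


class TestPredict:
    def test_sinusoidal_at_hatch_equals_offset_plus_phase_term(self, sin1):
        # y(0) = y0 + a sin(c), the published initial-weight rule
        expected = sin1["y0"] + sin1["a"] * math.sin(sin1["c"])
        got = gc.predict(gc.get_model("sinusoidal"), sin1, 0.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-0.1133, abs=5e-4)

    def test_logistic_near_asymptote_at_one_year(self):
        p = gc.reference_params(1, "logistic")
        y = gc.predict(gc.get_model("logistic"), p, 360.0)
        assert y == pytest.approx(104.5 / (1 + 19.9255 * math.exp(-0.0163 * 360)), rel=1e-12)
        assert y == pytest.approx(98.92, abs=0.01)

    @pytest.mark.parametrize("name", ["monomolecular", "logistic", "von_bertalanffy"])
    def test_zero_rate_gives_constant_curve(self, name):
        spec = gc.get_model(name)
        params = dict(CANONICAL_PARAMS[name], k=0.0)
        t = np.array([10.0, 100.0, 300.0])
        y = gc.predict(spec, params, t)
        assert np.allclose(y, y[0])

    def test_domain_error_at_zero_age_with_negative_exponent(self):
        spec = gc.get_model("bridges")
        params = {"W0": 3.0, "a": 100.0, "k": 0.1, "m": -1.0}
        with pytest.raises(ModelDomainError):
            gc.predict(spec, params, 0.0)


class TestDerivativeConsistency:
    """d1/d2 agree with central finite differences of predict."""

    @pytest.mark.parametrize("name", gc.MODEL_NAMES)
    def test_first_and_second_derivatives_match_finite_differences(self, name):
        spec = gc.get_model(name)
        params = CANONICAL_PARAMS[name]
        ts = np.linspace(20.0, 350.0, 20)
        d1 = np.array([gc.agr(spec, params, t) for t in ts])
        d2 = np.array([gc.curvature(spec, params, t) for t in ts])
        fd1 = np.array([finite_diff_d1(spec, params, t) for t in ts])
        fd2 = np.array([finite_diff_d2(spec, params, t) for t in ts])
        s1 = np.max(np.abs(d1))
        s2 = np.max(np.abs(d2))
        assert np.all(np.abs(d1 - fd1) <= 1e-6 * np.maximum(np.abs(d1), s1))
        assert np.all(np.abs(d2 - fd2) <= 1e-5 * np.maximum(np.abs(d2), s2))

    @settings(deadline=None, max_examples=25)
    @given(
        y0=st.floats(10, 80), a=st.floats(5, 80),
        b=st.floats(300, 2000), c=st.floats(-6, 6),
        t=st.floats(10, 350),
    )
    def test_sinusoidal_derivatives_any_parameters(self, y0, a, b, c, t):
        spec = gc.get_model("sinusoidal")
        params = {"y0": y0, "a": a, "b": b, "c": c}
        scale = a * TWO_PI / b
        assert gc.agr(spec, params, t) == pytest.approx(
            finite_diff_d1(spec, params, t), abs=1e-6 * max(scale, 1e-9)
        )


class TestAgrAndCurvature:
    def test_sinusoidal_agr_peaks_at_amplitude_rate(self, sin1):
        spec = gc.get_model("sinusoidal")
        t_ip = gc.inflection_time(spec, sin1, (0, 360))
        peak = gc.agr(spec, sin1, t_ip)
        assert peak == pytest.approx(TWO_PI * sin1["a"] / sin1["b"], rel=1e-9)
        assert peak == pytest.approx(0.3827, abs=2e-4)

    def test_sinusoidal_agr_zero_at_quarter_period(self, sin1):
        spec = gc.get_model("sinusoidal")
        t = sin1["b"] * (math.pi / 2 - sin1["c"]) / TWO_PI + sin1["b"]  # theta = pi/2 (+2pi)
        assert gc.agr(spec, sin1, t) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoidal_curvature_vanishes_at_inflection(self, sin1):
        spec = gc.get_model("sinusoidal")
        t_ip = gc.inflection_time(spec, sin1, (0, 360))
        assert gc.curvature(spec, sin1, t_ip) == pytest.approx(0.0, abs=1e-10)

    def test_weibull_curvature_vanishes_exactly_at_ip_parameter(self, weib1):
        spec = gc.get_model("weibull")
        assert gc.curvature(spec, weib1, weib1["IP"]) == pytest.approx(0.0, abs=1e-12)


class TestInflection:
    def test_sinusoidal_inflection_days_match_published_rounding(self, sin1, sin2):
        spec = gc.get_model("sinusoidal")
        t1 = gc.inflection_time(spec, sin1, (0, 360))
        t2 = gc.inflection_time(spec, sin2, (0, 366))
        assert round(t1) == 174
        assert round(t2) == 90
        assert t1 == pytest.approx(174.4, abs=0.1)

    def test_sinusoidal_inflection_satisfies_phase_identity(self, sin1, sin2):
        # every admissible root has (2 pi t / b + c) = 0 mod pi
        spec = gc.get_model("sinusoidal")
        for p in (sin1, sin2):
            t = gc.inflection_time(spec, p, (0, 366))
            assert (TWO_PI * t / p["b"] + p["c"]) % math.pi == pytest.approx(
                0.0, abs=1e-8
            ) or math.pi - (TWO_PI * t / p["b"] + p["c"]) % math.pi < 1e-8

    def test_weibull_inflection_is_its_ip_parameter(self, weib1):
        spec = gc.get_model("weibull")
        assert gc.inflection_time(spec, weib1, (0, 400)) == pytest.approx(161.0)

    @pytest.mark.parametrize("dataset,expected", [(2, 98.9849), (3, 68.2845)])
    def test_weibull_ip_identity_on_other_datasets(self, dataset, expected):
        # complete the partial published sets with an initial-weight value;
        # the curvature root depends only on k and IP
        spec = gc.get_model("weibull")
        vals = gc.reference_values(dataset, "weibull")
        vals.setdefault("b", 2.0)
        t = gc.inflection_time(spec, spec.make_params(vals), (0, 400))
        assert t == pytest.approx(expected, rel=1e-9)

    def test_weibull_ip_identity_matches_bruteforce_sign_scan(self, weib1):
        spec = gc.get_model("weibull")
        grid = np.linspace(1.0, 400.0, 100_000)
        curv = np.array(gc.curvature(spec, weib1, grid))
        idx = np.where(np.diff(np.sign(curv)) != 0)[0]
        roots = grid[idx]
        assert len(roots) == 1
        assert roots[0] == pytest.approx(161.0, abs=0.01)

    def test_logistic_closed_form_inflection(self):
        p = gc.reference_params(1, "logistic")
        t = gc.inflection_time(gc.get_model("logistic"), p, (0, 400))
        assert t == pytest.approx(math.log(19.9255) / 0.0163, rel=1e-12)

    def test_von_bertalanffy_closed_form_inflection(self):
        p = gc.reference_params(1, "von_bertalanffy")
        t = gc.inflection_time(gc.get_model("von_bertalanffy"), p, (0, 600))
        assert t == pytest.approx(math.log(3 * 0.8580) / 0.00656, rel=1e-12)

    def test_inflection_outside_window_returns_none(self):
        # root t = b/k = 0 lies below the window
        spec = gc.get_model("monomolecular")
        assert gc.inflection_time(spec, {"a": 100.0, "b": 0.0, "k": 0.01}, (1, 400)) is None

    def test_invalid_window_raises(self, sin1):
        with pytest.raises(ValueError):
            gc.inflection_time(gc.get_model("sinusoidal"), sin1, (100, 100))

    def test_generic_root_search_agrees_with_closed_form(self):
        # strip the closed form off the logistic spec; bisection must agree
        from dataclasses import replace

        p = gc.reference_params(1, "logistic")
        spec = replace(gc.get_model("logistic"), closed_form_ip=None)
        t_num = gc.inflection_time(spec, p, (0, 400))
        assert t_num == pytest.approx(math.log(19.9255) / 0.0163, abs=1e-6)


class TestDerivedWeights:
    def test_sinusoidal_final_weight_rule(self, sin1, sin2):
        spec = gc.get_model("sinusoidal")
        assert gc.asymptotic_weight(spec, sin1) == pytest.approx(100.7184)
        assert gc.asymptotic_weight(spec, sin2) == pytest.approx(100.4001)

    def test_weibull_asymptote_is_a_parameter(self):
        vals = gc.reference_values(3, "weibull")
        vals.setdefault("b", 2.0)
        spec = gc.get_model("weibull")
        assert gc.asymptotic_weight(spec, spec.make_params(vals)) == pytest.approx(-0.9938)

    def test_saturating_models_asymptote_equals_a(self):
        vb = gc.reference_params(1, "von_bertalanffy")
        assert gc.asymptotic_weight(gc.get_model("von_bertalanffy"), vb) == 131.0
        lg = gc.reference_params(1, "logistic")
        assert gc.asymptotic_weight(gc.get_model("logistic"), lg) == 104.5

    def test_bridges_asymptote_is_w0_plus_a_matching_janoschek(self):
        br = gc.reference_params(1, "bridges")
        ja = gc.reference_params(1, "janoschek")
        a_br = gc.asymptotic_weight(gc.get_model("bridges"), br)
        assert a_br == pytest.approx(2.8732 + 108.1)
        assert a_br == pytest.approx(gc.asymptotic_weight(gc.get_model("janoschek"), ja), abs=0.08)

    def test_schumacher_and_morgan_have_no_asymptote(self):
        for name in ("schumacher", "morgan"):
            spec = gc.get_model(name)
            assert gc.asymptotic_weight(spec, CANONICAL_PARAMS[name]) is None

    def test_initial_weight_rules(self, sin1):
        assert gc.initial_weight(gc.get_model("sinusoidal"), sin1) == pytest.approx(
            sin1["y0"] + sin1["a"] * math.sin(sin1["c"])
        )
        ja = gc.reference_params(1, "janoschek")
        assert gc.initial_weight(gc.get_model("janoschek"), ja) == pytest.approx(2.8732)
        br = gc.reference_params(1, "bridges")
        assert gc.initial_weight(gc.get_model("bridges"), br) == pytest.approx(2.8732)


class TestEquivalences:
    @settings(deadline=None, max_examples=30)
    @given(
        a=st.floats(50, 200), b=st.floats(-2, 4),
        k=st.floats(0.001, 0.05), t=st.floats(0, 400),
    )
    def test_monomolecular_is_logistic_reparameterization(self, a, b, k, t):
        mono = gc.predict(gc.get_model("monomolecular"), {"a": a, "b": b, "k": k}, t)
        logi = gc.predict(gc.get_model("logistic"), {"a": a, "b": math.exp(b), "k": k}, t)
        assert mono == pytest.approx(logi, rel=1e-12)

    def test_published_b_values_satisfy_the_exponential_map(self):
        for ds, expected in [(1, 19.9255), (2, 13.4828), (3, 12.0333)]:
            b_mono = gc.reference_values(ds, "monomolecular")["b"]
            assert math.exp(b_mono) == pytest.approx(expected, abs=2e-3)

    @settings(deadline=None, max_examples=30)
    @given(
        w0=st.floats(0.5, 10), a=st.floats(50, 200),
        k=st.floats(1e-6, 1e-3), m=st.floats(1.2, 2.5), t=st.floats(0, 400),
    )
    def test_bridges_is_janoschek_reparameterization(self, w0, a, k, m, t):
        br = gc.predict(gc.get_model("bridges"), {"W0": w0, "a": a, "k": k, "m": m}, t)
        ja = gc.predict(
            gc.get_model("janoschek"), {"a": w0 + a, "W0": w0, "k": k, "m": m}, t
        )
        assert br == pytest.approx(ja, rel=1e-12, abs=1e-12)

    def test_chanter_dialect_switch_changes_exponent(self):
        params = CANONICAL_PARAMS["chanter"]
        ratio = gc.build_registry("ratio")["chanter"]
        product = gc.build_registry("product")["chanter"]
        y_r = ratio.predict(params, 200.0)
        y_p = product.predict(params, 200.0)
        assert y_r != pytest.approx(y_p)
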