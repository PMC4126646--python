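"""Tensile/bending curve metrics, power-law fits and the section formula."""

import math

import numpy as np
import pytest

from rootslope import synthetic
from rootslope.mechanics import (
    BendingTest,
    MechanicsConfig,
    TensileTest,
    bending_metrics,
    fit_tmax_power_law,
    second_moment_of_inertia,
    tensile_curve_metrics,
)


def _simple_tensile(peak_force=10.0, diameter=None, gauge=50.0, drop_to=0.1):
    """A clean three-phase curve breaking at (5 mm, peak_force)."""
    if diameter is None:
        diameter = math.sqrt(4 * 0.5 / math.pi)  # CSA = 0.5 mm^2
    disp = np.linspace(0.0, 5.0, 21)
    force = np.interp(disp, [0, 0.75, 3.0, 5.0], [0, 0.05, 0.75, 1.0]) * peak_force
    curve = np.vstack([np.append(disp, 5.2), np.append(force, drop_to * peak_force)]).T
    return TensileTest(
        root_id="r1", species="sp", diameters=(diameter,) * 3,
        gauge_length=gauge, curve=curve,
    )


class TestTensileMetrics:
    def test_t_max_is_peak_force_over_csa(self):
        res = tensile_curve_metrics(_simple_tensile(peak_force=10.0, gauge=200.0))
        assert res.t_max == pytest.approx(20.0)  # 10 N / 0.5 mm^2
        assert res.csa == pytest.approx(0.5)

    def test_eps_ult_is_displacement_over_gauge(self):
        res = tensile_curve_metrics(_simple_tensile(gauge=50.0))
        assert res.eps_ult == pytest.approx(100.0 * 5.0 / 50.0)  # 10 %

    def test_clamp_failure_marks_invalid(self):
        t = _simple_tensile(gauge=200.0)
        t.failure_location = "clamp"
        res = tensile_curve_metrics(t)
        assert not res.valid and "failure_clamp" in res.invalid_reasons

    def test_slippage_and_short_gauge_mark_invalid(self):
        t = _simple_tensile(gauge=200.0)
        t.slipped = True
        assert "clamp_slippage" in tensile_curve_metrics(t).invalid_reasons
        short = _simple_tensile(gauge=10.0)  # gauge/diameter < 30
        assert "span_ratio_below_minimum" in tensile_curve_metrics(short).invalid_reasons

    def test_curve_without_break_is_invalid(self):
        disp = np.linspace(0, 5, 20)[1:]
        curve = np.vstack([disp, 2.0 * disp]).T  # monotonically ascending
        t = TensileTest(root_id="r", species="sp", diameters=(1.0,) * 3,
                        gauge_length=100.0, curve=curve)
        res = tensile_curve_metrics(t)
        assert not res.valid and "no_break_detected" in res.invalid_reasons

    def test_modulus_matches_elastic_slope(self):
        # elastic phase spans 5%..75% of peak stress over strain 0.375%..1.5%
        t = _simple_tensile(peak_force=10.0, gauge=200.0)
        res = tensile_curve_metrics(t)
        csa = res.csa
        slope = ((0.75 - 0.05) * 10.0 / csa) / ((3.0 - 0.75) / 200.0)
        assert res.tensile_modulus == pytest.approx(slope, rel=1e-6)

    def test_rejects_malformed_curves(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TensileTest(root_id="r", species="s", diameters=(1,) * 3,
                        gauge_length=50, curve=np.array([[0, 0], [1, 2], [1, 3]]))
        with pytest.raises(ValueError, match="at least 3"):
            tensile_curve_metrics(
                TensileTest(root_id="r", species="s", diameters=(1,) * 3,
                            gauge_length=50, curve=np.array([[0.0, 0.0], [1.0, 1.0]]))
            )


class TestPowerLawFit:
    def test_noiseless_power_law_recovered_exactly(self):
        diam = np.geomspace(0.1, 2.0, 12)
        results = [
            tensile_curve_metrics(
                _simple_tensile(
                    peak_force=20.0 * d**-0.8 * math.pi * d * d / 4.0,
                    diameter=d, gauge=40.0 * d,
                )
            )
            for d in diam
        ]
        fit = fit_tmax_power_law(results)
        assert fit.alpha == pytest.approx(20.0, rel=1e-9)
        assert fit.beta == pytest.approx(0.8, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n == 12

    def test_invalid_results_never_enter_fit(self, taproot_archetype):
        cfg = synthetic.GeneratorConfig(seed=5, n_tensile=60, noise_cv=0.1,
                                        invalid_fraction=0.3)
        results = [
            tensile_curve_metrics(t)
            for t in synthetic.generate_tensile_tests(taproot_archetype, cfg)
        ]
        n_valid = sum(r.valid for r in results)
        assert 0 < n_valid < len(results)
        assert fit_tmax_power_law(results).n == n_valid

    def test_all_invalid_raises(self):
        t = _simple_tensile(gauge=200.0)
        t.failure_location = "clamp"
        bad = [tensile_curve_metrics(t)] * 4
        with pytest.raises(ValueError, match="valid results"):
            fit_tmax_power_law(bad)

    def test_positive_beta_predicts_decreasing_strength(self):
        diam = np.geomspace(0.1, 2.0, 10)
        results = [
            tensile_curve_metrics(
                _simple_tensile(peak_force=30.0 * d**-0.5 * math.pi * d * d / 4.0,
                                diameter=d, gauge=40.0 * d)
            )
            for d in diam
        ]
        fit = fit_tmax_power_law(results)
        assert fit.beta > 0
        pred = fit.predict(diam)
        assert np.all(np.diff(pred) < 0)

    def test_stochastic_parameter_recovery_single_seed(self, taproot_archetype):
        cfg = synthetic.GeneratorConfig(seed=42, n_tensile=200, noise_cv=0.2)
        results = [
            tensile_curve_metrics(t)
            for t in synthetic.generate_tensile_tests(taproot_archetype, cfg)
        ]
        fit = fit_tmax_power_law(results)
        assert fit.alpha == pytest.approx(taproot_archetype.tmax_alpha, rel=0.10)
        assert fit.beta == pytest.approx(taproot_archetype.tmax_beta, rel=0.10)


class TestSecondMoment:
    def test_circular_section_oracle_over_log_grid(self):
        for d in np.geomspace(0.1, 20.0, 25):
            assert second_moment_of_inertia(d, d) == pytest.approx(
                math.pi * d**4 / 64.0, rel=1e-14
            )

    def test_degenerate_and_scaling(self):
        assert second_moment_of_inertia(0.0, 3.0) == 0.0
        i1 = second_moment_of_inertia(1.7, 2.3)
        assert second_moment_of_inertia(3.4, 2.3) == pytest.approx(8 * i1)
        with pytest.raises(ValueError):
            second_moment_of_inertia(-1.0, 1.0)


class TestBendingMetrics:
    def test_noiseless_modulus_recovery(self, taproot_archetype, noiseless_config):
        tests = synthetic.generate_bending_tests(taproot_archetype, noiseless_config)
        for t in tests:
            res = bending_metrics(t)
            assert res.valid
            assert res.bending_modulus == pytest.approx(
                taproot_archetype.bending_modulus_mean, rel=1e-3
            )

    def test_rigidity_is_product_of_modulus_and_inertia(self, taproot_archetype):
        cfg = synthetic.GeneratorConfig(seed=8, n_bending=10, noise_cv=0.15)
        for t in synthetic.generate_bending_tests(taproot_archetype, cfg):
            res = bending_metrics(t)
            assert res.rigidity == pytest.approx(
                res.bending_modulus * res.second_moment / 1e3, rel=1e-12
            )

    def test_short_span_flagged_invalid(self):
        d = 4.0
        span = 15.0 * d  # below the 20x threshold
        k = 48.0 * 500.0 * second_moment_of_inertia(d, d) / span**3
        defl = np.linspace(0, 2, 15)[1:]
        t = BendingTest(root_id="b", species="sp", depth_diameter=d,
                        width_diameter=d, span=span,
                        curve=np.vstack([defl, k * defl]).T)
        res = bending_metrics(t)
        assert not res.valid and "span_ratio_below_minimum" in res.invalid_reasons

    def test_unresolvable_slope_flagged(self):
        d = 4.0
        defl = np.linspace(0, 2, 15)[1:]
        t = BendingTest(root_id="b", species="sp", depth_diameter=d,
                        width_diameter=d, span=100.0,
                        curve=np.vstack([defl, np.full(defl.size, 3.0)]).T)
        res = bending_metrics(t)
        assert not res.valid and "initial_slope_unresolvable" in res.invalid_reasons
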