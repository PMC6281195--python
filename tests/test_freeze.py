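"""EL50 estimation, curve comparison and acclimation decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cbfreg.freeze import (
    LeakageCurve,
    compare_curves,
    curves_from_dataframe,
    decompose_acclimation,
    fit_el50,
)
from cbfreg.simulate import logistic_leakage


def _curve(temps, leaks, genotype="g", acclimation="non_acclimated"):
    pts = tuple((float(t), float(v), 0.0, 3) for t, v in zip(temps, leaks))
    return LeakageCurve(genotype=genotype, acclimation=acclimation, points=pts)


def _logistic_curve(el50, slope=1.0, half_span=6.0, n=13):
    temps = np.linspace(el50 - half_span, el50 + half_span, n)
    return _curve(temps, logistic_leakage(temps, el50, slope))


class TestFitEL50:
    def test_linear_ramp_midpoint(self):
        # leakage rising linearly 0->100 over -20..0 degC: the cubic
        # collapses to the line and EL50 is the midpoint
        temps = np.linspace(-20, 0, 5)
        est = fit_el50(_curve(temps, np.linspace(100, 0, 5)))
        assert est.el50 == pytest.approx(-10.0, abs=1e-8)
        assert est.in_range

    def test_logistic_recovery(self):
        est = fit_el50(_logistic_curve(-8.0, slope=1.0))
        assert abs(est.el50 - (-8.0)) < 0.3

    def test_recovery_grid_monotone(self):
        grid = np.linspace(-14, -4, 11)
        fitted = [fit_el50(_logistic_curve(e)).el50 for e in grid]
        rho = stats.spearmanr(grid, fitted).statistic
        assert rho == 1.0

    def test_temperature_shift_equivariance(self):
        base = _logistic_curve(-8.0, slope=1.5)
        shift = 3.7
        temps = base.temperatures + shift
        shifted = _curve(temps, base.leakage)
        assert fit_el50(shifted).el50 == pytest.approx(
            fit_el50(base).el50 + shift, abs=1e-6)

    def test_prediction_at_el50_is_50(self):
        est = fit_el50(_logistic_curve(-9.5, slope=2.0))
        assert est.predict(est.el50) == pytest.approx(50.0, abs=1e-6)

    def test_constant_50_rejected(self):
        temps = np.linspace(-10, 0, 5)
        with pytest.raises(ValueError, match="50% crossing"):
            fit_el50(_curve(temps, np.full(5, 50.0)))

    def test_no_crossing_rejected(self):
        # leakage capped well below 50: no real crossing anywhere
        temps = np.linspace(-10, 0, 9)
        leaks = 40.0 - 0.1 * (temps + 5.0) ** 2
        with pytest.raises(ValueError, match="no 50% crossing"):
            fit_el50(_curve(temps, leaks))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            fit_el50(_curve([-10, -5, 0], [90, 50, 10]))

    def test_out_of_span_crossing_flagged(self):
        # EL50 below the tested span: fit extrapolates and flags it
        temps = np.linspace(-6, 0, 7)
        est = fit_el50(_curve(temps, logistic_leakage(temps, -8.0, 1.5)))
        assert not est.in_range


class TestDecomposition:
    def test_printed_el50_arithmetic_sw(self):
        d = decompose_acclimation(-5.1, -12.4, -4.5, -8.9)
        assert d.delta_wt == pytest.approx(7.3)
        assert d.delta_mut == pytest.approx(4.4)
        assert d.cbf_dependent == pytest.approx(2.9)
        assert d.fraction_rounded_5pct == pytest.approx(0.40)

    def test_printed_el50_arithmetic_it(self):
        d = decompose_acclimation(-4.7, -8.7, -3.8, -7.3)
        assert d.delta_wt == pytest.approx(4.0)
        assert d.delta_mut == pytest.approx(3.5)
        assert d.cbf_dependent == pytest.approx(0.5)

    def test_identity_when_mutant_equals_wt(self):
        d = decompose_acclimation(-5.0, -9.0, -5.0, -9.0)
        assert d.cbf_dependent == 0.0
        assert d.fraction_cbf_dependent == 0.0

    @pytest.mark.parametrize("vals", [
        (-5.1, -12.4, -4.5, -8.9),
        (-4.7, -8.7, -3.8, -7.3),
        (0.0, -1.0, 2.0, 5.0),
        (-3.0, -3.0 - 1e-9, -2.0, -2.5),
    ])
    def test_conservation(self, vals):
        d = decompose_acclimation(*vals)
        assert d.cbf_dependent + d.cbf_independent == pytest.approx(
            d.delta_wt, abs=0.0)

    def test_zero_shift_flags_fraction(self):
        d = decompose_acclimation(-5.0, -5.0, -4.0, -6.0)
        assert not d.fraction_defined
        assert np.isnan(d.fraction_cbf_dependent)

    def test_accepts_estimates(self, leakage):
        from cbfreg.freeze import fit_el50 as f
        ests = {(c.genotype, c.acclimation): f(c) for c in leakage.curves}
        d = decompose_acclimation(
            ests[("SW", "non_acclimated")], ests[("SW", "cold_acclimated")],
            ests[("sw_cbf123", "non_acclimated")],
            ests[("sw_cbf123", "cold_acclimated")])
        # generating EL50s give 7.3 vs 4.4; noisy fits land near that
        assert d.delta_wt == pytest.approx(7.3, abs=1.0)
        assert d.cbf_dependent > 0


def _two_group_data(rng, el50_a, el50_b, slope=1.5, noise=3.0, reps=3):
    temps = np.linspace(-11, -5, 7)
    rows = []
    for geno, el in (("a", el50_a), ("b", el50_b)):
        for rep in range(reps):
            leak = np.clip(
                logistic_leakage(temps, el, slope) + rng.normal(0, noise, 7),
                0, 100)
            rows += [(geno, "cold_acclimated", t, rep, v)
                     for t, v in zip(temps, leak)]
    return pd.DataFrame(rows, columns=[
        "genotype", "acclimation", "temperature_C", "replicate", "leakage_pct"])


class TestCompareCurves:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(11)
        temps = np.linspace(-11, -5, 7)
        base = logistic_leakage(temps, -8.0, 1.5)
        rows = []
        for geno in ("a", "b"):
            for rep in range(3):
                eps = rng.normal(0, 1e-6, 7)  # jitter only, no group effect
                rows += [(geno, "ca", t, rep, v)
                         for t, v in zip(temps, base + eps)]
        df = pd.DataFrame(rows, columns=[
            "genotype", "acclimation", "temperature_C", "replicate",
            "leakage_pct"])
        cmp_ = compare_curves(df)
        assert cmp_.p_value > 0.05
        assert cmp_.significance == "ns"

    def test_separated_el50s_detected(self):
        rng = np.random.default_rng(3)
        cmp_ = compare_curves(_two_group_data(rng, -8.0, -13.0))
        assert cmp_.p_value < 0.001
        assert cmp_.significance == "***"

    def test_single_replicate_rejected(self):
        rng = np.random.default_rng(4)
        df = _two_group_data(rng, -8.0, -8.0, reps=1)
        with pytest.raises(ValueError, match="replicates"):
            compare_curves(df)

    def test_requires_two_genotypes(self):
        rng = np.random.default_rng(5)
        df = _two_group_data(rng, -8.0, -8.0)
        with pytest.raises(ValueError, match="two genotypes"):
            compare_curves(df[df.genotype == "a"])


def test_curves_from_dataframe_groups_and_orders(leakage):
    curves = curves_from_dataframe(leakage.data)
    assert len(curves) == 8
    for c in curves:
        temps = c.temperatures
        assert (np.diff(temps) > 0).all()
        assert len(c.points) == 10
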