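"""AAF core: trapezoidal integration, closed-form oracles, HED decomposition."""

import numpy as np
import pytest
from scipy import integrate, stats

from aafengine.aaf import (
    compute_aaf,
    compute_aaf_for_cause,
    compute_aaf_hed,
    fully_attributable_aaf,
    make_grid,
    trapezoid,
    truncated_gamma_pdf,
)
from aafengine.synthetic import default_scenario

from conftest import constant_registry, make_exposure, make_fn


class TestTrapezoid:
    def test_zero_integrand_is_zero(self):
        x = make_grid()
        pdf = truncated_gamma_pdf(x, 2.0, 10.0, 150.0)
        assert trapezoid(x, pdf, np.zeros_like(x)) == 0.0

    def test_constant_integrand_recovers_constant(self):
        # a density proper with respect to the integration grid returns the
        # constant exactly (normalization identity of the rule itself)
        x = make_grid()
        pdf = truncated_gamma_pdf(x, 2.0, 10.0, 150.0)
        pdf = pdf / np.trapezoid(pdf, x)
        assert trapezoid(x, pdf, np.full_like(x, 3.0)) == pytest.approx(
            3.0, rel=1e-6)

    def test_density_normalizes_to_one(self):
        z, _ = integrate.quad(
            lambda v: truncated_gamma_pdf(np.array([v]), 2.0, 10.0, 150.0)[0],
            0, 150, limit=200)
        assert z == pytest.approx(1.0, abs=1e-6)

    def test_matches_adaptive_quadrature(self):
        x = make_grid()
        pdf = truncated_gamma_pdf(x, 2.0, 10.0, 150.0)
        f = np.exp(0.01 * x) - 1
        got = trapezoid(x, pdf, np.where(x > 0, f, 0.0))
        z = stats.gamma.cdf(150, 2.0, scale=10.0)
        want, _ = integrate.quad(
            lambda v: stats.gamma.pdf(v, 2.0, scale=10.0) / z
            * (np.exp(0.01 * v) - 1), 0, 150, limit=200)
        assert got == pytest.approx(want, rel=1e-6)

    def test_mismatched_grids_raise(self):
        x = make_grid()
        with pytest.raises(ValueError, match="shape"):
            trapezoid(x, np.ones_like(x), np.ones(3))

    def test_descending_grid_raises(self):
        with pytest.raises(ValueError, match="ascending"):
            trapezoid(np.array([1.0, 0.5]), np.ones(2), np.ones(2))


class TestClosedFormOracle:
    """Constant RR, no former drinkers: AAF = p(RR-1)/(p(RR-1)+1)."""

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.8])
    @pytest.mark.parametrize("rr", [0.8, 1.0, 1.5, 2.0, 4.0])
    def test_constant_rr_grid(self, p, rr):
        e = make_exposure(p_former=0.0, p_current=p)
        former = make_fn(group="former", form="constant", beta=(0.0,))
        current = make_fn(group="current", form="constant",
                          beta=(np.log(rr),))
        est = compute_aaf(e, former, current)
        expected = p * (rr - 1) / (p * (rr - 1) + 1)
        assert est.aaf == pytest.approx(expected, abs=1e-9)

    def test_unit_rr_gives_zero(self):
        e = make_exposure(p_former=0.2, p_current=0.5)
        unit = make_fn(group="former", form="constant", beta=(0.0,))
        current = make_fn(group="current", beta=(0.0,))
        assert compute_aaf(e, unit, current).aaf == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_protective_rr_gives_negative_aaf(self):
        e = make_exposure(p_former=0.0, p_current=0.5)
        former = make_fn(group="former", form="constant", beta=(0.0,))
        current = make_fn(group="current", form="constant",
                          beta=(np.log(0.8),))
        assert compute_aaf(e, former, current).aaf == pytest.approx(
            -1.0 / 9.0, abs=1e-9)

    def test_former_term_closed_form(self):
        e = make_exposure(p_former=0.2, p_current=0.0)
        former = make_fn(group="former", form="constant", beta=(np.log(1.5),))
        current = make_fn(group="current", beta=(0.0,))
        n = 0.2 * 0.5
        assert compute_aaf(e, former, current).aaf == pytest.approx(
            n / (n + 1), abs=1e-12)


class TestComponents:
    def test_breakdown_recombines_to_numerator(self):
        e = make_exposure(p_former=0.1, p_current=0.5, p_hed=0.4)
        former = make_fn(group="former", form="constant", beta=(0.18,))
        nh = make_fn(group="current_non_hed", beta=(0.006,))
        h = make_fn(group="current_hed", beta=(0.012,))
        est = compute_aaf_hed(e, former, nh, h)
        assert est.numerator == pytest.approx(
            est.aaf / (1 - est.aaf), rel=1e-10)

    def test_aaf_strictly_below_one_for_partial(self):
        e = make_exposure(p_former=0.3, p_current=0.7 - 1e-9)
        former = make_fn(group="former", form="constant", beta=(3.0,))
        current = make_fn(group="current", beta=(0.03,))
        assert compute_aaf(e, former, current).aaf < 1.0


class TestHEDDecomposition:
    def _exposures(self):
        scenario = default_scenario(seed=0)
        return [make_exposure(p_former=s.p_former, p_current=s.p_current,
                              shape=s.shape, scale=s.scale, p_hed=s.p_hed,
                              sex=s.sex, age_group=s.age_group)
                for s in scenario.strata]

    def test_identical_functions_collapse_to_unstratified(self):
        former = make_fn(group="former", form="constant", beta=(0.18,))
        for e in self._exposures():
            common = make_fn(group="current", form="log-quadratic",
                             beta=(0.008, 2e-5))
            nh = make_fn(group="current_non_hed", form="log-quadratic",
                         beta=(0.008, 2e-5))
            h = make_fn(group="current_hed", form="log-quadratic",
                        beta=(0.008, 2e-5))
            plain = compute_aaf(e, former, common).aaf
            hed = compute_aaf_hed(e, former, nh, h).aaf
            assert hed == pytest.approx(plain, abs=1e-10)

    def test_zero_hed_prevalence_uses_hed_curve_above_threshold(self):
        e = make_exposure(p_former=0.0, p_current=0.5, p_hed=0.0,
                          shape=1.5, scale=30.0)
        former = make_fn(group="former", form="constant", beta=(0.0,))
        nh = make_fn(group="current_non_hed", beta=(0.005,))
        h = make_fn(group="current_hed", beta=(0.015,))
        est = compute_aaf_hed(e, former, nh, h)
        # oracle: non-HED curve below 60 g, HED curve above
        z = stats.gamma.cdf(150, 1.5, scale=30.0)
        pdf = lambda v: stats.gamma.pdf(v, 1.5, scale=30.0) / z
        low, _ = integrate.quad(lambda v: pdf(v) * (np.exp(0.005 * v) - 1),
                                0, 60, limit=200)
        high, _ = integrate.quad(lambda v: pdf(v) * (np.exp(0.015 * v) - 1),
                                 60, 150, limit=200)
        n = 0.5 * (low + high)
        assert est.aaf == pytest.approx(n / (n + 1), rel=1e-6)

    def test_all_hed_constant_rr_matches_closed_form(self):
        e = make_exposure(p_former=0.0, p_current=0.5, p_hed=1.0)
        former = make_fn(group="former", form="constant", beta=(0.0,))
        nh = make_fn(group="current_non_hed", form="constant", beta=(0.0,))
        h = make_fn(group="current_hed", form="constant", beta=(np.log(2.0),))
        assert compute_aaf_hed(e, former, nh, h).aaf == pytest.approx(
            1.0 / 3.0, abs=1e-9)

    def test_threshold_must_lie_on_grid(self):
        e = make_exposure()
        former = make_fn(group="former", form="constant", beta=(0.0,))
        nh = make_fn(group="current_non_hed", beta=(0.005,))
        h = make_fn(group="current_hed", beta=(0.01,))
        with pytest.raises(ValueError, match="grid"):
            compute_aaf_hed(e, former, nh, h, grid_size=1000)


class TestFullyAttributable:
    def test_aaf_is_exactly_one(self, registry):
        est = fully_attributable_aaf("alcohol_use_disorders", registry)
        assert est.aaf == 1.0
        assert est.grid_size == 0

    def test_breakdown_components_zero(self, registry):
        est = fully_attributable_aaf("alcohol_use_disorders", registry)
        assert all(v == 0.0 for v in est.components.values())

    def test_partial_cause_raises(self, registry):
        with pytest.raises(ValueError, match="liver_cirrhosis"):
            fully_attributable_aaf("liver_cirrhosis", registry)


class TestNumericalProperties:
    def test_grid_refinement_converges(self, registry):
        scenario = default_scenario(seed=0)
        for s in scenario.strata:
            e = make_exposure(p_former=s.p_former, p_current=s.p_current,
                              shape=s.shape, scale=s.scale, p_hed=s.p_hed,
                              sex=s.sex, age_group=s.age_group)
            for cause in ("liver_cirrhosis", "ischemic_heart_disease"):
                coarse = compute_aaf_for_cause(e, cause, registry,
                                               grid_size=1501).aaf
                fine = compute_aaf_for_cause(e, cause, registry,
                                             grid_size=15001).aaf
                assert abs(coarse - fine) < 1e-5

    def test_pointwise_larger_rr_never_decreases_aaf(self):
        rng = np.random.default_rng(17)
        former = make_fn(group="former", form="constant", beta=(0.1,))
        for _ in range(20):
            b = rng.uniform(0.001, 0.02)
            extra = rng.uniform(0.0005, 0.01)
            e = make_exposure(p_former=0.1,
                              p_current=rng.uniform(0.2, 0.6),
                              shape=rng.uniform(1.2, 3.0),
                              scale=rng.uniform(8, 30))
            small = compute_aaf(e, former, make_fn(beta=(b,))).aaf
            large = compute_aaf(e, former, make_fn(beta=(b + extra,))).aaf
            assert large >= small

    def test_literal_integrand_switch_changes_result(self):
        e = make_exposure(p_former=0.1, p_current=0.5)
        former = make_fn(group="former", form="constant", beta=(0.18,))
        current = make_fn(group="current", beta=(0.01,))
        excess = compute_aaf(e, former, current, excess_risk=True).aaf
        literal = compute_aaf(e, former, current, excess_risk=False).aaf
        assert literal > excess  # RR instead of RR-1 inflates the numerator
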