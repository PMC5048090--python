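"""Closed-form equilibrium, characteristic polynomial, Routh-Hurwitz,
critical values, Hopf quantities."""

import math

import numpy as np
import pytest

from wcpair.experiments import baseline_config
from wcpair.linear import (
    MarginalStabilityError,
    SingularEquilibriumError,
    _closed_form_state,
    analysis_report,
    char_poly_coeffs,
    critical_values,
    eigenvalues,
    equilibrium,
    find_critical_beta,
    hopf_info,
    linear_summary,
    routh_hurwitz,
)
from wcpair.model import ActivationKind, rhs

from conftest import random_config


def _nonsingular_config(rng):
    while True:
        cfg = random_config(rng)
        try:
            equilibrium(cfg)
        except SingularEquilibriumError:  # pragma: no cover
            continue
        return cfg


class TestEquilibrium:
    def test_case_a_printed_value(self, case_a):
        eq = equilibrium(case_a)
        # isolated closed form (E I1 - b J1)/(bc - E W) = 20.02/120.0201
        assert eq.x1 == pytest.approx(20.02 / 120.0201, rel=1e-12)
        assert eq.x1 == pytest.approx(0.167, abs=1e-3)

    def test_case_c_printed_value(self, case_c):
        assert equilibrium(case_c).x1 == pytest.approx(0.175, abs=1e-3)

    def test_origin_without_stimuli(self, case_c):
        cfg = case_c.replace(I1=0, I2=0, J1=0, J2=0)
        assert np.allclose(equilibrium(cfg).state, 0.0, atol=1e-14)

    def test_symmetric_stimuli_give_symmetric_equilibrium(self):
        cfg = baseline_config(w=8, alpha1=1.5, alpha2=1.5, beta1=0.5,
                              beta2=0.5).replace(I1=2, I2=2, J1=0.3, J2=0.3)
        eq = equilibrium(cfg)
        assert eq.x1 == pytest.approx(eq.x2, rel=1e-12)
        assert eq.y1 == pytest.approx(eq.y2, rel=1e-12)

    def test_is_fixed_point_of_linear_rhs(self, rng):
        for _ in range(30):
            cfg = _nonsingular_config(rng)
            eq = equilibrium(cfg)
            assert np.allclose(rhs(eq.state, cfg, ActivationKind.LINEAR),
                               0.0, atol=1e-10)

    def test_closed_form_matches_affine_solve(self, rng):
        for _ in range(50):
            cfg = _nonsingular_config(rng)
            assert np.allclose(equilibrium(cfg).state,
                               _closed_form_state(cfg), atol=1e-10)

    def test_isolated_reduction(self, case_a):
        ls = linear_summary(case_a)
        s = case_a.stimulus
        p = case_a.population
        eq = equilibrium(case_a)
        den = p.b * p.c - ls.E * ls.W
        assert eq.x2 == pytest.approx((ls.E * s.I2 - p.b * s.J2) / den, rel=1e-12)
        assert eq.y1 == pytest.approx((p.c * s.I1 - ls.W * s.J1) / den, rel=1e-12)

    def test_singular_denominator_raises(self):
        # alpha chosen so M = E*alpha exactly: M^2 - P1 P2 = 0
        cfg = baseline_config(w=8, alpha1=120.0201 / 10.01,
                              alpha2=120.0201 / 10.01)
        with pytest.raises(SingularEquilibriumError):
            equilibrium(cfg)


class TestCharPoly:
    def test_case_c_printed_coefficients(self, case_c):
        g = char_poly_coeffs(case_c)
        assert g.gamma1 == pytest.approx(4.04, abs=1e-10)
        assert g.gamma2 == pytest.approx(243.12, abs=0.01)
        assert g.gamma3 == pytest.approx(464.86, abs=0.01)
        assert g.gamma4 == pytest.approx(14304.6, abs=0.1)

    def test_isolated_factors_as_squared_quadratic(self, case_a):
        g = char_poly_coeffs(case_a)
        ls = linear_summary(case_a)
        D, M = ls.E - ls.W, ls.M
        assert g.gamma1 == pytest.approx(2 * D, rel=1e-12)
        assert g.gamma2 == pytest.approx(D * D + 2 * M, rel=1e-12)
        assert g.gamma3 == pytest.approx(2 * D * M, rel=1e-12)
        assert g.gamma4 == pytest.approx(M * M, rel=1e-12)

    def test_matches_jacobian_characteristic_polynomial(self, rng):
        for _ in range(100):
            cfg = random_config(rng)
            lam = eigenvalues(cfg)
            numeric = np.real(np.poly(lam))  # monic coefficients
            analytic = char_poly_coeffs(cfg).as_poly()
            scale = np.maximum(np.abs(analytic), 1.0)
            assert np.all(np.abs(numeric - analytic) / scale < 1e-8)

    def test_trace_and_det_identities(self, rng):
        from wcpair.model import jacobian
        for _ in range(50):
            cfg = random_config(rng)
            J = jacobian(np.zeros(4), cfg, ActivationKind.LINEAR)
            g = char_poly_coeffs(cfg)
            assert g.gamma1 == pytest.approx(-np.trace(J), rel=1e-8)
            assert g.gamma4 == pytest.approx(np.linalg.det(J), rel=1e-8)

    def test_stimuli_do_not_affect_stability(self, rng):
        cfg = random_config(rng)
        shifted = cfg.replace(I1=5.0, I2=-3.0, J1=2.2, J2=-1.1)
        assert char_poly_coeffs(cfg) == char_poly_coeffs(shifted)

    def test_monotonic_destabilization(self, rng):
        h = 1e-6
        for _ in range(30):
            cfg = random_config(rng).replace(alpha1=0.0, alpha2=0.0)
            cfg = cfg.replace(beta1=max(cfg.coupling.beta1, 0.1),
                              beta2=max(cfg.coupling.beta2, 0.1))
            for which in ("beta1", "beta2"):
                lo = char_poly_coeffs(cfg).gamma4
                hi = char_poly_coeffs(
                    cfg.replace(**{which: getattr(cfg.coupling, which) + h})
                ).gamma4
                assert hi < lo
        for _ in range(30):
            cfg = random_config(rng).replace(beta1=0.0, beta2=0.0)
            cfg = cfg.replace(alpha1=max(cfg.coupling.alpha1, 0.1),
                              alpha2=max(cfg.coupling.alpha2, 0.1))
            for which in ("alpha1", "alpha2"):
                g_lo = char_poly_coeffs(cfg)
                g_hi = char_poly_coeffs(
                    cfg.replace(**{which: getattr(cfg.coupling, which) + h}))
                assert g_hi.gamma2 <= g_lo.gamma2
                assert g_hi.gamma3 <= g_lo.gamma3
                assert g_hi.gamma4 <= g_lo.gamma4


class TestRouthHurwitz:
    def test_case_c_printed_table(self, case_c):
        rh = routh_hurwitz(char_poly_coeffs(case_c))
        assert rh.delta1 == pytest.approx(128, abs=0.5)
        assert rh.delta2 == pytest.approx(13.6, abs=0.1)
        assert rh.stable and all(rh.conditions) and not rh.marginal

    def test_isolated_stability_reduces_to_two_inequalities(self, rng):
        for _ in range(40):
            cfg = random_config(rng).replace(alpha1=0, alpha2=0,
                                             beta1=0, beta2=0)
            ls = linear_summary(cfg)
            expected = ls.E > ls.W and cfg.population.b * cfg.population.c > ls.E * ls.W
            rh = routh_hurwitz(char_poly_coeffs(cfg))
            if not rh.marginal:
                assert rh.stable == expected

    def test_verdict_agrees_with_eigenvalue_signs(self, rng):
        checked = 0
        while checked < 200:
            cfg = random_config(rng)
            lam = eigenvalues(cfg)
            max_re = lam.real.max()
            if abs(max_re) < 1e-6:
                continue
            try:
                rh = routh_hurwitz(char_poly_coeffs(cfg))
            except MarginalStabilityError:  # pragma: no cover
                continue
            if rh.marginal:
                continue
            assert rh.stable == (max_re < 0)
            checked += 1

    def test_degenerate_table_raises(self):
        from wcpair.linear import CharPolyCoeffs
        with pytest.raises(MarginalStabilityError):
            routh_hurwitz(CharPolyCoeffs(0.0, 1.0, 1.0, 1.0))


class TestEigenvalues:
    def test_case_a_quadratic_roots_doubled(self, case_a):
        # isolated: lambda^2 + 2.02 lambda + 120.0201, each root twice
        lam = eigenvalues(case_a)
        roots = np.roots([1, 2.02, 120.0201])
        assert np.allclose(sorted(lam.real), sorted([r.real for r in roots] * 2),
                           atol=1e-9)
        assert lam.real.max() == pytest.approx(-1.01, abs=1e-9)

    def test_sorted_by_descending_real_part(self, rng):
        for _ in range(20):
            lam = eigenvalues(random_config(rng))
            assert np.all(np.diff(lam.real) <= 1e-12)

    def test_near_imaginary_pair_at_critical_beta(self):
        cfg = baseline_config(w=8, alpha1=1, alpha2=1)
        beta_c = find_critical_beta(cfg, "beta2", (0, 5))
        lam = eigenvalues(cfg.replace(beta2=beta_c))
        assert abs(lam[0].real) < 1e-4
        assert abs(lam[0].imag) > 1.0


class TestCriticalValues:
    def test_printed_thresholds(self, case_a):
        cv = critical_values(case_a)
        assert cv.w_c == pytest.approx(10.02, abs=1e-12)
        assert cv.alpha_c == pytest.approx(2.02, abs=1e-12)
        assert cv.e_c == pytest.approx(8 - 0.02, abs=1e-12)

    def test_w_c_and_e_c_restate_same_inequality(self, rng):
        for _ in range(20):
            cfg = random_config(rng)
            cv = critical_values(cfg)
            assert (cfg.population.w < cv.w_c) == (cfg.population.e > cv.e_c)


class TestHopf:
    def test_period_at_symmetric_threshold(self):
        cfg = baseline_config(w=8, alpha1=2.02, alpha2=2.02)
        h = hopf_info(cfg)
        assert h.epsilon1 == pytest.approx(0.0, abs=1e-12)
        assert h.epsilon2 == pytest.approx(99.8, abs=0.01)
        assert h.period == pytest.approx(0.63, abs=0.01)

    def test_epsilon1_vanishes_exactly_at_alpha_c(self, case_a):
        alpha_c = critical_values(case_a).alpha_c
        h = hopf_info(case_a.replace(alpha1=alpha_c, alpha2=alpha_c))
        assert h.epsilon1 == pytest.approx(0.0, abs=1e-12)

    def test_delta2_vanishes_at_epsilon1_zero(self, rng):
        # algebraic equivalence of the two Hopf conditions, symmetric case
        for _ in range(20):
            cfg = random_config(rng)
            p = cfg.population
            alpha = p.a + p.d + p.e - p.w  # makes epsilon1 = 0
            if alpha < 0:
                continue
            beta = cfg.coupling.beta1
            sym = cfg.replace(alpha1=alpha, alpha2=alpha,
                              beta1=beta, beta2=beta)
            assert hopf_info(sym).epsilon1 == pytest.approx(0, abs=1e-10)
            rh = routh_hurwitz(char_poly_coeffs(sym))
            scale = max(1.0, abs(rh.delta1))
            assert abs(rh.delta2) / scale < 1e-6

    def test_negative_epsilon2_gives_no_period(self):
        cfg = baseline_config(w=8, alpha1=2.02, alpha2=2.02).replace(
            b=0.1, c=0.1)
        assert hopf_info(cfg).period is None

    def test_asymmetric_coupling_rejected(self):
        with pytest.raises(ValueError):
            hopf_info(baseline_config(w=8, alpha1=1, alpha2=2))


class TestCriticalBeta:
    def test_printed_beta_c(self):
        cfg = baseline_config(w=8, alpha1=1, alpha2=1)
        assert find_critical_beta(cfg, "beta2", (0, 5)) == pytest.approx(
            2.25, abs=0.01)

    def test_root_at_zero_when_alpha_at_threshold(self):
        cfg = baseline_config(w=8, alpha1=2.02, alpha2=2.02)
        assert find_critical_beta(cfg, "beta2", (0.0, 0.5)) == pytest.approx(
            0.0, abs=1e-6)

    def test_matches_symbolic_quadratic_root(self):
        # with beta1 = 0, clearing delta1 from delta1*g3 - g1*g4 = 0 gives
        # g1 g2 g3 - g3^2 - g1^2 g4 = 0, a quadratic in beta2
        cfg = baseline_config(w=8, alpha1=1, alpha2=1)
        numeric = find_critical_beta(cfg, "beta2", (0, 5))

        def resid(beta2):
            g = char_poly_coeffs(cfg.replace(beta2=float(beta2)))
            return (g.gamma1 * g.gamma2 * g.gamma3 - g.gamma3 ** 2
                    - g.gamma1 ** 2 * g.gamma4)

        # quadratic coefficients by exact interpolation at 3 points
        r0, r1, r2 = resid(0.0), resid(1.0), resid(2.0)
        c2 = (r2 - 2 * r1 + r0) / 2
        c1 = r1 - r0 - c2
        roots = np.roots([c2, c1, r0])
        positive = min(r for r in roots.real if r > 0)
        assert numeric == pytest.approx(positive, abs=1e-6)

    def test_no_sign_change_reports_endpoint_values(self):
        cfg = baseline_config(w=8, alpha1=1, alpha2=1)
        with pytest.raises(ValueError, match="delta2"):
            find_critical_beta(cfg, "beta2", (0, 1))


def test_analysis_report_is_json_serializable(case_c):
    import json
    report = analysis_report(case_c)
    text = json.dumps(report)
    assert "14304" in text  # gamma4 present
    assert report["stable"] is True
    assert report["hopf"]["epsilon1"] is not None
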