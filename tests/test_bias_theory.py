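"""Moment-based ascertainment-bias estimator and sign predictions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casebias._fast import ols_slope
from casebias.bias import (conditional_mean, delta_approx, delta_exact,
                           delta_from_sample, predict_sign_pattern,
                           standardize)
from casebias.models import CausalModelSpec, simulate_population


def _random_sample(rng, n=4_000):
    b = rng.standard_normal(n)
    g = rng.binomial(2, 0.3, n).astype(float)
    d = rng.binomial(1, 0.35, n)
    if d.sum() in (0, n):
        d[:2] = [0, 1]
    return b, g, d


class TestStandardize:
    def test_idempotent_on_standardized_input(self, rng):
        b, g, d = _random_sample(rng)
        B, G, D, _ = standardize(b, g, d)
        B2, G2, D2, _ = standardize(B, G, np.asarray(d, float))
        assert np.allclose(B, B2, atol=1e-12)
        assert np.allclose(G, G2, atol=1e-12)

    def test_constant_vector_names_offender(self):
        with pytest.raises(ValueError, match="d"):
            standardize([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], [1.0, 1.0, 1.0])

    def test_independent_disease_moments_vanish(self, rng):
        n = 1_000_000
        b = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, n).astype(float)
        d = rng.binomial(1, 0.3, n)  # independent of b, g
        _, _, _, m = standardize(b, g, d)
        bound = 5.0 / np.sqrt(n)
        for value in (m.e_bd, m.e_gd, m.e_bgd, m.e_g2d):
            assert abs(value) < bound


class TestConditionalMomentIdentity:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_identity_is_algebraic(self, seed):
        """E[X|d=1] = E[X] + (sigma_d/mu_d) E[XD] exactly on finite samples."""
        rng = np.random.default_rng(seed)
        b, g, d = _random_sample(rng, n=500)
        B, G, D, m = standardize(b, g, d)
        mask = d == 1
        for X in (B, G, B * G, G * G, B * B * G):
            lhs = X[mask].mean()
            rhs = conditional_mean(X.mean(), (X * D).mean(), m.mu_d)
            assert abs(lhs - rhs) < 1e-10


class TestDeltaExact:
    def test_zero_when_disease_independent(self):
        from casebias.bias import MomentSet
        m = MomentSet(e_bg=0.25, e_bd=0.0, e_gd=0.0, e_bgd=0.0, e_g2d=0.0,
                      mu_d=0.3)
        est = delta_exact(m)
        assert est.delta == pytest.approx(0.0, abs=1e-14)

    def test_equals_two_regression_difference(self):
        """Moment route == brute-force case-minus-population OLS difference."""
        spec = CausalModelSpec("c", omega_g=0.4, omega_b=-0.4, prevalence=0.3)
        s = simulate_population(spec, 200_000, seed_or_rng=11)
        B, G, D, m = standardize(s.b, s.g, s.d)
        est = delta_exact(m)
        mask = s.d == 1
        brute = ols_slope(G[mask], B[mask]) - ols_slope(G, B)
        assert est.delta == pytest.approx(brute, abs=1e-10)
        assert est.delta > 0  # sign(Delta_c) = -sign(omega_g * omega_b)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        b, g, d = _random_sample(rng, n=2_000)
        est = delta_exact(standardize(b, g, d)[3])
        brute = delta_from_sample(b, g, d)
        assert est.delta == pytest.approx(brute.delta, abs=1e-10)

    def test_degenerate_conditional_variance_rejected(self):
        from casebias.bias import MomentSet
        m = MomentSet(e_bg=0.0, e_bd=0.0, e_gd=0.9, e_bgd=0.0, e_g2d=-0.4,
                      mu_d=0.5)
        with pytest.raises(ValueError):
            delta_exact(m)


class TestDeltaApprox:
    def test_model_b_is_exactly_zero(self):
        spec = CausalModelSpec("b", beta=-0.2, omega_g=0.3)
        assert delta_approx(spec).delta == 0.0

    def test_model_a_sign_flips_beta(self):
        spec = CausalModelSpec("a", beta=-0.3, omega_b=-0.5)
        assert delta_approx(spec).delta > 0
        spec = CausalModelSpec("a", beta=0.3, omega_b=-0.5)
        assert delta_approx(spec).delta < 0

    @pytest.mark.parametrize("spec", [
        CausalModelSpec("a", beta=-0.3, omega_b=-0.5, prevalence=0.3),
        CausalModelSpec("c", omega_g=0.4, omega_b=-0.4, prevalence=0.3),
        CausalModelSpec("d", gamma=-0.3, omega_g=0.4, prevalence=0.3),
    ])
    def test_sign_and_magnitude_against_exact(self, spec):
        """The approximation's contract: correct sign, sane magnitude.

        The closed forms assume a common disease with small effects and
        near-normal variables; with a binomial genotype the constant is off,
        so the check is sign agreement plus order of magnitude, not a tight
        relative error.
        """
        s = simulate_population(spec, 400_000, seed_or_rng=21)
        exact = delta_exact(standardize(s.b, s.g, s.d)[3]).delta
        approx = delta_approx(spec).delta
        assert np.sign(approx) == np.sign(exact)
        assert 0.1 < abs(approx / exact) < 10.0

    def test_rare_disease_attenuates_bias(self):
        """Case-only bias under independent risk factors shrinks as the
        disease becomes rare (the rare-disease-limit factorization)."""
        common = CausalModelSpec("c", omega_g=0.4, omega_b=-0.4, prevalence=0.3)
        rare = CausalModelSpec("c", omega_g=0.4, omega_b=-0.4, prevalence=0.01)
        d_common = delta_exact(standardize(
            *(lambda s: (s.b, s.g, s.d))(
                simulate_population(common, 2_000_000, seed_or_rng=31)))[3]).delta
        d_rare = delta_exact(standardize(
            *(lambda s: (s.b, s.g, s.d))(
                simulate_population(rare, 2_000_000, seed_or_rng=32)))[3]).delta
        assert abs(d_rare) < abs(d_common)


class TestSignPattern:
    def test_canonical_table(self):
        """Full expected-sign table for the canonical effect directions."""
        expected = {
            "a": ("-", "-", "+", "+"),
            "b": ("-", "-", "0", "+"),
            "c": ("0", "+", "+", "-"),
            "d": ("-", "0", "+", "0"),
        }
        for model, (pop, case, delta, panel) in expected.items():
            p = predict_sign_pattern(model)
            assert (p.population, p.case_only, p.delta, p.panel_corr) == \
                (pop, case, delta, panel)

    def test_model_c_follows_omega_product(self):
        p = predict_sign_pattern("c", omega_g=1.0, omega_b=1.0)
        assert p.case_only == "-"
        p = predict_sign_pattern("c", omega_g=-1.0, omega_b=1.0)
        assert p.case_only == "+"

    def test_contradictory_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_sign_pattern("a", beta=0.0)
        with pytest.raises(ValueError):
            predict_sign_pattern("e")
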