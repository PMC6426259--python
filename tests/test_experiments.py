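"""Simulation experiments: replicate grids, sparsity, heterogeneity,
severity, panels, polynomial approximation."""

import numpy as np
import pytest

from casebias.experiments import (fit_polynomial_logit_approx,
                                  run_bias_experiment,
                                  run_heterogeneity_experiment,
                                  run_panel_experiment,
                                  run_severity_experiment,
                                  run_sparsity_experiment,
                                  sparsity_bin_summary)
from casebias.models import CausalModelSpec


class TestBiasExperiment:
    def test_delta_identity_per_replicate(self):
        spec = CausalModelSpec("a", beta=-0.3, omega_b=-0.5, prevalence=0.3)
        df = run_bias_experiment([spec], reps=5, n=5_000, seed=1)
        assert len(df) == 5
        assert np.allclose(df["delta"], df["beta_case"] - df["beta_pop"])

    def test_attenuation_sign_under_mediation(self):
        """Model a with beta < 0: case-only slope biased toward the null."""
        spec = CausalModelSpec("a", beta=-0.3, omega_b=-0.7, prevalence=0.3)
        df = run_bias_experiment([spec], reps=60, n=10_000, seed=2)
        assert df["delta"].median() > 0
        assert (df["delta"] > 0).mean() > 0.7

    def test_pleiotropy_unbiased(self):
        spec = CausalModelSpec("b", beta=-0.3, omega_g=0.5, prevalence=0.3)
        df = run_bias_experiment([spec], reps=60, n=10_000, seed=3)
        se = df["delta"].std(ddof=1) / np.sqrt(len(df))
        assert abs(df["delta"].mean()) < 3.5 * se

    def test_error_distributions_share_delta_sign(self):
        specs = [CausalModelSpec("c", omega_g=0.5, omega_b=-0.5,
                                 prevalence=0.3, error_dist=dist)
                 for dist in ("normal", "exponential", "uniform")]
        df = run_bias_experiment(specs, reps=40, n=10_000, seed=4)
        medians = df.groupby("error_dist")["delta"].median()
        assert (medians > 0).all()


class TestSparsityExperiment:
    def test_smoke_run_deterministic(self):
        a = run_sparsity_experiment("a", reps=10, n=2_000, n_cases=100, seed=5)
        b = run_sparsity_experiment("a", reps=10, n=2_000, n_cases=100, seed=5)
        assert a.equals(b)
        assert {"zero_frac", "signed_r2_raw", "signed_r2_int"} <= set(a.columns)

    def test_effect_attenuates_with_sparsity(self):
        df = run_sparsity_experiment("b", reps=300, seed=6)
        s = sparsity_bin_summary(df, 3)
        med = s["med_signed_r2_int"].abs().to_numpy()
        assert med[0] > med[-1]

    def test_raw_and_int_agree_in_sign(self):
        df = run_sparsity_experiment("a", reps=300, seed=7)
        s = sparsity_bin_summary(df, 3)
        assert (np.sign(s["med_signed_r2_raw"])
                == np.sign(s["med_signed_r2_int"])).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            run_sparsity_experiment("x", reps=2, n=500, n_cases=50, seed=0)


class TestHeterogeneityExperiment:
    def test_true_effect_visible_in_every_stratum(self):
        """Model a's G->B link is a population property, so the independently
        drawn UC stratum shows it just like the CD stratum does."""
        df = run_heterogeneity_experiment("a", reps=150, seed=8)
        for stratum in ("IBD", "CD", "UC"):
            assert df[f"beta_{stratum}"].median() < 0

    def test_null_models_calibrated_in_all_strata(self):
        """Models c and d: rare disease keeps the case-only bias negligible,
        so rejection stays near the nominal level in every stratum."""
        for model, seed in (("c", 9), ("d", 10)):
            df = run_heterogeneity_experiment(model, reps=150, seed=seed)
            for stratum in ("IBD", "CD", "UC"):
                rej = (df[f"p_{stratum}"].dropna() < 0.05).mean()
                assert rej < 0.12


class TestSeverityExperiment:
    def test_reverse_causation_removed_by_adjustment(self):
        """Model d: severity carries the G->B path; adjusting removes it."""
        df = run_severity_experiment("d", reps=40, n=10_000, seed=10)
        assert (df["p_unadj"] < 0.05).mean() > 0.9
        assert abs(df["corr_adj"].mean()) < 0.05

    def test_mediation_persists_after_adjustment(self):
        df = run_severity_experiment("a", reps=20, n=10_000, seed=11)
        assert df["corr_unadj"].mean() < -0.1
        assert df["corr_adj"].mean() < -0.1


class TestPanelExperiment:
    def test_mediation_panels_concordant(self):
        res = run_panel_experiment(30, "a", reps=6, seed=12, n_pop=3_000)
        assert np.nanmean(res.correlations) > 0.3

    def test_independent_risk_panels_anticorrelated(self):
        res = run_panel_experiment(50, "c", reps=8, seed=13, n_pop=3_000)
        assert np.nanmean(res.correlations) < 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            run_panel_experiment(1, "a", reps=1, seed=0)


class TestPolynomialApproximation:
    @staticmethod
    def _surface(prevalence, omega_b, omega_g, n=20_000, seed=14, dist="normal"):
        rng = np.random.default_rng(seed)
        G = rng.binomial(2, 0.1, n).astype(float)
        G = (G - G.mean()) / G.std()
        B = rng.standard_normal(n) if dist == "normal" else \
            rng.exponential(1.0, n) - 1.0
        from scipy import optimize
        base = np.log(prevalence / (1 - prevalence))
        eta = omega_b * B + omega_g * G
        w0 = optimize.brentq(
            lambda w: np.mean(1 / (1 + np.exp(-(w + eta)))) - prevalence,
            base - 12, base + 12)
        p = 1 / (1 + np.exp(-(w0 + eta)))
        return B, G, p

    def test_nested_fit_quality_non_decreasing(self):
        B, G, p = self._surface(0.1, -0.8, 0.8)
        res = fit_polynomial_logit_approx(B, G, p)
        assert all(b >= a - 1e-12 for a, b in zip(res.r2, res.r2[1:]))

    def test_balanced_modest_case_needs_only_marginal_terms(self):
        B, G, p = self._surface(0.5, -0.3, 0.3)
        res = fit_polynomial_logit_approx(B, G, p)
        assert res.r2[-1] - res.r2[0] < 0.01

    def test_rare_large_case_needs_higher_orders(self):
        B, G, p = self._surface(0.02, -1.5, 1.5, dist="exponential")
        res = fit_polynomial_logit_approx(B, G, p)
        assert res.r2[-1] - res.r2[0] > 0.03

    def test_order_one_is_marginal_model(self):
        B, G, p = self._surface(0.3, -0.5, 0.5, n=2_000)
        res = fit_polynomial_logit_approx(B, G, p, max_order=1)
        assert set(res.coefs[0]) == {"const", "B^0*G^1", "B^1*G^0"}
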