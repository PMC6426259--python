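"""Moment-based theory of the case-only ascertainment bias Delta.

When a secondary trait B (a bacterial level) is regressed on a genotype G in a
sample ascertained on disease status (cases only), the regression coefficient
differs from its population value by

    Delta = beta_{d=1} - beta.

With B, G, D the population-standardized variables (divide-by-n convention)
and mu_d the disease prevalence, every conditional moment reduces to an
unconditional one through the algebraic identity

    E[X | d=1] = E[X] + (sigma_d / mu_d) * E[X D],       sigma_d^2 = mu_d(1-mu_d),

which holds exactly on any finite sample.  Substituting gives a closed form
for Delta in terms of five mixed moments — valid for *any* generating model
and data distribution:

    var(G | d=1) = 1 + E[G^2 D] r - (E[G D] r)^2,        r = sigma_d / mu_d
    Delta = (E[BGD] r - E[GD] E[BD] r^2) / var(G|d=1)
            + E[BG] (1 - var(G|d=1)) / var(G|d=1)

Under a logistic disease model with a common disease, small effects and
near-normal B and G, Delta further reduces per causal model to the
closed-form approximations in :func:`delta_approx`; outside that regime only
their sign is guaranteed, which is what the counterfactual model ranking
uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._fast import ols_slope, standardize_pop
from .models import CausalModelSpec


@dataclass(frozen=True)
class MomentSet:
    """Mixed moments of the standardized triplet (B, G, D) plus prevalence."""

    e_bg: float
    e_bd: float
    e_gd: float
    e_bgd: float
    e_g2d: float
    mu_d: float

    @property
    def sigma_d(self) -> float:
        return float(np.sqrt(self.mu_d * (1.0 - self.mu_d)))

    @property
    def ratio(self) -> float:
        """sigma_d / mu_d, the factor of the conditional-moment identity."""
        return self.sigma_d / self.mu_d


@dataclass(frozen=True)
class BiasEstimate:
    """One evaluation of the ascertainment bias."""

    delta: float
    var_g_case: float
    beta_pop: Optional[float] = None
    beta_case: Optional[float] = None
    predicted_sign: Optional[int] = None
    approximation: bool = False


def standardize(b, g, d) -> tuple[np.ndarray, np.ndarray, np.ndarray, MomentSet]:
    """Standardize raw (b, g, d) and compute the mixed moments.

    All three vectors must have positive variance and equal length; the
    population-variance convention keeps the conditional-moment identity exact
    on finite samples.
    """
    b = np.asarray(b, dtype=float)
    g = np.asarray(g, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (b.shape == g.shape == d.shape):
        raise ValueError("b, g, d must have equal length")
    if not set(np.unique(d)) <= {0.0, 1.0}:
        raise ValueError("d must be binary 0/1")
    B = standardize_pop(b, "b")
    G = standardize_pop(g, "g")
    D = standardize_pop(d, "d")
    moments = MomentSet(
        e_bg=float(np.mean(B * G)),
        e_bd=float(np.mean(B * D)),
        e_gd=float(np.mean(G * D)),
        e_bgd=float(np.mean(B * G * D)),
        e_g2d=float(np.mean(G * G * D)),
        mu_d=float(d.mean()),
    )
    return B, G, D, moments


def conditional_mean(x_mean: float, xd_mean: float, mu_d: float) -> float:
    """E[X | d=1] from unconditional moments: E[X] + (sigma_d/mu_d) E[XD]."""
    sigma_d = np.sqrt(mu_d * (1.0 - mu_d))
    return x_mean + (sigma_d / mu_d) * xd_mean


def delta_exact(moments: MomentSet) -> BiasEstimate:
    """Exact ascertainment bias from the mixed moments.

    Model-free: when the moments are the empirical moments of one finite
    sample, the returned Delta equals the difference of the two OLS slopes
    (cases-only minus whole-population, both on the population-standardized
    variables) computed on that same sample, up to floating-point error.
    """
    r = moments.ratio
    var_g_case = 1.0 + moments.e_g2d * r - (moments.e_gd * r) ** 2
    if var_g_case <= 0.0:
        raise ValueError("conditional variance of G among cases is not positive")
    beta_pop = moments.e_bg
    delta = ((moments.e_bgd * r - moments.e_gd * moments.e_bd * r * r) / var_g_case
             + moments.e_bg * (1.0 - var_g_case) / var_g_case)
    return BiasEstimate(delta=float(delta), var_g_case=float(var_g_case),
                        beta_pop=float(beta_pop),
                        beta_case=float(beta_pop + delta),
                        predicted_sign=int(np.sign(delta)))


def delta_from_sample(b, g, d) -> BiasEstimate:
    """Convenience wrapper: standardize a raw sample and apply delta_exact.

    Also returns the brute-force two-regression difference for auditing; the
    two routes agree to floating point by construction.
    """
    B, G, D, moments = standardize(b, g, d)
    est = delta_exact(moments)
    mask = np.asarray(d) == 1
    beta_case = ols_slope(G[mask], B[mask])
    beta_pop = ols_slope(G, B)
    return BiasEstimate(delta=float(beta_case - beta_pop),
                        var_g_case=est.var_g_case,
                        beta_pop=float(beta_pop), beta_case=float(beta_case),
                        predicted_sign=int(np.sign(beta_case - beta_pop)))


def delta_approx(spec: CausalModelSpec, var_g_case: float = 1.0) -> BiasEstimate:
    """Closed-form approximation of Delta for one causal model.

    Valid regime: common disease, small effects, near-normal B and G.  Outside
    it only the sign is contractually guaranteed:

        sign(Delta_a) = -sign(beta)
        Delta_b       =  0
        sign(Delta_c) = -sign(omega_g * omega_b)
        sign(Delta_d) = -sign(gamma * omega_g)
    """
    mu = spec.prevalence
    sigma_d = np.sqrt(mu * (1.0 - mu))
    if spec.model_id == "a":
        num = -spec.beta * spec.omega_b ** 2 * (1.0 - mu) ** 2
        delta = num / ((1.0 - spec.beta ** 2) * var_g_case)
        sign = -np.sign(spec.beta)
    elif spec.model_id == "b":
        delta = 0.0
        sign = 0
    elif spec.model_id == "c":
        delta = -spec.omega_g * spec.omega_b * (1.0 - mu) ** 2 / var_g_case
        sign = -np.sign(spec.omega_g * spec.omega_b)
    else:  # model d: beta_case ~ 0, so Delta = -beta_pop = -E[BG]
        delta = -spec.gamma * spec.omega_g * sigma_d
        sign = -np.sign(spec.gamma * spec.omega_g)
    return BiasEstimate(delta=float(delta), var_g_case=float(var_g_case),
                        predicted_sign=int(sign), approximation=True)


# ---------------------------------------------------------------------------
# qualitative sign predictions per causal model

#: entries are "-", "0", "+" or "pop" (same as the population association)
SIGN_KEYS = ("population", "case_only", "delta", "panel_corr")


@dataclass(frozen=True)
class SignPattern:
    """Expected association signs for one causal model.

    ``population``: G-B association in the whole population;
    ``case_only``: G-B association among cases;
    ``delta``: the ascertainment bias;
    ``panel_corr``: correlation, across a panel of taxa, between the case-only
    SNP-bacterium estimate and the case-control bacterium-disease estimate.
    """

    model_id: str
    population: str
    case_only: str
    delta: str
    panel_corr: str

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in SIGN_KEYS}


def _sgn(x: float) -> int:
    return (x > 0) - (x < 0)


def _fmt(s: int) -> str:
    return {1: "+", 0: "0", -1: "-"}[s]


def predict_sign_pattern(model_id: str, beta: float = -1.0, gamma: float = -1.0,
                         omega_b: float = -1.0, omega_g: float = 1.0) -> SignPattern:
    """Expected-sign table for one causal model given the effect directions.

    Defaults encode the canonical configuration of the study: a risk allele
    (positive effect on disease), a protective bacterium (negative effect on
    or association with disease).
    """
    if model_id not in ("a", "b", "c", "d"):
        raise ValueError(f"unknown model id {model_id!r}")
    if model_id == "a":
        if beta == 0 or omega_b == 0:
            raise ValueError("model a requires nonzero beta and omega_b")
        s = _sgn(beta)
        return SignPattern("a", population=_fmt(s), case_only=_fmt(s),
                           delta=_fmt(-s), panel_corr="+")
    if model_id == "b":
        if beta == 0 or omega_g == 0:
            raise ValueError("model b requires nonzero beta and omega_g")
        s = _sgn(beta)
        return SignPattern("b", population=_fmt(s), case_only=_fmt(s),
                           delta="0", panel_corr="+")
    if model_id == "c":
        if omega_b == 0 or omega_g == 0:
            raise ValueError("model c requires nonzero omega_b and omega_g")
        s = -_sgn(omega_g * omega_b)
        return SignPattern("c", population="0", case_only=_fmt(s),
                           delta=_fmt(s), panel_corr="-")
    if gamma == 0 or omega_g == 0:
        raise ValueError("model d requires nonzero gamma and omega_g")
    s = _sgn(gamma * omega_g)
    return SignPattern("d", population=_fmt(s), case_only="0",
                       delta=_fmt(-s), panel_corr="0")
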