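"""Generative causal models linking a genetic variant, a bacterial level and disease.

Four parsimonious models are supported for the triplet (g, b, d):

* **a (mediation)** — the variant shifts the bacterial level, which shifts
  disease risk: ``B = beta*G + eps`` and ``logit P(d) = w0 + wB*B``.
* **b (pleiotropy)** — the variant shifts both independently:
  ``B = beta*G + eps`` and ``logit P(d) = w0 + wG*G``.
* **c (independent risk factors)** — bacterium and variant are unassociated in
  the population but both affect disease:
  ``logit P(d) = w0 + wB*B + wG*G``.
* **d (reverse causation)** — disease, caused by the variant, shifts the
  bacterial level: ``logit P(d) = w0 + wG*G`` then ``B = gamma*D + eps``.

``G``, ``B`` and ``D`` denote the population-standardized versions of the raw
variables (mean 0, variance 1, divide-by-n convention), so ``beta`` and
``gamma`` are on the standardized scale and ``wB``/``wG`` are log-odds per SD.
The residual ``eps`` is standardized to unit variance and may be normal,
(centered) exponential or uniform.  A negative-binomial residual is handled
differently: there the bacterial level *is* a negative-binomial count whose
log-mean is shifted by the causal effect, because an additive NB residual is
ill-defined; monotone-rank analyses are invariant to that link choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize

from ._fast import standardize_pop

MODEL_IDS = ("a", "b", "c", "d")
ERROR_DISTS = ("normal", "exponential", "uniform", "negative-binomial")


@dataclass(frozen=True)
class CausalModelSpec:
    """Parameters of one generative causal model.

    Parameters
    ----------
    model_id:
        One of ``"a"``, ``"b"``, ``"c"``, ``"d"``.
    beta:
        Effect of standardized genotype on the bacterial level (SD units).
        Forced to 0 under models c and d.
    gamma:
        Effect of standardized disease on the bacterial level (SD units).
        Only model d uses it.
    omega0, omega_b, omega_g:
        Logistic intercept and log-odds coefficients of the standardized
        bacterial level / genotype.  ``omega0 = None`` means "calibrate to
        ``prevalence``".
    maf:
        Allele frequency of the coded allele, in (0, 1).
    prevalence:
        Target disease prevalence, in (0, 1).
    error_dist:
        Residual distribution of the bacterial level.
    nb_zero_frac, nb_mean:
        Only for ``error_dist="negative-binomial"``: target zero fraction and
        mean of the count distribution.
    """

    model_id: str
    beta: float = 0.0
    gamma: float = 0.0
    omega0: Optional[float] = None
    omega_b: float = 0.0
    omega_g: float = 0.0
    maf: float = 0.2
    prevalence: float = 0.3
    error_dist: str = "normal"
    nb_zero_frac: float = 0.3
    nb_mean: float = 10.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must be strictly inside (0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.error_dist not in ERROR_DISTS:
            raise ValueError(f"unknown error distribution {self.error_dist!r}")
        # per-model structural zeros
        checks = {
            "a": {"gamma": self.gamma, "omega_g": self.omega_g},
            "b": {"gamma": self.gamma, "omega_b": self.omega_b},
            "c": {"beta": self.beta, "gamma": self.gamma},
            "d": {"beta": self.beta, "omega_b": self.omega_b},
        }[self.model_id]
        for name, value in checks.items():
            if value != 0.0:
                raise ValueError(
                    f"model {self.model_id} forces {name}=0 (got {value})")

    def with_omega0(self, omega0: float) -> "CausalModelSpec":
        return replace(self, omega0=omega0)


@dataclass
class PopulationSample:
    """Joint draws of genotype, bacterial level and disease status.

    ``g``, ``b``, ``d`` are the raw vectors; ``G``, ``B``, ``D`` are the
    population-standardized views.  Optional ``subtype`` labels (strings) and
    integer ``severity`` (0..5) support the heterogeneity and severity
    experiments.
    """

    g: np.ndarray
    b: np.ndarray
    d: np.ndarray
    subtype: Optional[np.ndarray] = None
    severity: Optional[np.ndarray] = None
    G: np.ndarray = field(init=False)
    B: np.ndarray = field(init=False)
    D: np.ndarray = field(init=False)

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.d = np.asarray(self.d)
        if not set(np.unique(self.d)) <= {0, 1}:
            raise ValueError("disease status must be binary 0/1")
        self.G = standardize_pop(self.g, "genotype")
        self.B = standardize_pop(self.b, "bacterial level")
        self.D = standardize_pop(self.d.astype(float), "disease status")

    @property
    def n(self) -> int:
        return self.g.size

    @property
    def case_mask(self) -> np.ndarray:
        return np.asarray(self.d) == 1


def nb_size_for_zero_frac(mean: float, zero_frac: float) -> tuple[float, bool]:
    """Dispersion (size) of a negative binomial hitting a target zero fraction.

    For NB(mean m, size k), P(0) = (k/(k+m))^k, decreasing in k from 1 (k->0)
    to exp(-m) (Poisson limit).  Returns ``(size, clamped)``; ``clamped`` is
    True when the target lies below the Poisson floor and the closest
    attainable value (a large ``size``) is returned instead.
    """
    if not (0.0 <= zero_frac < 1.0):
        raise ValueError("zero fraction must be in [0, 1)")
    if mean <= 0:
        raise ValueError("mean must be positive")
    floor = np.exp(-mean)
    if zero_frac <= floor:
        return 1e6, zero_frac < floor

    def f(log_k):
        k = np.exp(log_k)
        return k * (np.log(k) - np.log(k + mean)) - np.log(zero_frac)

    lo, hi = -20.0, 20.0
    sol = optimize.brentq(f, lo, hi, xtol=1e-12)
    return float(np.exp(sol)), False


def _draw_error(rng: np.random.Generator, n: int, dist: str) -> np.ndarray:
    """Unit-variance, zero-mean residual draw."""
    if dist == "normal":
        return rng.standard_normal(n)
    if dist == "exponential":
        return rng.exponential(1.0, n) - 1.0
    if dist == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), n)
    raise ValueError(f"residual distribution {dist!r} has no additive form")


def _draw_genotype(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    g = rng.binomial(2, maf, n).astype(float)
    # at tiny n a monomorphic draw can occur; retry a few times then give up
    for _ in range(20):
        if g.std() > 0:
            return g
        g = rng.binomial(2, maf, n).astype(float)
    raise RuntimeError("genotype draw degenerate (all identical)")


def calibrate_intercept(spec: CausalModelSpec, target_prevalence: Optional[float] = None,
                        n_cal: int = 400_000, cal_seed: int = 2_019) -> float:
    """Logistic intercept giving the requested marginal disease prevalence.

    Solved by root-finding on the Monte-Carlo marginal expectation of the
    model's logistic over a large fixed calibration sample; closed form when
    all logistic effects are zero.
    """
    target = spec.prevalence if target_prevalence is None else target_prevalence
    if not (0.0 < target < 1.0):
        raise ValueError("target prevalence must be in (0, 1)")
    base = float(np.log(target / (1.0 - target)))
    if spec.omega_b == 0.0 and spec.omega_g == 0.0:
        return base
    rng = np.random.default_rng(cal_seed)
    g = _draw_genotype(rng, n_cal, spec.maf)
    G = standardize_pop(g)
    if spec.model_id in ("b", "d"):
        eta = spec.omega_g * G
    else:
        if spec.error_dist == "negative-binomial":
            b = _nb_level(rng, spec, G, None)
        else:
            b = spec.beta * G + _draw_error(rng, n_cal, spec.error_dist)
        B = standardize_pop(b)
        eta = spec.omega_b * B + spec.omega_g * G

    def f(w0):
        return np.mean(1.0 / (1.0 + np.exp(-(w0 + eta)))) - target

    lo, hi = base - 12.0, base + 12.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("intercept calibration failed to bracket the target")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _nb_level(rng: np.random.Generator, spec: CausalModelSpec,
              G: np.ndarray, D: Optional[np.ndarray]) -> np.ndarray:
    """Negative-binomial bacterial level with log-link causal shift."""
    size, _ = nb_size_for_zero_frac(spec.nb_mean, spec.nb_zero_frac)
    shift = spec.beta * G
    if D is not None:
        shift = shift + spec.gamma * D
    mean = spec.nb_mean * np.exp(shift)
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_population(spec: CausalModelSpec, n: int,
                        seed_or_rng) -> PopulationSample:
    """Draw one population of size ``n`` from a causal model.

    For models a/b/c the bacterial level is built from the genotype first and
    disease is then drawn from the model's logistic; for model d the disease is
    drawn first (it only depends on the genotype) and the bacterial level is
    derived from the standardized disease status.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    g = _draw_genotype(rng, n, spec.maf)
    G = standardize_pop(g)
    w0 = spec.omega0 if spec.omega0 is not None else calibrate_intercept(spec)

    if spec.model_id == "d":
        p = 1.0 / (1.0 + np.exp(-(w0 + spec.omega_g * G)))
        d = rng.binomial(1, p)
        D = standardize_pop(d.astype(float), "disease status")
        if spec.error_dist == "negative-binomial":
            b = _nb_level(rng, spec, np.zeros(n), D)
        else:
            b = spec.gamma * D + _draw_error(rng, n, spec.error_dist)
        return PopulationSample(g=g, b=b, d=d)

    if spec.error_dist == "negative-binomial":
        b = _nb_level(rng, spec, G, None)
    else:
        b = spec.beta * G + _draw_error(rng, n, spec.error_dist)
    B = standardize_pop(b, "bacterial level")
    eta = w0 + spec.omega_b * B + spec.omega_g * G
    p = 1.0 / (1.0 + np.exp(-eta))
    d = rng.binomial(1, p)
    return PopulationSample(g=g, b=b, d=d)


def ascertain(sample: PopulationSample, n_cases: Optional[int] = None,
              seed_or_rng=0) -> PopulationSample:
    """Uniform subsample of cases, with views re-standardized within it."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    idx = np.flatnonzero(sample.case_mask)
    if n_cases is None:
        chosen = idx
    else:
        if idx.size < n_cases:
            raise ValueError(
                f"only {idx.size} cases available, {n_cases} requested")
        chosen = rng.choice(idx, size=n_cases, replace=False)
    d = np.asarray(sample.d)[chosen]
    out = PopulationSample.__new__(PopulationSample)
    out.g = sample.g[chosen]
    out.b = sample.b[chosen]
    out.d = d
    out.subtype = None if sample.subtype is None else sample.subtype[chosen]
    out.severity = None if sample.severity is None else sample.severity[chosen]
    out.G = standardize_pop(out.g, "genotype")
    out.B = standardize_pop(out.b, "bacterial level")
    out.D = np.zeros_like(out.G)  # d is constant within cases by construction
    return out
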