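"""Meta-analysis, directional enrichment, effect concordance and slope tests.

Discovery and replication summary statistics are pooled by fixed-effect
inverse-variance weighting.  Directional enrichment (are most SNP-taxon
effects negative?) uses an exact binomial test; concordance between the
per-taxon summed SNP effects and the taxon-disease effects uses a Pearson
correlation with a permutation p-value; and the attenuation of a stratum's
effects relative to the full sample is tested as a regression slope against
the value 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    weights: tuple

    @property
    def n_studies(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class EnrichmentResult:
    n_direction: int
    n_total: int
    direction: str
    p: float


@dataclass(frozen=True)
class ConcordanceResult:
    summed_beta_g: np.ndarray
    beta_b: np.ndarray
    correlation: float
    p: float
    bins: Optional[object] = None


@dataclass(frozen=True)
class SlopeTest:
    slope: float
    se: float
    t: float
    p: float
    n: int


def se_from_beta_p(beta: float, p_two_sided: float) -> float:
    """Recover a standard error from a printed (beta, two-sided p) pair.

    Inverts the Wald test: SE = |beta| / Phi^{-1}(1 - p/2).  Used to
    reconstruct pooled estimates from published tables that print only the
    coefficient and its p-value.
    """
    if not 0.0 < p_two_sided < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    if beta == 0.0:
        raise ValueError("beta must be nonzero to recover a scale")
    z = stats.norm.ppf(1.0 - p_two_sided / 2.0)
    if z <= 0.0:
        raise ValueError("p too large; z-quantile not positive")
    return abs(beta) / z


def inverse_variance_meta(studies: Sequence[tuple]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of (beta, SE) pairs.

    Weights are proportional to 1/SE^2; the pooled SE is 1/sqrt(sum of
    weights), never larger than the smallest per-study SE.  A single study
    passes through with a warning.
    """
    if len(studies) == 0:
        raise ValueError("no studies to pool")
    betas = np.array([s[0] for s in studies], dtype=float)
    ses = np.array([s[1] for s in studies], dtype=float)
    if (ses <= 0).any() or not np.isfinite(ses).all():
        raise ValueError("standard errors must be positive and finite")
    if len(studies) == 1:
        warnings.warn("single study: pooled result equals the input",
                      stacklevel=2)
    w = 1.0 / ses ** 2
    wn = w / w.sum()
    beta = float(np.sum(wn * betas))
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta=beta, se=se, z=float(z), p=p, weights=tuple(wn))


def sign_enrichment(betas, direction: str = "negative") -> EnrichmentResult:
    """Exact one-sided binomial test for an excess of same-direction effects.

    Zero coefficients count toward neither side and reduce the total.  The
    p-value is P(X >= k | n, 1/2) for k effects in the tested direction.
    """
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    b = np.asarray(betas, dtype=float)
    b = b[np.isfinite(b)]
    nonzero = b[b != 0.0]
    n_total = nonzero.size
    if n_total == 0:
        raise ValueError("no nonzero coefficients to test")
    k = int((nonzero < 0).sum() if direction == "negative"
            else (nonzero > 0).sum())
    p = float(stats.binomtest(k, n_total, 0.5, alternative="greater").pvalue)
    return EnrichmentResult(n_direction=k, n_total=n_total,
                            direction=direction, p=p)


def concordance(beta_g_tables: Sequence[np.ndarray], beta_b,
                n_perm: int = 10_000, seed: int = 0,
                n_bins: int = 8) -> ConcordanceResult:
    """Concordance of summed SNP-taxon effects with taxon-disease effects.

    Per taxon the SNP effects are summed across genes; the Pearson
    correlation of the sums with the taxon-disease coefficients is tested by
    permuting taxon labels.  ``bins`` summarizes the disease effects over
    bins of the summed SNP effect for display.
    """
    tables = [np.asarray(t, dtype=float) for t in beta_g_tables]
    beta_b = np.asarray(beta_b, dtype=float)
    if not tables:
        raise ValueError("need at least one SNP-effect table")
    if any(t.shape != beta_b.shape for t in tables):
        raise ValueError("per-gene tables and beta_b must align over taxa")
    summed = np.sum(tables, axis=0)
    mask = np.isfinite(summed) & np.isfinite(beta_b)
    summed, beta_b = summed[mask], beta_b[mask]
    if summed.size < 3:
        raise ValueError("fewer than 3 paired taxa")
    r_obs = float(np.corrcoef(summed, beta_b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = np.corrcoef(summed, rng.permutation(beta_b))[0, 1]
        if abs(r) >= abs(r_obs) - 1e-15:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    edges = np.quantile(summed, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    which = np.clip(np.searchsorted(edges, summed, side="left") - 1,
                    0, n_bins - 1)
    bins = [{"bin": i, "lo": float(edges[i]), "hi": float(edges[i + 1]),
             "n": int((which == i).sum()),
             "mean_beta_b": float(beta_b[which == i].mean())
             if (which == i).any() else float("nan")}
            for i in range(n_bins)]
    return ConcordanceResult(summed_beta_g=summed, beta_b=beta_b,
                             correlation=r_obs, p=float(p), bins=bins)


def slope_vs_unity(beta_subset, beta_full) -> SlopeTest:
    """Test whether subset effects attenuate relative to full-sample effects.

    Least-squares slope of the subset coefficients on the full-sample ones; a
    Student t-test of (slope - 1)/SE against an expected slope of 1.  A slope
    below 1 indicates attenuation of the subset effects.
    """
    y = np.asarray(beta_subset, dtype=float)
    x = np.asarray(beta_full, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 effect pairs")
    if np.std(x) == 0:
        raise ValueError("full-sample effects are constant")
    xc = x - x.mean()
    slope = float((xc @ (y - y.mean())) / (xc @ xc))
    resid = y - y.mean() - slope * xc
    df = x.size - 2
    se = float(np.sqrt((resid @ resid) / df / (xc @ xc)))
    if se == 0.0:
        t = 0.0 if slope == 1.0 else np.inf * np.sign(slope - 1.0)
        return SlopeTest(slope=slope, se=se, t=float(t),
                         p=1.0 if slope == 1.0 else 0.0, n=int(x.size))
    t = (slope - 1.0) / se
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return SlopeTest(slope=slope, se=se, t=float(t), p=p, n=int(x.size))
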