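"""Simulation experiments: bias replicate grids, sparsity, heterogeneity,
severity, taxon panels and the polynomial check of the logistic linearization.

Every experiment follows the same template: draw a population from one of the
four causal models, form the case-only subsample a clinical study would
collect, estimate the SNP-bacterium association in both, and record the
replicate-level estimates.  The experiments differ in which nuisance feature
of real data they add (zero-inflated counts, subtype admixture, a severity
intermediate).  All randomness flows from a single master seed through
counter-based child generators, so runs are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._fast import (logistic_slope, ols_slope, ols_slope_se_p, signed_r2,
                    standardize_pop)
from .assoc import rank_int
from .models import (CausalModelSpec, calibrate_intercept,
                     nb_size_for_zero_frac, simulate_population)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _calibrate_eta(eta: np.ndarray, target: float) -> float:
    """Intercept making mean(sigmoid(w0 + eta)) hit the target prevalence."""
    base = np.log(target / (1.0 - target))
    if not np.any(eta):
        return float(base)
    return float(optimize.brentq(
        lambda w: _sigmoid(w + eta).mean() - target,
        base - 15.0, base + 15.0, xtol=1e-6))


# ---------------------------------------------------------------------------
# bias replicate grids (normal / exponential / uniform residuals)

def run_bias_experiment(specs: Sequence[CausalModelSpec], reps: int, n: int,
                        seed: int = 0) -> pd.DataFrame:
    """Replicate grid of whole-population vs case-only OLS coefficients.

    For every spec and replicate, draws a population of size ``n``, regresses
    the population-standardized bacterial level on the population-standardized
    genotype in everyone and in cases only, and records both coefficients and
    their difference (the realized ascertainment bias
    ``delta = beta_case - beta_pop``).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    specs = list(specs)
    rows = []
    ss = np.random.SeedSequence(seed)
    for spec, child in zip(specs, ss.spawn(len(specs))):
        spec = spec if spec.omega0 is not None else spec.with_omega0(
            calibrate_intercept(spec))
        rngs = [np.random.default_rng(c) for c in child.spawn(reps)]
        for rep, rng in enumerate(rngs):
            s = simulate_population(spec, n, rng)
            beta_pop, _, p_pop = ols_slope_se_p(s.G, s.B)
            mask = s.case_mask
            beta_case, _, p_case = ols_slope_se_p(s.G[mask], s.B[mask])
            rows.append({
                "model": spec.model_id, "error_dist": spec.error_dist,
                "beta": spec.beta, "gamma": spec.gamma,
                "omega_b": spec.omega_b, "omega_g": spec.omega_g,
                "prevalence": spec.prevalence, "rep": rep, "n": n,
                "n_cases": int(mask.sum()),
                "beta_pop": beta_pop, "beta_case": beta_case,
                "delta": beta_case - beta_pop,
                "p_pop": p_pop, "p_case": p_case,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sparsity experiment: negative-binomial levels, varying zero fraction

#: large-effect, common-disease regime of the replicate grids
SPARSITY_EFFECTS = {"beta_link": -0.5, "omega_b": -0.7, "omega_g": 0.7,
                    "gamma_shift": -0.7, "prevalence": 0.3, "nb_mean": 10.0}


def _nb_draw(rng, mean, size):
    return rng.negative_binomial(size, size / (size + mean)).astype(float)


def run_sparsity_experiment(model_id: str, reps: int = 20_000, n: int = 10_000,
                            n_cases: int = 200, seed: int = 0,
                            zero_frac_range=(0.0, 0.95)) -> pd.DataFrame:
    """Case-only association strength as data sparsity grows.

    Per replicate: allele frequency ~ U[0.05, 0.95]; the bacterial level is a
    negative-binomial count whose dispersion is solved to hit a
    replicate-specific zero fraction; disease follows the causal model's
    logistic on the standardized count; 200 cases are sampled and the
    SNP-bacterium association is estimated on the raw and on the rank-INT
    level.  Records the signed explained variance and p-value per replicate
    together with its realized zero fraction.
    """
    eff = SPARSITY_EFFECTS
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        maf = rng.uniform(0.05, 0.95)
        zf = rng.uniform(*zero_frac_range)
        size, _ = nb_size_for_zero_frac(eff["nb_mean"], zf)
        g = rng.binomial(2, maf, n).astype(float)
        if g.std() == 0:
            continue
        G = standardize_pop(g)
        if model_id in ("a", "b"):
            b = _nb_draw(rng, eff["nb_mean"] * np.exp(eff["beta_link"] * G), size)
        else:
            b = _nb_draw(rng, np.full(n, eff["nb_mean"]), size)
        if b.std() == 0:
            continue
        B = standardize_pop(b)
        if model_id == "a":
            eta = eff["omega_b"] * B
        elif model_id == "b":
            eta = eff["omega_g"] * G
        elif model_id == "c":
            eta = eff["omega_b"] * B + eff["omega_g"] * G
        elif model_id == "d":
            eta = eff["omega_g"] * G
        else:
            raise ValueError(f"unknown model id {model_id!r}")
        w0 = _calibrate_eta(eta, eff["prevalence"])
        d = rng.binomial(1, _sigmoid(w0 + eta))
        if model_id == "d":
            D = standardize_pop(d.astype(float))
            b = _nb_draw(rng, eff["nb_mean"] * np.exp(
                eff["gamma_shift"] * (d - d.mean())), size)
        cases = np.flatnonzero(d == 1)
        if cases.size < n_cases:
            continue
        pick = rng.choice(cases, n_cases, replace=False)
        g_c, b_c = g[pick], b[pick]
        if g_c.std() == 0 or b_c.std() == 0:
            continue
        _, _, p_raw = ols_slope_se_p(g_c, b_c)
        b_int = rank_int(b_c)
        _, _, p_int = ols_slope_se_p(g_c, b_int)
        rows.append({
            "model": model_id, "rep": rep, "zero_frac": zf,
            "zero_frac_obs": float((b == 0).mean()), "maf": maf,
            "signed_r2_raw": signed_r2(g_c, b_c),
            "signed_r2_int": signed_r2(g_c, b_int),
            "p_raw": p_raw, "p_int": p_int,
        })
    return pd.DataFrame(rows)


def sparsity_bin_summary(df: pd.DataFrame, n_bins: int = 5) -> pd.DataFrame:
    """Median signed explained variance per zero-fraction bin."""
    edges = np.linspace(df["zero_frac"].min() - 1e-9,
                        df["zero_frac"].max() + 1e-9, n_bins + 1)
    which = np.clip(np.searchsorted(edges, df["zero_frac"]) - 1, 0, n_bins - 1)
    out = df.assign(bin=which).groupby("bin").agg(
        n=("rep", "size"),
        zero_frac_mid=("zero_frac", "mean"),
        med_signed_r2_raw=("signed_r2_raw", "median"),
        med_signed_r2_int=("signed_r2_int", "median"),
        med_p_int=("p_int", "median"),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# heterogeneity experiment: CD from the causal model, UC independent

#: literature-scale regime: IBD prevalence ~1%, per-SD genetic log-odds 0.15,
#: bacteria-disease log-odds -0.4 per SD, case-control level shift -0.4 SD
HET_EFFECTS = {"cd_prev": 0.005, "uc_prev": 0.005, "omega_g": 0.15,
               "omega_b": -0.4, "beta_link": -0.4, "case_shift": -0.4,
               "nb_mean": 10.0}


def run_heterogeneity_experiment(model_id: str, reps: int = 10_000,
                                 n: int = 30_000, n_cases: int = 200,
                                 seed: int = 0) -> pd.DataFrame:
    """Subtype admixture: does pooling CD with an unrelated UC dilute or bias?

    CD status follows the causal model; UC is drawn independently of
    everything; IBD is their union.  From each replicate 200 IBD cases are
    sampled and the G-B association (after rank-INT) is tested in the IBD
    sample and in the CD-only and UC-only subsets.
    """
    eff = HET_EFFECTS
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        maf = rng.uniform(0.05, 0.20)
        zf = rng.uniform(0.0, 0.80)
        size, _ = nb_size_for_zero_frac(eff["nb_mean"], zf)
        g = rng.binomial(2, maf, n).astype(float)
        if g.std() == 0:
            continue
        G = standardize_pop(g)
        if model_id in ("a", "b"):
            b = _nb_draw(rng, eff["nb_mean"] * np.exp(eff["beta_link"] * G), size)
        else:
            b = _nb_draw(rng, np.full(n, eff["nb_mean"]), size)
        if b.std() == 0:
            continue
        B = standardize_pop(b)
        if model_id == "a":
            eta = eff["omega_b"] * B
        elif model_id == "b":
            eta = eff["omega_g"] * G
        elif model_id == "c":
            eta = eff["omega_b"] * B + eff["omega_g"] * G
        elif model_id == "d":
            eta = eff["omega_g"] * G
        else:
            raise ValueError(f"unknown model id {model_id!r}")
        w0 = _calibrate_eta(eta, eff["cd_prev"])
        cd = rng.binomial(1, _sigmoid(w0 + eta))
        if model_id == "d":
            sigma_cd = np.sqrt(eff["cd_prev"] * (1 - eff["cd_prev"]))
            gamma_link = eff["case_shift"] * sigma_cd  # per standardized-CD unit
            D = standardize_pop(cd.astype(float)) if cd.std() > 0 else np.zeros(n)
            b = _nb_draw(rng, eff["nb_mean"] * np.exp(gamma_link * D), size)
        uc = rng.binomial(1, eff["uc_prev"], n)
        uc = np.where(cd == 1, 0, uc)  # subtypes are exclusive labels
        ibd = ((cd == 1) | (uc == 1)).astype(int)
        cases = np.flatnonzero(ibd == 1)
        if cases.size < n_cases:
            continue
        pick = rng.choice(cases, n_cases, replace=False)
        row = {"model": model_id, "rep": rep, "maf": maf, "zero_frac": zf,
               "n_ibd": int(cases.size)}
        strata = {"IBD": np.ones(n_cases, bool),
                  "CD": cd[pick] == 1, "UC": uc[pick] == 1}
        for name, mask in strata.items():
            g_s, b_s = g[pick][mask], b[pick][mask]
            if mask.sum() < 10 or g_s.std() == 0 or np.unique(b_s).size < 3:
                row[f"beta_{name}"] = np.nan
                row[f"p_{name}"] = np.nan
                continue
            beta, _, p = ols_slope_se_p(g_s, rank_int(b_s))
            row[f"beta_{name}"] = beta
            row[f"p_{name}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# severity experiment: a 0-5 severity score replaces the binary status

SEVERITY_EFFECTS = {"beta": -0.4, "omega_b": -0.7, "omega_g": 0.7,
                    "gamma": -0.4, "prevalence": 0.3, "maf": 0.2}


def run_severity_experiment(model_id: str, reps: int = 200, n: int = 10_000,
                            seed: int = 0) -> pd.DataFrame:
    """Disease severity (Binomial, 5 trials) as the true intermediate.

    The causal model's logistic supplies the per-trial probability; severity
    is the number of successes out of 5 and IBD is severity >= 1.  The
    case-only G-B correlation is computed with and without adjusting the
    bacterial level for severity (residualizing on the score).
    """
    eff = SEVERITY_EFFECTS
    # per-trial probability whose 5-trial union hits the prevalence target
    p_trial = 1.0 - (1.0 - eff["prevalence"]) ** (1.0 / 5.0)
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        g = rng.binomial(2, eff["maf"], n).astype(float)
        G = standardize_pop(g)
        eps = rng.standard_normal(n)
        if model_id in ("a", "b"):
            b = eff["beta"] * G + eps
        else:
            b = eps.copy()
        B = standardize_pop(b)
        if model_id == "a":
            eta = eff["omega_b"] * B
        elif model_id == "b":
            eta = eff["omega_g"] * G
        elif model_id in ("c",):
            eta = eff["omega_b"] * B + eff["omega_g"] * G
        else:
            eta = eff["omega_g"] * G
        w0 = _calibrate_eta(eta, p_trial)
        sev = rng.binomial(5, _sigmoid(w0 + eta))
        if model_id == "d":
            S = standardize_pop(sev.astype(float))
            b = eff["gamma"] * S + eps
        case = sev >= 1
        if case.sum() < 30 or case.sum() == n:
            continue
        g_c, b_c, s_c = g[case], b[case], sev[case].astype(float)
        r_unadj = float(np.corrcoef(g_c, b_c)[0, 1])
        # adjust the bacterial level for severity within cases
        s_cent = s_c - s_c.mean()
        if s_cent.std() > 0:
            b_adj = b_c - (s_cent @ (b_c - b_c.mean())) / (s_cent @ s_cent) * s_cent
        else:
            b_adj = b_c
        r_adj = float(np.corrcoef(g_c, b_adj)[0, 1])
        _, _, p_unadj = ols_slope_se_p(g_c, b_c)
        _, _, p_adj = ols_slope_se_p(g_c, b_adj)
        rows.append({"model": model_id, "rep": rep, "n_cases": int(case.sum()),
                     "corr_unadj": r_unadj, "corr_adj": r_adj,
                     "p_unadj": p_unadj, "p_adj": p_adj})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# taxon panels: corr(beta^g in cases, beta^B case-control) across taxa

PANEL_EFFECTS = {"beta": -0.4, "omega_b": -0.5, "omega_g": 0.5, "gamma": -0.4,
                 "prevalence": 0.3, "maf": 0.2, "scale_sd": 0.3}


@dataclass
class PanelResult:
    """Per-taxon estimate pairs and their correlation, per panel."""

    per_panel: pd.DataFrame      # one row per (panel, taxon)
    correlations: np.ndarray     # one correlation per panel


def run_panel_experiment(n_taxa: int = 50, model_id: str = "a", reps: int = 20,
                         seed: int = 0, n_cases: int = 500,
                         n_controls: int = 500, n_pop: int = 4_000,
                         effects: Optional[dict] = None) -> PanelResult:
    """Panels of taxa under one causal model; pairs (beta^g_cases, beta^B).

    Per taxon the SNP-taxon coefficient is estimated in cases only (OLS) and
    the taxon-disease coefficient by case-control logistic regression.  Taxa
    within a panel share the causal model but differ by a positive
    "involvement" scale multiplying the model's effect(s) — under mediation or
    pleiotropy the gene-taxon and taxon-disease effects co-vary across taxa,
    which is what produces the concordance signature.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    eff = dict(PANEL_EFFECTS)
    if effects:
        eff.update(effects)
    ss = np.random.SeedSequence(seed)
    rows = []
    corrs = []
    for panel, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        scale = np.clip(rng.normal(1.0, eff["scale_sd"], n_taxa), 0.2, None)
        bg, bb = [], []
        for t in range(n_taxa):
            u = scale[t]
            g = rng.binomial(2, eff["maf"], n_pop).astype(float)
            if g.std() == 0:
                g[0] = 1.0
            G = standardize_pop(g)
            eps = rng.standard_normal(n_pop)
            if model_id in ("a", "b"):
                b = eff["beta"] * u * G + eps
            else:
                b = eps.copy()
            B = standardize_pop(b)
            if model_id == "a":
                eta = eff["omega_b"] * u * B
            elif model_id == "b":
                eta = eff["omega_g"] * G
            elif model_id == "c":
                eta = eff["omega_b"] * u * B + eff["omega_g"] * G
            elif model_id == "d":
                eta = eff["omega_g"] * G
            else:
                raise ValueError(f"unknown model id {model_id!r}")
            w0 = _calibrate_eta(eta, eff["prevalence"])
            d = rng.binomial(1, _sigmoid(w0 + eta))
            if model_id == "d":
                D = standardize_pop(d.astype(float))
                b = eff["gamma"] * u * D + eps
            cases = np.flatnonzero(d == 1)
            controls = np.flatnonzero(d == 0)
            if cases.size < n_cases or controls.size < n_controls:
                bg.append(np.nan)
                bb.append(np.nan)
                continue
            pick_ca = rng.choice(cases, n_cases, replace=False)
            pick_co = rng.choice(controls, n_controls, replace=False)
            beta_g = ols_slope(g[pick_ca], b[pick_ca])
            cc = np.r_[pick_ca, pick_co]
            b_cc = standardize_pop(b[cc])
            beta_b, _ = logistic_slope(b_cc, d[cc])
            bg.append(beta_g)
            bb.append(beta_b)
            rows.append({"panel": panel, "taxon": t, "scale": u,
                         "beta_g_cases": beta_g, "beta_b_cc": beta_b})
        bg_a, bb_a = np.asarray(bg), np.asarray(bb)
        ok = np.isfinite(bg_a) & np.isfinite(bb_a)
        corrs.append(float(np.corrcoef(bg_a[ok], bb_a[ok])[0, 1])
                     if ok.sum() > 2 else np.nan)
    return PanelResult(per_panel=pd.DataFrame(rows),
                       correlations=np.asarray(corrs))


# ---------------------------------------------------------------------------
# end-to-end recovery: simulate two-stage panels, score the causal models

def run_model_recovery(model_id: str, runs: int = 100, seed: int = 0,
                       n_taxa: int = 50, n_cases: int = 500,
                       n_controls: int = 500, n_pop: int = 5_000) -> pd.DataFrame:
    """Full-circle check: can the sign-based ranking recover the generator?

    Each run simulates a discovery and an (independent) replication panel
    under one causal model, extracts the observed sign pattern (panel-level
    case-only direction across the two stages, concordance of the per-taxon
    SNP and disease effects) and scores the four models.  A run whose data
    yield no informative feature excludes nothing, so its verdict is the full
    model set.  Returns one row per run with the verdict and whether it
    contains the generating model.
    """
    from .meta import concordance as _concordance
    from .modelfit import MODELS, collect_observed, score_models

    ss = np.random.SeedSequence(seed)
    rows = []
    for run, child in enumerate(ss.spawn(runs)):
        s1, s2 = child.spawn(2)
        disc = run_panel_experiment(n_taxa, model_id, reps=1,
                                    seed=s1.generate_state(1)[0] % (2 ** 31),
                                    n_cases=n_cases, n_controls=n_controls,
                                    n_pop=n_pop)
        repl = run_panel_experiment(n_taxa, model_id, reps=1,
                                    seed=s2.generate_state(1)[0] % (2 ** 31),
                                    n_cases=n_cases, n_controls=n_controls,
                                    n_pop=n_pop)
        bg1 = disc.per_panel["beta_g_cases"].to_numpy()
        bg2 = repl.per_panel["beta_g_cases"].to_numpy()
        bb = disc.per_panel["beta_b_cc"].to_numpy()
        conc = _concordance([bg1], bb, n_perm=500,
                            seed=s1.generate_state(1)[0] % (2 ** 31))
        obs = collect_observed(beta_g_discovery=bg1, beta_g_replication=bg2,
                               concordance_result=conc)
        try:
            report = score_models(obs)
            verdicts = set(report.verdicts)
        except ValueError:  # nothing informative -> nothing excluded
            verdicts = set(MODELS)
        rows.append({"model": model_id, "run": run,
                     "verdict": "".join(sorted(verdicts)),
                     "contains_true": model_id in verdicts,
                     "case_only": obs.case_only,
                     "concordance_sign": obs.concordance})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# polynomial linear approximation of the logistic surface

@dataclass
class PolyApproxResult:
    """Nested linear fits of the disease probability surface.

    ``orders[k]`` is the maximal monomial degree of model k (model0 = order 1,
    marginal terms only; model3 = order 4 with interactions); ``r2[k]`` is the
    squared correlation between fitted and true probabilities; ``coefs[k]``
    maps monomial labels "B^i*G^j" to their lambda coefficients.
    """

    orders: list
    r2: list
    coefs: list

    def __post_init__(self):
        if any(b < a - 1e-12 for a, b in zip(self.r2, self.r2[1:])):
            raise AssertionError("fit quality must be non-decreasing in order")


def fit_polynomial_logit_approx(B, G, p_true, max_order: int = 4) -> PolyApproxResult:
    """Least-squares polynomial approximations of a logistic probability.

    Regresses the true disease probability on monomials ``B^i G^j`` with
    ``1 <= i+j <= order`` for each order up to ``max_order`` (rank-deficient
    columns dropped via least squares on the pseudo-inverse).  Near a
    prevalence of one half with modest effects the first-order (marginal)
    model already captures the surface; for rare diseases or large effects
    the higher-order terms are needed.
    """
    B = np.asarray(B, dtype=float)
    G = np.asarray(G, dtype=float)
    p = np.asarray(p_true, dtype=float)
    if not 1 <= max_order <= 6:
        raise ValueError("max_order must be in 1..6")
    orders, r2s, coefs = [], [], []
    for order in range(1, max_order + 1):
        labels = ["const"]
        cols = [np.ones_like(p)]
        for total in range(1, order + 1):
            for i in range(total + 1):
                j = total - i
                cols.append((B ** i) * (G ** j))
                labels.append(f"B^{i}*G^{j}")
        X = np.column_stack(cols)
        lam, *_ = np.linalg.lstsq(X, p, rcond=None)
        fitted = X @ lam
        r = np.corrcoef(fitted, p)[0, 1] if fitted.std() > 0 else 0.0
        orders.append(order)
        r2s.append(float(r * r))
        coefs.append(dict(zip(labels, map(float, lam))))
    r2s = list(np.maximum.accumulate(r2s))  # guard tiny numerical dips
    return PolyApproxResult(orders=orders, r2=r2s, coefs=coefs)
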