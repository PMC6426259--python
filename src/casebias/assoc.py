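"""Association pipeline: taxon filtering, rank-INT, covariate search, regressions.

The study's discovery test is an ordinary least-squares regression of a
rank-inverse-normal-transformed taxon on an untransformed genotype, adjusting
for host confounders plus same-rank taxon covariates chosen by a greedy
screen; the case-control arm is a logistic regression of disease on the taxon.
Multiplicity is controlled by Bonferroni within each taxonomic rank, and the
genotype model is re-fit within disease-subtype strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DISCOVERY_CONFOUNDERS = ["sex", "age", "smoking", "treat_5asa",
                         "treat_corticosteroids", "treat_antitnf",
                         "treat_thiopurine_mtx"]
REPLICATION_CONFOUNDERS = ["sex", "age", "smoking", "mesalamine",
                           "antibiotics", "immunosuppressants"]
STRATA = ("IBD", "CD", "CDil", "CDni", "UC")

#: offset of the Blom rank-INT variant
INT_OFFSET = 3.0 / 8.0


@dataclass
class ProcessedTable:
    """Outcome of taxon filtering: retained values plus a drop ledger."""

    values: pd.DataFrame                 # samples x retained taxa (raw)
    transformed: pd.DataFrame            # samples x retained taxa (rank-INT)
    ranks: dict                          # taxon id -> rank label
    dropped: pd.DataFrame                # columns: taxon, reason

    @property
    def retained(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AssocResult:
    """One regression result."""

    taxon: str
    predictor: str
    stratum: str
    beta: float
    se: float
    p: float
    n: int
    covariates: list = field(default_factory=list)
    nuisance: dict = field(default_factory=dict)
    rank: Optional[str] = None
    candidate: bool = False
    missing: bool = False
    flag: Optional[str] = None

    def as_row(self) -> dict:
        return {"taxon": self.taxon, "predictor": self.predictor,
                "stratum": self.stratum, "rank": self.rank, "beta": self.beta,
                "se": self.se, "p": self.p, "n": self.n,
                "candidate": self.candidate, "missing": self.missing,
                "covariates": ",".join(self.covariates), "flag": self.flag}


def rank_int(values, offset: float = INT_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset, mid-ranks for ties).

    Maps ranks r (1..n) through the standard normal quantile at
    (r - offset) / (n + 1 - 2*offset); ties — including the zero mass of
    sparse taxa — share their mid-rank.  Invariant to any strictly monotone
    re-scaling of the input.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("rank_int expects a 1-d vector")
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if not np.isfinite(v).all():
        raise ValueError("input contains non-finite values")
    if np.unique(v).size == 1:
        raise ValueError("input is constant; rank-INT undefined")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.size + 1.0 - 2.0 * offset))


def filter_taxa(table: pd.DataFrame, ranks: dict,
                min_nonzero_frac: float = 0.20,
                lineages: Optional[dict] = None,
                require_annotation: bool = False) -> ProcessedTable:
    """Drop low-prevalence (and optionally poorly annotated) taxa.

    A taxon is retained when its fraction of non-zero values is >= the
    threshold (a taxon present in exactly 20% of samples is kept).  When
    ``require_annotation`` is set, taxa whose lineage string (from
    ``lineages``) is missing or incomplete are dropped as unannotated.
    Retained taxa are rank-INT transformed.
    """
    if table.shape[1] == 0:
        raise ValueError("empty taxon table")
    dropped = []
    keep = []
    nonzero = (table > 0).mean(axis=0)
    for tid in table.columns:
        if require_annotation:
            lin = (lineages or {}).get(tid, "")
            if not lin or "__" not in str(lin).split("|")[-1]:
                dropped.append({"taxon": tid, "reason": "unannotated"})
                continue
        if nonzero[tid] < min_nonzero_frac:
            dropped.append({"taxon": tid, "reason": "low-prevalence"})
        else:
            keep.append(tid)
    if not keep:
        raise ValueError("all taxa dropped by the prevalence filter")
    transformed = pd.DataFrame(
        {tid: rank_int(table[tid].to_numpy()) for tid in keep},
        index=table.index)
    return ProcessedTable(values=table[keep].copy(), transformed=transformed,
                          ranks={t: ranks.get(t) for t in keep},
                          dropped=pd.DataFrame(dropped,
                                               columns=["taxon", "reason"]))


def select_level_covariates(outcome: np.ndarray, candidates: pd.DataFrame,
                            genotype: np.ndarray, max_k: int = 5,
                            alpha_in: float = 0.05,
                            alpha_geno: float = 0.05) -> list[str]:
    """Greedy same-rank covariate screen for the genotype model.

    Admits up to ``max_k`` candidate taxa that (i) explain residual outcome
    variance (nominal partial p < ``alpha_in``) and (ii) show no association
    with the genotype (nominal p > ``alpha_geno``), so conditioning cannot
    open a genotype-collider path.  Deterministic given the data: at each step
    the eligible candidate with the smallest partial p is added.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(genotype, dtype=float)
    n = y.size
    eligible = []
    for cid in candidates.columns:
        x = candidates[cid].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        r = np.corrcoef(x, g)[0, 1]
        t = r * np.sqrt(max(n - 2, 1)) / np.sqrt(max(1 - r * r, 1e-12))
        p_g = 2 * stats.t.sf(abs(t), df=n - 2)
        if p_g > alpha_geno:
            eligible.append(cid)
    chosen: list[str] = []
    resid = y - y.mean()
    for _ in range(max_k):
        best, best_p = None, alpha_in
        for cid in eligible:
            if cid in chosen:
                continue
            x = candidates[cid].to_numpy(dtype=float)
            X = sm.add_constant(np.column_stack(
                [candidates[c].to_numpy(dtype=float) for c in chosen] + [x]))
            fit = sm.OLS(y, X).fit()
            p = fit.pvalues[-1]
            if p < best_p:
                best, best_p = cid, p
        if best is None:
            break
        chosen.append(best)
    return chosen


def _design(frames: Sequence[np.ndarray]) -> np.ndarray:
    return sm.add_constant(np.column_stack(frames)) if frames else None


def fit_snp_taxon(y, g, Z: Optional[pd.DataFrame] = None,
                  C: Optional[pd.DataFrame] = None, stratum: str = "IBD",
                  taxon: str = "", predictor: str = "",
                  rank: Optional[str] = None) -> AssocResult:
    """OLS of a (transformed) taxon on the genotype with covariates.

    The outcome is expected variance-standardized (rank-INT already is);
    the genotype is left untransformed, so beta is the change in outcome mean
    per additional risk allele (or per carrier state).  Two-sided p from the
    t reference.  Missing covariate rows are dropped listwise.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    parts = [g]
    names = ["genotype"]
    for block in (Z, C):
        if block is not None and block.shape[1]:
            parts.append(block.to_numpy(dtype=float))
            names.extend(block.columns)
    X = np.column_stack(parts)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    if np.std(X[:, 0]) == 0:
        raise ValueError("genotype is constant in this stratum")
    X = sm.add_constant(X)
    if y.size < X.shape[1] + 1:
        raise ValueError("too few observations for the design")
    # drop collinear columns (keep genotype) rather than failing
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    dropped_cols = X.shape[1] - len(keep)
    X = X[:, keep]
    fit = sm.OLS(y, X).fit()
    nuisance = {("const" if k == 0 else names[k - 1]): float(fit.params[i])
                for i, k in enumerate(keep) if k != 1}
    return AssocResult(
        taxon=taxon, predictor=predictor, stratum=stratum, rank=rank,
        beta=float(fit.params[keep.index(1)]),
        se=float(fit.bse[keep.index(1)]),
        p=float(fit.pvalues[keep.index(1)]), n=int(y.size),
        covariates=[names[k - 1] for k in keep if k >= 2],
        nuisance=nuisance,
        flag=f"dropped {dropped_cols} collinear columns" if dropped_cols else None)


def fit_taxon_disease(b, status, Z: Optional[pd.DataFrame] = None,
                      taxon: str = "", rank: Optional[str] = None) -> AssocResult:
    """Logistic regression of case/control status on a transformed taxon.

    Returns the log-odds of disease per SD of the (rank-INT) taxon.  Perfect
    separation yields a flagged sentinel result (infinite coefficient) that
    downstream consumers exclude.
    """
    b = np.asarray(b, dtype=float)
    d = np.asarray(status, dtype=float)
    parts = [b]
    names = ["taxon"]
    if Z is not None and Z.shape[1]:
        parts.append(Z.to_numpy(dtype=float))
        names.extend(Z.columns)
    X = np.column_stack(parts)
    mask = np.isfinite(d) & np.isfinite(X).all(axis=1)
    d, X = d[mask], X[mask]
    classes = set(np.unique(d))
    if not classes == {0.0, 1.0}:
        raise ValueError("need both cases and controls")
    X = sm.add_constant(X)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(d, X).fit(disp=0, maxiter=100)
        beta, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
        separated = not np.isfinite(se) or se > 50 or abs(beta) > 15
    except Exception:
        separated = True
    if separated:
        return AssocResult(taxon=taxon, predictor="disease", stratum="case-control",
                           rank=rank, beta=float("inf"), se=float("inf"), p=1.0,
                           n=int(d.size), missing=True, flag="perfect separation")
    return AssocResult(taxon=taxon, predictor="disease", stratum="case-control",
                       rank=rank, beta=beta, se=se, p=p, n=int(d.size),
                       covariates=names[1:])


def per_level_bonferroni(results: Sequence[AssocResult],
                         alpha: float = 0.05) -> list[AssocResult]:
    """Flag candidates at p < alpha / (number of tests within the same rank)."""
    counts: dict = {}
    for r in results:
        if not r.missing:
            counts[r.rank] = counts.get(r.rank, 0) + 1
    for r in results:
        m = counts.get(r.rank, 0)
        r.candidate = bool(m and not r.missing and r.p < alpha / m)
    return list(results)


def stratified_analysis(transformed: pd.DataFrame, genotype: pd.Series,
                        metadata: pd.DataFrame, ranks: dict,
                        Z: Optional[pd.DataFrame] = None,
                        strata: Sequence[str] = STRATA,
                        min_n: int = 10,
                        predictor: str = "") -> list[AssocResult]:
    """Re-fit the genotype model within disease-subtype strata.

    Strata: IBD (all cases), CD, ileal CD, non-ileal CD, UC.  A stratum with a
    constant genotype or fewer than ``min_n`` samples emits a missing-result
    record (the "-" cells of a results table) rather than failing.
    """
    cases = metadata["d"] == 1
    masks = {
        "IBD": cases,
        "CD": cases & (metadata["subtype"] == "CD"),
        "CDil": cases & (metadata["subtype"] == "CD") & (metadata["ileal"] == 1),
        "CDni": cases & (metadata["subtype"] == "CD") & (metadata["ileal"] == 0),
        "UC": cases & (metadata["subtype"] == "UC"),
    }
    out: list[AssocResult] = []
    for stratum in strata:
        mask = masks[stratum].to_numpy()
        for tid in transformed.columns:
            y = transformed.loc[mask, tid].to_numpy()
            g = genotype.to_numpy()[mask]
            Zs = Z.loc[mask] if Z is not None else None
            try:
                if mask.sum() < min_n or np.std(g[np.isfinite(g)]) == 0:
                    raise ValueError("degenerate stratum")
                res = fit_snp_taxon(y, g, Zs, None, stratum=stratum,
                                    taxon=tid, predictor=predictor,
                                    rank=ranks.get(tid))
            except ValueError as exc:
                res = AssocResult(taxon=tid, predictor=predictor,
                                  stratum=stratum, rank=ranks.get(tid),
                                  beta=float("nan"), se=float("nan"), p=float("nan"),
                                  n=int(mask.sum()), missing=True, flag=str(exc))
            out.append(res)
    return out


def results_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
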