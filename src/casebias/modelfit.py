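"""Counterfactual model ranking: observed association signs vs model predictions.

Each causal model predicts a distinctive pattern of signs — the case-only
SNP-taxon association, the panel-level concordance between SNP-taxon and
taxon-disease effects, and the subtype-vs-full slope.  This module reduces
the pipeline's outputs to an :class:`ObservedSigns` pattern, compares it with
each model's predicted pattern and returns the set of models that no observed
feature contradicts.  Models are not mutually exclusive, so the report is a
verdict *set*; the slope feature can only mark one of the surviving models as
favored (mediation attenuates a subtype's effects, pleiotropy does not).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bias import predict_sign_pattern

MODELS = ("a", "b", "c", "d")

#: feature states
POS, NEG, NULL, UNINFORMATIVE = "+", "-", "0", "?"


@dataclass
class ObservedSigns:
    """Observed association pattern with per-feature provenance.

    ``case_only`` is the direction of the case-only SNP-taxon association
    ("+", "-", "0" when compatible with no association, or "?" when the data
    cannot tell); ``concordance`` the sign of the panel concordance
    correlation; ``slope`` "<1", ">=1" or "?" for the subset-vs-full slope.
    ``taxon_disease`` is recorded for completeness but does not discriminate
    between the models (all four predict the observed direction).
    """

    case_only: str = UNINFORMATIVE
    concordance: str = UNINFORMATIVE
    slope: str = "?"
    taxon_disease: str = UNINFORMATIVE
    provenance: dict = field(default_factory=dict)


def classify_two_stage(z_discovery: float, z_replication: Optional[float],
                       alpha_persistent: float = 1e-3,
                       z_null: float = 1.28) -> str:
    """Three-way call for a two-stage association statistic.

    * persistent sign: same direction in both stages and pooled |z| beyond the
      two-sided ``alpha_persistent`` quantile;
    * null: pooled |z| below ``z_null`` or stage signs disagree;
    * otherwise uninformative (suggestive but unreplicated).

    With no replication stage the discovery z alone is used and the
    same-direction requirement is vacuous.
    """
    if z_replication is None or not np.isfinite(z_replication):
        pooled = z_discovery
        same_sign = True
    else:
        pooled = (z_discovery + z_replication) / np.sqrt(2.0)
        same_sign = np.sign(z_discovery) == np.sign(z_replication)
    z_crit = stats.norm.ppf(1.0 - alpha_persistent / 2.0)
    if same_sign and abs(pooled) > z_crit:
        return POS if pooled > 0 else NEG
    if abs(pooled) < z_null or not same_sign:
        return NULL
    return UNINFORMATIVE


def collect_observed(beta_g_discovery=None, beta_g_replication=None,
                     concordance_result=None, slope_test=None,
                     beta_b=None, alpha_persistent: float = 1e-3,
                     alpha_feature: float = 0.01,
                     slope_informative: bool = False,
                     z_discovery: Optional[float] = None,
                     z_replication: Optional[float] = None) -> ObservedSigns:
    """Reduce pipeline outputs to an observed sign pattern.

    ``beta_g_discovery`` / ``beta_g_replication`` are per-taxon case-only
    SNP-taxon coefficients from the two stages (the panel-level direction is
    the mean effect tested against zero, echoing a directional-enrichment
    read-out); explicit ``z_discovery`` / ``z_replication`` override that
    mean statistic, e.g. with a Stouffer combination of the candidate
    associations' Wald z-scores; ``concordance_result`` is a
    :class:`casebias.meta.ConcordanceResult`; ``slope_test`` a
    :class:`casebias.meta.SlopeTest`, consulted only when
    ``slope_informative`` is set (the genetic effect must be known to
    concentrate in one subtype for the slope to discriminate mediation from
    pleiotropy).  Missing inputs leave their slots uninformative.
    """
    obs = ObservedSigns()
    z1 = z_discovery
    if z1 is None and beta_g_discovery is not None and len(beta_g_discovery) > 0:
        disc = np.asarray(beta_g_discovery, dtype=float)
        disc = disc[np.isfinite(disc)]
        z1 = disc.mean() / (disc.std(ddof=1) / np.sqrt(disc.size))
    z2 = z_replication
    if z2 is None and beta_g_replication is not None and len(beta_g_replication) > 0:
        rep = np.asarray(beta_g_replication, dtype=float)
        rep = rep[np.isfinite(rep)]
        z2 = rep.mean() / (rep.std(ddof=1) / np.sqrt(rep.size))
    if z1 is not None and np.isfinite(z1):
        obs.case_only = classify_two_stage(float(z1), z2, alpha_persistent)
        obs.provenance["case_only"] = {
            "z_discovery": float(z1),
            "z_replication": None if z2 is None else float(z2)}
    if concordance_result is not None:
        if concordance_result.p < alpha_feature:
            obs.concordance = POS if concordance_result.correlation > 0 else NEG
        else:
            obs.concordance = UNINFORMATIVE
        obs.provenance["concordance"] = {
            "correlation": concordance_result.correlation,
            "p": concordance_result.p}
    if slope_test is not None and slope_informative:
        if slope_test.p < alpha_feature:
            obs.slope = "<1" if slope_test.slope < 1 else ">1"
        else:
            obs.slope = "?"
        obs.provenance["slope"] = {"slope": slope_test.slope, "p": slope_test.p}
    if beta_b is not None and len(beta_b) > 0:
        bb = np.asarray(beta_b, dtype=float)
        bb = bb[np.isfinite(bb)]
        if bb.size:
            zb = bb.mean() / (bb.std(ddof=1) / np.sqrt(bb.size))
            obs.taxon_disease = (POS if zb > 2 else NEG if zb < -2
                                 else UNINFORMATIVE)
    return obs


@dataclass
class ModelFitReport:
    """Consistency matrix, verdict set and narrative flags."""

    matrix: dict                 # model -> feature -> consistent/inconsistent/uninformative
    verdicts: set
    favored: Optional[str]
    flags: list
    observed: ObservedSigns

    def to_json(self) -> str:
        return json.dumps({
            "matrix": self.matrix,
            "verdicts": sorted(self.verdicts),
            "favored": self.favored,
            "flags": self.flags,
            "observed": {"case_only": self.observed.case_only,
                         "concordance": self.observed.concordance,
                         "slope": self.observed.slope,
                         "provenance": self.observed.provenance},
        }, indent=2)


def _feature_verdict(observed: str, expected: str) -> str:
    """Compare one observed feature state with a model's expectation."""
    if observed == UNINFORMATIVE:
        return "uninformative"
    return "consistent" if observed == expected else "inconsistent"


def score_models(observed: ObservedSigns,
                 models: Sequence[str] = MODELS) -> ModelFitReport:
    """Confront an observed sign pattern with each causal model.

    A model stays in the verdict set iff no informative feature contradicts
    its predicted pattern (canonical effect directions: risk allele positive
    on disease, bacterium protective).  A persistent negative case-only
    association is consistent with mediation (a) and pleiotropy (b) only; a
    positive one with independent-risk-factors (c); a null one with reverse
    causation (d).  The concordance correlation separates {a, b} (+) from c
    (-) and d (0); a subtype slope below 1, when informative, favors
    mediation over pleiotropy among the surviving models.
    """
    informative = [f for f in (observed.case_only, observed.concordance)
                   if f != UNINFORMATIVE]
    if not informative and observed.slope == "?":
        raise ValueError("no informative observed feature")
    matrix: dict = {}
    verdicts = set()
    for m in models:
        pattern = predict_sign_pattern(m)
        row = {
            "case_only": _feature_verdict(observed.case_only, pattern.case_only),
            "concordance": _feature_verdict(observed.concordance,
                                            pattern.panel_corr),
        }
        matrix[m] = row
        if all(v != "inconsistent" for v in row.values()):
            verdicts.add(m)
    favored = None
    flags = []
    if observed.slope == "<1" and "a" in verdicts:
        favored = "a"
        flags.append("subtype slope below 1: attenuation consistent with "
                     "mediation; favors model a over model b")
    if verdicts <= {"a", "b"} and verdicts:
        flags.append("persistent case-only association: selection bias ruled "
                     "out as sole explanation")
    if not verdicts:
        flags.append("no model consistent with all informative features")
    return ModelFitReport(matrix=matrix, verdicts=verdicts, favored=favored,
                          flags=flags, observed=observed)
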