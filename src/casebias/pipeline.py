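"""End-to-end pipeline: filter -> INT -> associations -> meta -> inference.

The stages mirror a discovery analysis: the taxon table is prevalence
filtered and rank-INT transformed; each locus is regressed against each taxon
in cases (with confounders and same-rank covariates) and across subtype
strata; per-rank Bonferroni flags candidates; when controls exist, per-taxon
case-control logistic effects support the enrichment/concordance read-outs;
and the observed sign pattern is confronted with the four causal models.
Every output embeds the config hash and seed; a stage log records the
filtering funnel.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as A
from . import meta as M
from .io import RunConfig, ValidationError, read_abundance, read_genotypes_metadata
from .modelfit import collect_observed, score_models
from .synthetic import DEFAULT_LOCI

log = logging.getLogger("casebias.pipeline")


def _locus_table(config: RunConfig) -> dict:
    out = {}
    for gene, variants in config.loci.items():
        freqs = dict(DEFAULT_LOCI).get(gene, (None, None))[1]
        out[gene] = (list(variants), freqs)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report bundle (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    table = read_abundance(config.abundance)
    cohort = read_genotypes_metadata(config.genotypes, config.metadata,
                                     loci=_locus_table(config))
    missing_meta = [c for c in config.confounders + ["d", "subtype", "ileal"]
                    if c not in cohort.metadata.columns]
    if missing_meta:
        raise ValidationError(f"metadata lacks columns {missing_meta}")
    shared = table.values.index.intersection(cohort.metadata.index)
    if len(shared) == 0:
        raise ValidationError("no overlap between abundance and metadata samples")
    values = table.values.loc[shared]
    meta_df = cohort.metadata.loc[shared]
    cases = meta_df["d"] == 1
    log.info("stage read: %d samples (%d cases), %d taxa",
             len(shared), int(cases.sum()), values.shape[1])

    # ---- filter + transform (within cases, the analyzed sample) -----------
    ranks = {t: table.taxonomy.nodes[t].rank for t in values.columns}
    processed = A.filter_taxa(values.loc[cases], ranks,
                              min_nonzero_frac=config.filter_threshold)
    log.info("stage filter: %d taxa in, %d retained, %d dropped",
             values.shape[1], len(processed.retained), len(processed.dropped))

    Z = meta_df.loc[cases, config.confounders].astype(float)
    z_ok = Z.notna().all(axis=1)
    if (~z_ok).any():
        log.info("stage filter: %d case samples dropped listwise for "
                 "missing confounders", int((~z_ok).sum()))

    # ---- per-locus associations ------------------------------------------
    all_results = []
    enrich = {}
    per_locus_betas = {}
    for gene in config.loci:
        genotype = cohort.locus_dosage(gene, config.coding).loc[shared]
        g_cases = genotype[cases]
        if g_cases.std() == 0:
            log.warning("locus %s constant among cases; skipped", gene)
            continue
        locus_results = []
        for tid in processed.retained:
            y = processed.transformed[tid].to_numpy()
            C = None
            if config.use_covariate_search:
                peers = [t for t in processed.retained
                         if t != tid and processed.ranks[t] == processed.ranks[tid]]
                chosen = A.select_level_covariates(
                    y, processed.transformed[peers], g_cases.to_numpy(),
                    max_k=config.max_covariates)
                C = processed.transformed[chosen] if chosen else None
            res = A.fit_snp_taxon(y, g_cases.to_numpy(), Z, C, stratum="IBD",
                                  taxon=tid, predictor=gene,
                                  rank=processed.ranks[tid])
            locus_results.append(res)
        A.per_level_bonferroni(locus_results, alpha=config.alpha)
        strata_extra = [s for s in config.strata if s != "IBD"]
        locus_results += A.stratified_analysis(
            processed.transformed, g_cases, meta_df.loc[cases],
            processed.ranks, Z=Z, strata=strata_extra, predictor=gene)
        all_results.extend(locus_results)
        betas = np.array([r.beta for r in locus_results
                          if r.stratum == "IBD" and not r.missing])
        per_locus_betas[gene] = betas
        if betas.size:
            enr = M.sign_enrichment(betas, "negative")
            enrich[gene] = {"n_negative": enr.n_direction,
                            "n_total": enr.n_total, "p": enr.p}
    assoc_df = A.results_frame(all_results)
    for k, v in stamp.items():
        assoc_df[k] = v
    assoc_df.to_csv(outdir / "assoc.tsv", sep="\t", index=False, na_rep="NA")

    # ---- case-control taxon-disease effects ------------------------------
    beta_b = None
    if (meta_df["d"] == 0).any():
        cc_results = []
        for tid in processed.retained:
            y_all = A.rank_int(values[tid].to_numpy()) \
                if np.unique(values[tid]).size > 2 else None
            if y_all is None:
                cc_results.append(np.nan)
                continue
            res = A.fit_taxon_disease(y_all, meta_df["d"].to_numpy(),
                                      taxon=tid, rank=processed.ranks[tid])
            cc_results.append(np.nan if res.missing else res.beta)
        beta_b = np.asarray(cc_results)

    # ---- meta-analysis against optional replication TSVs ------------------
    meta_rows = []
    pooled_by_locus = {}
    if config.replication_assoc:
        rep_frames = [pd.read_csv(p, sep="\t") for p in config.replication_assoc]
        disc = assoc_df[(assoc_df["stratum"] == "IBD")
                        & (~assoc_df["missing"].astype(bool))]
        for _, row in disc.iterrows():
            studies = [(row["beta"], row["se"])]
            for rf in rep_frames:
                hit = rf[(rf["taxon"] == row["taxon"])
                         & (rf["predictor"] == row["predictor"])
                         & (rf["stratum"] == "IBD")]
                if len(hit):
                    studies.append((float(hit["beta"].iloc[0]),
                                    float(hit["se"].iloc[0])))
            if len(studies) > 1:
                pooled = M.inverse_variance_meta(studies)
                meta_rows.append({"taxon": row["taxon"],
                                  "predictor": row["predictor"],
                                  "beta": pooled.beta, "se": pooled.se,
                                  "p": pooled.p, "n_studies": pooled.n_studies})
                pooled_by_locus.setdefault(row["predictor"], []).append(pooled.beta)
        if meta_rows:
            mdf = pd.DataFrame(meta_rows)
            for k, v in stamp.items():
                mdf[k] = v
            mdf.to_csv(outdir / "meta.tsv", sep="\t", index=False, na_rep="NA")

    # ---- concordance + model fit -----------------------------------------
    conc = None
    if beta_b is not None and per_locus_betas:
        tables = [per_locus_betas[g] for g in per_locus_betas
                  if per_locus_betas[g].size == beta_b.size]
        finite = beta_b[np.isfinite(beta_b)]
        if tables and finite.size >= 3:
            conc = M.concordance(tables, beta_b, n_perm=2_000, seed=config.seed)

    disc_betas = np.concatenate(list(per_locus_betas.values())) \
        if per_locus_betas else np.array([])
    rep_betas = None
    if pooled_by_locus:
        rep_betas = np.concatenate([np.asarray(v) for v in pooled_by_locus.values()])
    # the case-only direction is judged on the candidate associations when
    # any exist (a Stouffer combination of their Wald z-scores); the all-taxa
    # mean is the fallback — compositional closure makes per-taxon signs of
    # null taxa drift when a dominant taxon carries a real effect
    candidates = [r for r in all_results
                  if r.stratum == "IBD" and r.candidate and not r.missing
                  and np.isfinite(r.se) and r.se > 0]
    z_disc = None
    if candidates:
        z_disc = float(sum(r.beta / r.se for r in candidates)
                       / np.sqrt(len(candidates)))
    observed = collect_observed(beta_g_discovery=disc_betas,
                                beta_g_replication=rep_betas,
                                concordance_result=conc, beta_b=beta_b,
                                z_discovery=z_disc)
    if candidates:
        observed.provenance.setdefault("case_only", {})["n_candidates"] = \
            len(candidates)
    try:
        report = score_models(observed)
        verdict = {"verdicts": sorted(report.verdicts), "favored": report.favored,
                   "matrix": report.matrix, "flags": report.flags}
    except ValueError:
        verdict = {"verdicts": [], "favored": None, "matrix": {},
                   "flags": ["no informative observed feature"]}

    bundle = {
        **stamp,
        "n_samples": int(len(shared)), "n_cases": int(cases.sum()),
        "taxa_in": int(values.shape[1]),
        "taxa_retained": len(processed.retained),
        "taxa_dropped": int(len(processed.dropped)),
        "enrichment": enrich,
        "concordance": None if conc is None else
            {"correlation": conc.correlation, "p": conc.p},
        "observed": {"case_only": observed.case_only,
                     "concordance": observed.concordance,
                     "provenance": observed.provenance},
        "model_fit": verdict,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
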