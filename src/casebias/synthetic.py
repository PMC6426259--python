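"""Synthetic study data with the statistical structure of an IBD microbiome cohort.

Emulates the discovery design: ~182 IBD cases (CD/UC, ileal or not, flare or
remission, under various treatments) plus ~38 controls, genotypes at four IBD
risk loci, and a 168-taxon relative-abundance table over six nested ranks with
negative-binomial counts, per-taxon zero inflation and hierarchy-induced
correlation.

Counts are generated at the finest annotated level: every taxon owns an
"unassigned below" mass component (a pseudo-taxon per node, which is the whole
mass for nodes without children) drawn from a negative binomial whose
dispersion is tuned to a per-taxon zero-fraction target; totals aggregate
upward, so a child's abundance never exceeds its parent's and parent-child
correlations arise by construction.  A root-level "unknown" component leaves
per-rank sums below 1, mimicking unassigned reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._fast import standardize_pop
from .models import CausalModelSpec, nb_size_for_zero_frac
from .taxonomy import RANKS, Taxonomy, build_taxonomy

#: Marginal covariate frequencies of the discovery cohort (Total column).
TABLE1_FREQUENCIES = {
    "female": 105 / 182,
    "cd": 115 / 182,          # CD vs UC among cases
    "ileal_given_cd": 0.60,   # ileal involvement among CD; cohort papers' range
    "flare": 0.462,
    "smoking": 0.214,
    "treat_5asa": 0.385,
    "treat_corticosteroids": 0.187,
    "treat_antitnf": 0.495,
    "treat_thiopurine_mtx": 0.385,
}

MEAN_AGE = 40.6
SD_AGE = 12.0
MIN_AGE = 18.0

#: Default risk loci: (gene, variant ids, risk-allele frequencies).
DEFAULT_LOCI = {
    "ATG16L1": (["rs12994997"], [0.55]),
    "CARD9": (["rs10781499"], [0.58]),
    "LRRK2": (["rs11564258"], [0.02]),
    "NOD2": (["rs2066844", "rs2066845", "rs2066847"], [0.04, 0.01, 0.02]),
}

TREATMENT_COLUMNS = ["treat_5asa", "treat_corticosteroids", "treat_antitnf",
                     "treat_thiopurine_mtx"]


@dataclass
class TaxonTable:
    """Samples x taxa relative abundances over a six-rank taxonomy.

    ``values`` has samples as rows and taxon ids as columns, entries in [0,1].
    Synthetic tables additionally carry the generating leaf-count state so a
    causal shift can be embedded and the hierarchy re-aggregated.
    """

    values: pd.DataFrame
    taxonomy: Taxonomy
    _own_counts: Optional[pd.DataFrame] = None   # per-node unassigned-below mass
    _own_meta: Optional[pd.DataFrame] = None     # per-node NB mean and size
    _unknown: Optional[np.ndarray] = None        # root-level unknown mass

    def __post_init__(self):
        vals = self.values.to_numpy()
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("relative abundances must lie in [0, 1]")
        unknown = set(self.values.columns) - set(self.taxonomy.nodes)
        if unknown:
            raise ValueError(f"taxa absent from taxonomy: {sorted(unknown)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def rank_of(self, taxon_id: str) -> str:
        return self.taxonomy.nodes[taxon_id].rank

    def check_hierarchy(self, atol: float = 1e-9) -> None:
        """Raise unless child sums never exceed parents and rank sums <= 1."""
        for tid in self.values.columns:
            kids = [k for k in self.taxonomy.children(tid)
                    if k in self.values.columns]
            if kids:
                excess = (self.values[kids].sum(axis=1)
                          - self.values[tid]).max()
                if excess > atol:
                    raise AssertionError(
                        f"children of {tid} exceed parent by {excess:.3g}")
        for rank in RANKS:
            cols = [t for t in self.values.columns if self.rank_of(t) == rank]
            if cols and (self.values[cols].sum(axis=1) > 1 + atol).any():
                raise AssertionError(f"rank {rank} sums exceed 1")


def _aggregate(taxonomy: Taxonomy, own: pd.DataFrame,
               unknown: np.ndarray) -> pd.DataFrame:
    """Node totals (own mass + descendants), scaled to per-sample proportions."""
    totals = own.copy()
    for rank in reversed(RANKS[:-1]):
        for tid in taxonomy.ids_at_rank(rank):
            kids = taxonomy.children(tid)
            if kids:
                totals[tid] = totals[tid] + totals[kids].sum(axis=1)
    grand = totals[taxonomy.ids_at_rank("phylum")].sum(axis=1) + unknown
    grand = grand.replace(0, np.nan) if isinstance(grand, pd.Series) else grand
    props = totals.div(grand, axis=0).fillna(0.0)
    return props


def sample_abundance_table(taxonomy: Taxonomy, n_samples: int,
                           target_zero_fracs=None, dispersion: float = None,
                           depth: int = 10_000, seed: int = 0,
                           sample_prefix: str = "S") -> TaxonTable:
    """Negative-binomial abundance table over a taxonomy.

    Parameters
    ----------
    target_zero_fracs:
        Scalar in [0, 0.95] or mapping taxon id -> target zero fraction of the
        taxon's own-mass component; dispersion is solved per taxon from the NB
        zero-probability equation (clamped with a warning when the target lies
        below the Poisson floor of the taxon's mean).  ``None`` draws targets
        uniformly in [0, 0.8], mirroring the observed sparsity profile.
    dispersion:
        When given, a fixed NB size parameter for every taxon (overrides the
        zero-fraction targeting).
    depth:
        Expected total count per sample (the rarefaction depth being emulated).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(taxonomy.nodes)
    n_taxa = len(ids)

    if target_zero_fracs is None:
        zf = dict(zip(ids, rng.uniform(0.0, 0.8, n_taxa)))
    elif np.isscalar(target_zero_fracs):
        zf = {tid: float(target_zero_fracs) for tid in ids}
    else:
        zf = {tid: float(target_zero_fracs.get(tid, 0.3)) for tid in ids}
    bad = [t for t, z in zf.items() if not 0.0 <= z <= 0.95]
    if bad:
        raise ValueError(f"zero-fraction targets outside [0, 0.95]: {bad[:5]}")

    # heterogeneous own-mass means on a log scale, normalized to the depth
    raw_means = np.exp(rng.normal(0.0, 1.5, n_taxa))
    raw_means *= depth / raw_means.sum()
    raw_means = np.maximum(raw_means, 0.5)

    sizes = np.empty(n_taxa)
    clamped = []
    for j, tid in enumerate(ids):
        if dispersion is not None:
            sizes[j] = dispersion
        else:
            sizes[j], was_clamped = nb_size_for_zero_frac(raw_means[j], zf[tid])
            if was_clamped:
                clamped.append(tid)
    if clamped:
        warnings.warn(
            f"zero-fraction target unreachable for {len(clamped)} taxa at "
            f"their means; clamped to the Poisson floor", stacklevel=2)

    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    p = sizes / (sizes + raw_means)
    counts = rng.negative_binomial(sizes, p, size=(n_samples, n_taxa)).astype(float)
    own = pd.DataFrame(counts, index=samples, columns=ids)
    unknown = rng.negative_binomial(10.0, 10.0 / (10.0 + 0.15 * depth),
                                    size=n_samples).astype(float)
    props = _aggregate(taxonomy, own, unknown)
    meta = pd.DataFrame({"mean": raw_means, "size": sizes}, index=ids)
    return TaxonTable(values=props, taxonomy=taxonomy, _own_counts=own,
                      _own_meta=meta, _unknown=unknown)


@dataclass
class CohortData:
    """Host covariates, disease labels and genotypes for one cohort.

    ``metadata`` rows are samples; columns include disease status ``d``,
    ``subtype`` (CD/UC, only for cases), ``ileal``/``flare`` flags, ``sex``,
    ``age``, ``smoking`` and the four treatment flags (cases only; ``NA`` for
    controls).  ``genotypes`` holds allele-dosage columns per variant.
    """

    metadata: pd.DataFrame
    genotypes: pd.DataFrame
    loci: dict = field(default_factory=lambda: dict(DEFAULT_LOCI))

    def __post_init__(self):
        if not self.metadata.index.equals(self.genotypes.index):
            raise ValueError("metadata and genotype sample ids differ")
        cases = self.metadata["d"] == 1
        if self.metadata.loc[~cases, "subtype"].notna().any():
            raise ValueError("subtype defined for a control")
        geno = self.genotypes.to_numpy(dtype=float)
        finite = geno[np.isfinite(geno)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("genotype dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.index)

    def locus_dosage(self, locus: str, coding: str = "carrier") -> pd.Series:
        """Composite genotype for a locus: carrier 0/1 or summed dosage."""
        variants, _ = self.loci[locus]
        block = self.genotypes[variants]
        if coding == "carrier":
            return (block.sum(axis=1) > 0).astype(float).rename(locus)
        if coding == "dosage":
            return block.sum(axis=1).rename(locus)
        raise ValueError(f"unknown genotype coding {coding!r}")


def sample_host_data(n_cases: int = 182, n_controls: int = 38,
                     frequency_table: Optional[dict] = None, seed: int = 0,
                     loci: Optional[dict] = None,
                     control_genotypes: bool = True) -> CohortData:
    """Host covariates and genotypes at the discovery cohort's frequencies.

    Binary covariates are drawn independently at the Table-1-style marginal
    frequencies; age is normal around 40.6 (SD 12, truncated at 18).
    Controls carry no treatment flags; their genotypes are generated unless
    ``control_genotypes`` is False (the real controls lacked SNP data).
    """
    freqs = dict(TABLE1_FREQUENCIES)
    if frequency_table:
        unknown = set(frequency_table) - set(freqs)
        if unknown:
            raise ValueError(f"unknown covariate frequencies: {sorted(unknown)}")
        freqs.update(frequency_table)
    bad = {k: v for k, v in freqs.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"frequencies outside [0, 1]: {bad}")
    loci = dict(DEFAULT_LOCI) if loci is None else dict(loci)
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    ids = [f"S{i + 1:04d}" for i in range(n)]
    d = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]

    age = rng.normal(MEAN_AGE, SD_AGE, n)
    while (age < MIN_AGE).any():
        redo = age < MIN_AGE
        age[redo] = rng.normal(MEAN_AGE, SD_AGE, redo.sum())

    meta = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    meta["d"] = d
    meta["sex"] = (rng.random(n) < freqs["female"]).astype(int)  # 1 = female
    meta["age"] = np.round(age, 1)
    meta["smoking"] = (rng.random(n) < freqs["smoking"]).astype(int)
    is_cd = rng.random(n) < freqs["cd"]
    subtype = np.where(is_cd, "CD", "UC").astype(object)
    subtype[d == 0] = None
    meta["subtype"] = subtype
    ileal = (rng.random(n) < freqs["ileal_given_cd"]).astype(float)
    ileal[~((d == 1) & (subtype == "CD"))] = 0.0
    meta["ileal"] = ileal.astype(int)
    flare = (rng.random(n) < freqs["flare"]).astype(float)
    flare[d == 0] = np.nan
    meta["flare"] = flare
    for col in TREATMENT_COLUMNS:
        flags = (rng.random(n) < freqs[col]).astype(float)
        flags[d == 0] = np.nan
        meta[col] = flags

    geno = pd.DataFrame(index=meta.index)
    for gene, (variants, fs) in loci.items():
        for rsid, f in zip(variants, fs):
            geno[rsid] = rng.binomial(2, f, n).astype(float)
    if not control_genotypes:
        geno.loc[meta["d"] == 0, :] = np.nan
    return CohortData(metadata=meta, genotypes=geno, loci=loci)


def embed_causal_structure(table: TaxonTable, cohort: CohortData,
                           assignments: dict, seed: int = 0) -> CohortData:
    """Regenerate disease status (and assigned taxa) under causal models.

    ``assignments`` maps taxon id -> ``(locus, CausalModelSpec)``; at most one
    model per taxon.  For models a/b the assigned taxon's subtree counts are
    redrawn with a log-link genotype shift, disease is then drawn from the
    joint logistic; for model d disease is drawn first and the subtree shifted
    by the standardized status.  Unassigned taxa remain independent of disease
    and genotype.  The expected case fraction is kept at the cohort's original
    one.  ``table.values`` is updated in place.
    """
    if table._own_counts is None:
        raise ValueError("table lacks generator state; use a synthetic table")
    for tid in assignments:
        if tid not in table.values.columns:
            raise ValueError(f"assigned taxon {tid} not in table")
    rng = np.random.default_rng(seed)
    meta = cohort.metadata.copy()
    n = len(meta)
    target_prev = float((meta["d"] == 1).mean())

    def subtree(tid):
        out = [tid]
        for kid in table.taxonomy.children(tid):
            out.extend(subtree(kid))
        return out

    def redraw(tid, shift):
        for node in subtree(tid):
            mean0, size = table._own_meta.loc[node, ["mean", "size"]]
            mean = mean0 * np.exp(shift)
            p = size / (size + mean)
            table._own_counts[node] = rng.negative_binomial(
                size, p, size=n).astype(float)

    # stage 1: genotype -> bacterium shifts (models a and b)
    for tid, (locus, spec) in assignments.items():
        if spec.model_id in ("a", "b") and spec.beta != 0.0:
            G = standardize_pop(cohort.locus_dosage(locus).to_numpy())
            redraw(tid, spec.beta * G)
    table.values = _aggregate(table.taxonomy, table._own_counts, table._unknown)

    # stage 2: disease from the joint logistic over all a/b/c/d contributions
    eta = np.zeros(n)
    for tid, (locus, spec) in assignments.items():
        G = standardize_pop(cohort.locus_dosage(locus).to_numpy())
        if spec.model_id in ("a", "c"):
            vals = table.values[tid].to_numpy()
            if vals.std() > 0:
                eta += spec.omega_b * standardize_pop(vals)
        if spec.model_id in ("b", "c", "d"):
            eta += spec.omega_g * G
    base = np.log(target_prev / (1.0 - target_prev))
    from scipy import optimize as _opt
    w0 = _opt.brentq(
        lambda w: np.mean(1.0 / (1.0 + np.exp(-(w + eta)))) - target_prev,
        base - 12, base + 12) if eta.any() else base
    d = rng.binomial(1, 1.0 / (1.0 + np.exp(-(w0 + eta))))
    if d.sum() in (0, n):
        raise RuntimeError("degenerate disease draw; adjust effects or n")

    # stage 3: disease -> bacterium shifts (model d)
    D = standardize_pop(d.astype(float))
    for tid, (locus, spec) in assignments.items():
        if spec.model_id == "d" and spec.gamma != 0.0:
            redraw(tid, spec.gamma * D)
    table.values = _aggregate(table.taxonomy, table._own_counts, table._unknown)

    meta["d"] = d
    subtype = meta["subtype"].astype(object)
    new_cd = np.asarray(rng.random(n) < TABLE1_FREQUENCIES["cd"])
    refresh = (d == 1) & subtype.isna().to_numpy()
    subtype[refresh] = np.where(new_cd[refresh], "CD", "UC")
    subtype[d == 0] = None
    meta["subtype"] = subtype
    for col in TREATMENT_COLUMNS + ["flare"]:
        vals = meta[col].to_numpy(dtype=float)
        fill = (d == 1) & ~np.isfinite(vals)
        vals[fill] = (rng.random(fill.sum()) < TABLE1_FREQUENCIES[
            col if col in TABLE1_FREQUENCIES else "flare"]).astype(float)
        vals[d == 0] = np.nan
        meta[col] = vals
    return CohortData(metadata=meta, genotypes=cohort.genotypes, loci=cohort.loci)
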