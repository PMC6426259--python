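"""TSV readers/writers and run configuration.

All tables are plain UTF-8 TSV with ``NA`` for missing values and a
deterministic column order, so fixtures stay diffable and round-trips are
bit-exact.  The abundance format has taxa as rows (``taxon_id``, ``rank``,
``lineage`` columns, then one column per sample); genotypes and metadata have
samples as rows.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .synthetic import DEFAULT_LOCI, CohortData, TaxonTable
from .taxonomy import RANKS, Taxonomy, TaxonNode

NA = "NA"


class ValidationError(ValueError):
    """Malformed input file or configuration."""


def write_abundance(table: TaxonTable, path) -> None:
    """Write a taxa-as-rows abundance TSV with rank and lineage columns."""
    path = Path(path)
    tax = table.taxonomy
    rows = pd.DataFrame({
        "taxon_id": list(table.values.columns),
        "rank": [tax.nodes[t].rank for t in table.values.columns],
        "lineage": [tax.lineage_string(t) for t in table.values.columns],
    })
    values = table.values.T
    values.columns = table.sample_ids
    out = pd.concat([rows.set_index(pd.Index(table.values.columns)),
                     values], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.17g")


def read_abundance(path) -> TaxonTable:
    """Read and validate an abundance TSV into a :class:`TaxonTable`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=[NA],
                     float_precision="round_trip")
    for col in ("taxon_id", "rank", "lineage"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    if df["taxon_id"].duplicated().any():
        dupes = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise ValidationError(f"{path.name}: duplicate taxon ids {dupes[:5]}")
    bad_rank = sorted(set(df["rank"]) - set(RANKS))
    if bad_rank:
        raise ValidationError(f"{path.name}: unknown rank labels {bad_rank}")
    sample_cols = [c for c in df.columns
                   if c not in ("taxon_id", "rank", "lineage")]
    vals = df[sample_cols].to_numpy(dtype=float)
    bad = np.argwhere((vals < 0) | (vals > 1))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path.name}: value {vals[i, j]!r} outside [0, 1] at line "
            f"{i + 2}, taxon {df['taxon_id'].iloc[i]!r}, "
            f"sample {sample_cols[j]!r}")

    nodes: dict[str, TaxonNode] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        lineage = str(row.lineage).split("|")
        if lineage[-1] != row.taxon_id:
            raise ValidationError(
                f"{path.name} line {line_no}: lineage does not end "
                f"in taxon_id {row.taxon_id!r}")
        if len(lineage) != RANKS.index(row.rank) + 1:
            raise ValidationError(
                f"{path.name} line {line_no}: lineage depth does not match "
                f"rank {row.rank!r}")
        for depth, tid in enumerate(lineage):
            parent = lineage[depth - 1] if depth else None
            node = TaxonNode(taxon_id=tid, rank=RANKS[depth],
                             parent=parent, name=tid)
            if tid in nodes and nodes[tid] != node:
                raise ValidationError(
                    f"{path.name} line {line_no}: conflicting lineage for {tid!r}")
            nodes[tid] = node
    taxonomy = Taxonomy(nodes)
    values = pd.DataFrame(vals.T, index=pd.Index(sample_cols, name="sample_id"),
                          columns=df["taxon_id"].tolist())
    return TaxonTable(values=values, taxonomy=taxonomy)


def write_genotypes(cohort: CohortData, path) -> None:
    cohort.genotypes.to_csv(path, sep="\t", na_rep=NA, float_format="%.17g")


def write_metadata(cohort: CohortData, path) -> None:
    cohort.metadata.to_csv(path, sep="\t", na_rep=NA, float_format="%.17g")


def write_cohort(table: TaxonTable, cohort: CohortData, outdir) -> dict:
    """Write the three cohort TSVs; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"abundance": outdir / "abundance.tsv",
             "genotypes": outdir / "genotypes.tsv",
             "metadata": outdir / "metadata.tsv"}
    write_abundance(table, paths["abundance"])
    write_genotypes(cohort, paths["genotypes"])
    write_metadata(cohort, paths["metadata"])
    return paths


def read_genotypes_metadata(genotypes_path, metadata_path,
                            loci: Optional[dict] = None) -> CohortData:
    """Join genotype and metadata TSVs into a :class:`CohortData`.

    Samples present in only one file are dropped with a warning; non-biallelic
    dosage codes raise.  Composite loci (e.g. the three-variant NOD2 carrier
    state) are resolved later through ``CohortData.locus_dosage``.
    """
    geno = pd.read_csv(genotypes_path, sep="\t", index_col=0, na_values=[NA],
                       float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, na_values=[NA],
                       float_precision="round_trip")
    finite = geno.to_numpy(dtype=float)
    finite = finite[np.isfinite(finite)]
    if finite.size and (np.any(finite < 0) or np.any(finite > 2)
                        or np.any(finite != np.round(finite))):
        raise ValidationError("genotype dosages must be integers in {0, 1, 2}")
    shared = meta.index.intersection(geno.index)
    dropped = (len(meta) - len(shared)) + (len(geno) - len(shared))
    if dropped:
        warnings.warn(f"dropped {dropped} unmatched sample rows across "
                      "genotypes/metadata", stacklevel=2)
    if len(shared) == 0:
        raise ValidationError("no overlapping samples between genotypes and metadata")
    loci = dict(DEFAULT_LOCI) if loci is None else dict(loci)
    for gene, (variants, _) in loci.items():
        missing = [v for v in variants if v not in geno.columns]
        if missing:
            raise ValidationError(
                f"locus {gene}: variant columns {missing} absent from genotypes")
    meta = meta.loc[shared]
    if "subtype" in meta.columns:
        meta["subtype"] = meta["subtype"].where(meta["subtype"].notna(), None)
    return CohortData(metadata=meta, genotypes=geno.loc[shared], loci=loci)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flat YAML on disk)."""

    abundance: str
    genotypes: str
    metadata: str
    outdir: str = "results/run"
    loci: dict = field(default_factory=lambda: {
        g: list(v[0]) for g, v in DEFAULT_LOCI.items()})
    coding: str = "carrier"
    confounders: list = field(default_factory=lambda: [
        "sex", "age", "smoking", "treat_5asa", "treat_corticosteroids",
        "treat_antitnf", "treat_thiopurine_mtx"])
    filter_threshold: float = 0.20
    int_offset: float = 0.375
    strata: list = field(default_factory=lambda: ["IBD", "CD", "CDil",
                                                  "CDni", "UC"])
    alpha: float = 0.05
    multiplicity: str = "per-rank-bonferroni"
    max_covariates: int = 5
    use_covariate_search: bool = True
    seed: int = 0
    replication_assoc: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k)
                            for k in self.__dataclass_fields__}, fh,
                           sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump({k: getattr(self, k)
                               for k in self.__dataclass_fields__},
                              sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
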