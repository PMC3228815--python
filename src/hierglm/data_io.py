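"""Readers, writers and preprocessing for genotype/phenotype data.

Formats
-------
* Genotype TSV: header row of variant ids, first column ``sample_id``,
  cells in {0, 1, 2, NA} (reals after imputation).
* VCF 4.x (biallelic sites, GT field) via cyvcf2.
* Group map TSV: columns ``variant_id``, ``group``.
* Prior-means TSV: columns ``variant_id``, ``mu``.
* Phenotype TSV: ``sample_id``, ``y``, then covariate columns.

Dosages are additive minor-allele counts.  The minor allele is determined
per variant from the observed allele frequency (ties: ALT is minor).  MAFs
are computed on observed entries only; mean imputation preserves them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "ModelFrame",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_groups",
    "write_groups",
    "read_prior_means",
    "impute_mean",
    "classify_by_maf",
    "drop_non_segregating",
    "build_model_frame",
]


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosages with per-variant metadata."""

    dosages: pd.DataFrame                    # NaN marks missing
    groups: pd.Series | None = None          # variant id -> group label
    prior_means: pd.Series | None = None     # variant id -> mu_j
    maf_class: pd.Series | None = None       # 'common' / 'rare'

    def __post_init__(self):
        self.dosages = pd.DataFrame(self.dosages).astype(float)
        vals = self.dosages.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.dosages.columns.duplicated().any():
            dup = self.dosages.columns[self.dosages.columns.duplicated()]
            raise ValueError(f"duplicate variant ids: {list(dup)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.dosages.isna()

    @property
    def maf(self) -> pd.Series:
        """Minor allele frequency per variant, from observed entries only."""
        freq = self.dosages.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            None if self.groups is None else self.groups.copy(),
            None if self.prior_means is None else self.prior_means.copy(),
            None if self.maf_class is None else self.maf_class.copy(),
        )


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF (format guessed from suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" or \
            path.name.lower().endswith(".vcf.gz") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col="sample_id",
                         na_values=["NA"], float_precision="round_trip")
        return GenotypeMatrix(df)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"non-biallelic VCF record {rec.ID or f'{rec.CHROM}:{rec.POS}'}")
        vid = rec.ID if rec.ID not in (None, ".") else \
            f"{rec.CHROM}_{rec.POS}_{rec.REF}_{rec.ALT[0]}"
        gt = np.asarray(rec.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        obs = dose[~np.isnan(dose)]
        if obs.size:
            alt_freq = float(obs.mean()) / 2.0
            if alt_freq > 0.5:  # REF is the minor allele; ties keep ALT minor
                dose = 2.0 - dose
                logger.info("variant %s: REF is minor, dosages flipped", vid)
        ids.append(vid)
        cols.append(dose)
    df = pd.DataFrame(np.column_stack(cols) if cols else np.empty((len(samples), 0)),
                      index=pd.Index(samples, name="sample_id"), columns=ids)
    return GenotypeMatrix(df)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    df = g.dosages.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_phenotype(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"],
                       float_precision="round_trip")


def write_phenotype(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "group"}.issubset(df.columns):
        raise ValueError("group map must have columns variant_id and group")
    return df.set_index("variant_id")["group"]


def write_groups(groups: pd.Series, path) -> None:
    df = groups.rename("group").to_frame()
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


def read_prior_means(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"variant_id", "mu"}.issubset(df.columns):
        raise ValueError("prior-means table must have columns variant_id and mu")
    return df.set_index("variant_id")["mu"].astype(float)


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with the observed mean of its variant."""
    fully_missing = g.dosages.columns[g.dosages.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"variants with no observed genotypes: {list(fully_missing)}")
    out = g.copy()
    out.dosages = g.dosages.fillna(g.dosages.mean(axis=0, skipna=True))
    return out


def classify_by_maf(g: GenotypeMatrix, threshold: float = 0.01) -> pd.Series:
    """Label variants 'rare' (MAF < threshold) or 'common' (MAF >= threshold)."""
    labels = pd.Series(np.where(g.maf < threshold, "rare", "common"),
                       index=g.variant_ids)
    g.maf_class = labels
    return labels


def drop_non_segregating(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove variants whose observed dosages have zero variance."""
    var = g.dosages.var(axis=0, skipna=True, ddof=0)
    keep = g.variant_ids[(var > 0).to_numpy()]
    dropped = [v for v in g.variant_ids if v not in set(keep)]
    if dropped:
        logger.info("dropping %d non-segregating variants: %s",
                    len(dropped), dropped)
    out = GenotypeMatrix(g.dosages[keep])
    for attr in ("groups", "prior_means", "maf_class"):
        val = getattr(g, attr)
        if val is not None:
            setattr(out, attr, val.reindex(keep))
    return out


# --------------------------------------------------------------------------
# model frame assembly
# --------------------------------------------------------------------------

@dataclass
class ModelFrame:
    """Aligned response, covariates, genotypes and grouping for one fit."""

    y: pd.Series
    covariates: pd.DataFrame
    genotypes: pd.DataFrame
    groups: dict[str, list[str]]
    prior_means: pd.Series
    family: str
    singletons: list[str] = field(default_factory=list)


def build_model_frame(g: GenotypeMatrix, pheno: pd.DataFrame,
                      groups: pd.Series | None = None,
                      prior_means: pd.Series | None = None,
                      family: str = "gaussian",
                      response: str = "y",
                      singleton_action: str = "covariate",
                      uncovered_action: str = "drop",
                      join: str = "strict") -> ModelFrame:
    """Assemble an aligned :class:`ModelFrame` for the grouped-variant fit.

    Samples are matched by id (never positionally).  ``join="strict"``
    errors on any mismatch; ``join="intersect"`` keeps the common ids and
    logs the drop.  Rows with missing covariates are dropped (logged).
    Categorical covariates are dummy-expanded against the alphabetically
    first level.  Variants not covered by ``groups`` are dropped or routed
    to covariates; groups of size 1 follow ``singleton_action``.
    """
    if groups is None:
        groups = g.groups
    if groups is None:
        raise ValueError("no variant grouping supplied")
    if prior_means is None:
        prior_means = g.prior_means

    gid = g.sample_ids
    pid = pheno.index
    common = gid.intersection(pid)
    if join == "strict":
        if len(common) != len(gid) or len(common) != len(pid):
            raise ValueError(
                "sample ids of genotypes and phenotype do not match "
                "(use join='intersect' to keep the overlap)")
    elif join == "intersect":
        dropped = len(gid.union(pid)) - len(common)
        if dropped:
            logger.info("dropping %d samples outside the id intersection", dropped)
    else:
        raise ValueError(f"unknown join mode {join!r}")
    if len(common) < 2:
        raise ValueError("fewer than 2 samples after id join")

    pheno = pheno.loc[common]
    if response not in pheno.columns:
        raise ValueError(f"response column {response!r} not in phenotype table")
    cov_cols = [c for c in pheno.columns if c != response]
    ok = pheno[cov_cols].notna().all(axis=1) & pheno[response].notna()
    if (~ok).any():
        logger.info("dropping %d samples with missing covariates/response",
                    int((~ok).sum()))
        pheno = pheno.loc[ok]
        common = pheno.index
    y = pheno[response].astype(float)
    if set(np.unique(y)) <= {0.0, 1.0} and family == "binomial":
        pass  # binary response validated

    # dummy-expand categoricals against the alphabetically first level
    parts = []
    for c in cov_cols:
        col = pheno[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            cat = pd.Categorical(col.astype(str), categories=levels)
            dm = pd.get_dummies(cat, prefix=c, drop_first=True, dtype=float)
            dm.index = pheno.index
            parts.append(dm)
        else:
            parts.append(col.astype(float).to_frame(c))
    covariates = pd.concat(parts, axis=1) if parts else \
        pd.DataFrame(index=pheno.index)

    unknown = [v for v in groups.index if v not in g.variant_ids]
    if unknown:
        raise KeyError(f"group map references unknown variants: {unknown}")
    imputed = impute_mean(g)
    dos = imputed.dosages.loc[common]

    uncovered = [v for v in g.variant_ids if v not in set(groups.index)]
    singles: list[str] = []
    gmap: dict[str, list[str]] = {}
    for k in pd.unique(groups.to_numpy()):
        ids = sorted(groups.index[groups == k])
        if len(ids) == 1:
            singles.extend(ids)
        else:
            gmap[str(k)] = ids
    if uncovered:
        if uncovered_action == "covariate":
            singles.extend(uncovered)
        elif uncovered_action == "drop":
            logger.info("dropping %d ungrouped variants: %s",
                        len(uncovered), uncovered)
        else:
            raise ValueError(f"unknown uncovered_action {uncovered_action!r}")
    if singles:
        if singleton_action == "covariate":
            covariates = pd.concat([covariates, dos[singles]], axis=1)
        elif singleton_action == "drop":
            logger.info("dropping %d singleton variants: %s", len(singles), singles)
            singles = []
        else:
            raise ValueError(f"unknown singleton_action {singleton_action!r}")

    grouped_ids = [v for ids in gmap.values() for v in ids]
    mu = (pd.Series(1.0, index=grouped_ids) if prior_means is None
          else pd.Series(prior_means, dtype=float).reindex(grouped_ids).fillna(1.0))
    return ModelFrame(y=y, covariates=covariates, genotypes=dos[grouped_ids],
                      groups=gmap, prior_means=mu, family=family,
                      singletons=singles)
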