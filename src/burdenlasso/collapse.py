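"""Rare-variant collapsing: PROP, DAS and WS gene scores and design assembly.

Variants are split at a MAF threshold (default 5%; sites at exactly the
threshold count as rare).  Rare variants within a gene are collapsed to one
per-individual score:

* **PROP** (proportion coding): the fraction of the gene's rare sites at
  which the individual carries at least one minor allele — bounded in [0, 1].
* **DAS** (data-adaptive sum): the dosage sum after flipping the coding
  (g -> 2 - g) of any rare variant whose marginal effect on the trait is
  significantly negative, so protective and deleterious alleles do not
  cancel.  Flip decisions are re-estimated from each phenotype replicate.
* **WS** (weighted sum): dosages down-weighted by a frequency-based standard
  deviation estimate; common and rare variants are pooled into the single
  gene term, so a WS design carries no separate common-variant columns.

``build_design`` assembles the regression design: covariate columns
(unpenalized), individual common-variant dosages (except under WS), and one
collapsed score per gene — or two when nonsynonymous and synonymous rare
variants are collapsed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigurationError
from .types import NONSYNONYMOUS, SYNONYMOUS, GenotypeSet

logger = logging.getLogger(__name__)

PROP = "PROP"
DAS = "DAS"
WS = "WS"
METHODS = (PROP, DAS, WS)

# feature kinds
COVARIATE = "covariate"
COMMON_VARIANT = "common_variant"
GENE_SCORE = "gene_score"

# penalty classes
UNPENALIZED = "unpenalized"
PENALIZED = "penalized"
PENALIZED_NS = "penalized_ns"
PENALIZED_S = "penalized_s"


@dataclass(frozen=True)
class CollapseConfig:
    rare_maf_threshold: float = 0.05
    method: str = PROP
    das_alpha0: float = 0.1
    ws_frequency_source: str = "all_samples"  # or "unaffected_only"
    split_by_annotation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.rare_maf_threshold <= 0.5:
            raise ConfigurationError("rare_maf_threshold must be in (0, 0.5]")
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown collapsing method {self.method!r}")
        if not 0.0 <= self.das_alpha0 < 1.0:
            raise ConfigurationError("das_alpha0 must be in [0, 1)")
        if self.ws_frequency_source not in ("all_samples", "unaffected_only"):
            raise ConfigurationError("invalid ws_frequency_source")


@dataclass
class CollapsedDesign:
    """Design matrix with per-column metadata and penalty classes.

    ``columns`` has one row per feature with fields ``feature`` (name),
    ``kind`` (covariate / common_variant / gene_score), ``gene``,
    ``annotation`` (nonsynonymous / synonymous / pooled, gene scores only)
    and ``penalty_class``.
    """

    values: np.ndarray
    columns: pd.DataFrame
    individual_ids: list[str]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.columns["feature"])

    def penalty_classes(self) -> np.ndarray:
        return self.columns["penalty_class"].to_numpy()

    def genetic_mask(self) -> np.ndarray:
        return (self.columns["kind"] != COVARIATE).to_numpy()

    def subset(self, mask: np.ndarray) -> "CollapsedDesign":
        return CollapsedDesign(
            values=self.values[:, mask],
            columns=self.columns.loc[mask].reset_index(drop=True),
            individual_ids=self.individual_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.feature_names)


def classify_variants(
    g: GenotypeSet, threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Partition variant ids into (rare, common); MAF <= threshold is rare."""
    rare, common = [], []
    for v, m in zip(g.variant_ids, g.maf):
        (rare if m <= threshold else common).append(v)
    return rare, common


def collapse_prop(g: GenotypeSet, gene: str, rare_set) -> np.ndarray:
    """Carrier proportion: fraction of the gene's rare sites with dosage >= 1."""
    sites = [v for v in g.variants_in_gene(gene) if v in set(rare_set)]
    if not sites:
        raise ConfigurationError(f"gene {gene} has no rare variants to collapse")
    carriers = g.columns(sites) >= 1
    return carriers.mean(axis=1)


def _marginal_flip_mask(
    dosages: np.ndarray, y: np.ndarray, alpha0: float, link: str
) -> np.ndarray:
    """True where the marginal slope is negative with p < alpha0.

    Identity link: exact OLS slope t-test, vectorized across variants.
    Logit link: logistic score test (same sign as the score statistic).
    Monomorphic columns are never flipped.
    """
    n, m = dosages.shape
    if alpha0 <= 0:
        return np.zeros(m, dtype=bool)
    xc = dosages - dosages.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    poly = sxx > 0
    flip = np.zeros(m, dtype=bool)
    if not poly.any():
        return flip
    yc = y - y.mean()
    sxy = xc.T @ yc
    if link == "identity":
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(poly, sxy / sxx, 0.0)
            syy = float((yc**2).sum())
            rss = syy - slope * sxy
            dof = n - 2
            se2 = np.where(poly, rss / np.maximum(dof, 1) / np.where(poly, sxx, 1.0), np.inf)
            tstat = slope / np.sqrt(np.maximum(se2, 1e-300))
        pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
        flip = poly & (slope < 0) & (pval < alpha0)
    elif link == "logit":
        ybar = y.mean()
        v = ybar * (1.0 - ybar) * sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(v > 0, sxy / np.sqrt(np.where(v > 0, v, 1.0)), 0.0)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        flip = poly & (sxy < 0) & (pval < alpha0)
    else:
        raise ConfigurationError(f"unknown link {link!r}")
    return flip


def collapse_das(
    g: GenotypeSet,
    y: np.ndarray,
    gene: str,
    rare_set,
    alpha0: float = 0.1,
    link: str = "identity",
    return_flips: bool = False,
):
    """Data-adaptive sum: dosage sum after flipping significantly negative sites."""
    sites = [v for v in g.variants_in_gene(gene) if v in set(rare_set)]
    if not sites:
        raise ConfigurationError(f"gene {gene} has no rare variants to collapse")
    dosages = g.columns(sites).astype(float)
    flip = _marginal_flip_mask(dosages, np.asarray(y, dtype=float), alpha0, link)
    dosages[:, flip] = 2.0 - dosages[:, flip]
    score = dosages.sum(axis=1)
    if return_flips:
        return score, {v for v, f in zip(sites, flip) if f}
    return score


def ws_weights(
    dosages: np.ndarray, reference_mask: np.ndarray
) -> np.ndarray:
    """Weighted-sum weights w_j = sqrt(n q_j (1 - q_j)).

    q_j = (m_j + 1) / (2 n_u + 2) where m_j is the minor-allele count in the
    frequency-reference group (unaffected individuals for a disease trait,
    everyone for quantitative traits), n_u its size, and n the total number
    of genotyped individuals.
    """
    n = dosages.shape[0]
    n_u = int(reference_mask.sum())
    if n_u == 0:
        raise ConfigurationError("empty frequency-source group for WS weights")
    m = dosages[reference_mask].sum(axis=0)
    q = (m + 1.0) / (2.0 * n_u + 2.0)
    return np.sqrt(n * q * (1.0 - q))


def collapse_ws(
    g: GenotypeSet,
    y: np.ndarray | None,
    gene: str,
    frequency_source: str = "all_samples",
) -> np.ndarray:
    """Weighted sum over ALL variants in the gene (common and rare pooled)."""
    sites = g.variants_in_gene(gene)
    if not sites:
        raise ConfigurationError(f"gene {gene} has no variants")
    dosages = g.columns(sites).astype(float)
    if frequency_source == "unaffected_only":
        if y is None:
            raise ConfigurationError("unaffected_only WS weights require the trait vector")
        ref = np.asarray(y) == 0
    else:
        ref = np.ones(g.n_individuals, dtype=bool)
    w = ws_weights(dosages, ref)
    return (dosages / w).sum(axis=1)


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate encoding; categorical columns one-hot with first level dropped."""
    return pd.get_dummies(covariates, drop_first=True, dtype=float)


def build_design(
    g: GenotypeSet,
    covariates: pd.DataFrame,
    config: CollapseConfig,
    y: np.ndarray | None = None,
    link: str = "identity",
) -> CollapsedDesign:
    """Assemble covariates, common-variant dosages and collapsed gene scores.

    ``y`` is required for DAS (flip orientation) and for WS on a disease
    trait (unaffected frequency reference); PROP designs are phenotype-free.
    Genes without rare variants contribute no score column (their common
    variants still enter individually, except under WS which pools
    everything and drops only genes with no variants at all).
    """
    if list(covariates.index) != list(g.individual_ids):
        raise AlignmentError("covariate individual ids do not match genotypes")
    if config.method in (DAS,) and y is None:
        raise ConfigurationError("DAS collapsing requires the trait vector y")
    if config.method == WS and config.ws_frequency_source == "unaffected_only" and y is None:
        raise ConfigurationError("unaffected-only WS weights require the trait vector y")

    rare, common = classify_variants(g, config.rare_maf_threshold)
    rare_by_gene: dict[str, list[str]] = {}
    for v in rare:
        rare_by_gene.setdefault(g.gene_of[v], []).append(v)

    cov = encode_covariates(covariates)
    names: list[str] = list(cov.columns)
    kinds: list[str] = [COVARIATE] * len(cov.columns)
    genes_meta: list[str] = [""] * len(cov.columns)
    annos: list[str] = [""] * len(cov.columns)
    classes: list[str] = [UNPENALIZED] * len(cov.columns)
    blocks: list[np.ndarray] = [cov.to_numpy(dtype=float)]

    if config.method != WS:
        for v in common:
            names.append(v)
            kinds.append(COMMON_VARIANT)
            genes_meta.append(g.gene_of[v])
            annos.append("")
            classes.append(PENALIZED)
            blocks.append(g.column(v).astype(float)[:, None])

    def add_score(gene: str, score: np.ndarray, annotation: str, penalty: str) -> None:
        suffix = {NONSYNONYMOUS: " (n)", SYNONYMOUS: " (s)"}.get(annotation, "")
        names.append(f"{gene}{suffix}")
        kinds.append(GENE_SCORE)
        genes_meta.append(gene)
        annos.append(annotation)
        classes.append(penalty)
        blocks.append(score[:, None])

    for gene in g.genes:
        if config.method == WS:
            score = collapse_ws(g, y, gene, config.ws_frequency_source)
            add_score(gene, score, "pooled", PENALIZED)
            continue
        gene_rare = rare_by_gene.get(gene, [])
        if not gene_rare:
            logger.warning("gene %s has no rare variants; no collapsed score", gene)
            continue
        strata: list[tuple[list[str], str, str]]
        if config.split_by_annotation:
            ns_sites = [v for v in gene_rare if g.annotation_of[v] == NONSYNONYMOUS]
            s_sites = [v for v in gene_rare if g.annotation_of[v] == SYNONYMOUS]
            strata = [
                (ns_sites, NONSYNONYMOUS, PENALIZED_NS),
                (s_sites, SYNONYMOUS, PENALIZED_S),
            ]
        else:
            strata = [(gene_rare, "pooled", PENALIZED)]
        for sites, annotation, penalty in strata:
            if not sites:
                continue
            if config.method == PROP:
                score = collapse_prop(g, gene, sites)
            else:  # DAS
                score = collapse_das(g, y, gene, sites, config.das_alpha0, link)
            add_score(gene, score, annotation, penalty)

    columns = pd.DataFrame(
        {
            "feature": names,
            "kind": kinds,
            "gene": genes_meta,
            "annotation": annos,
            "penalty_class": classes,
        }
    )
    values = np.hstack(blocks) if blocks else np.empty((g.n_individuals, 0))
    return CollapsedDesign(values=values, columns=columns, individual_ids=list(g.individual_ids))


def covariates_only_design(g: GenotypeSet, covariates: pd.DataFrame) -> CollapsedDesign:
    """Baseline design with covariate columns only (all unpenalized)."""
    if list(covariates.index) != list(g.individual_ids):
        raise AlignmentError("covariate individual ids do not match genotypes")
    cov = encode_covariates(covariates)
    columns = pd.DataFrame(
        {
            "feature": list(cov.columns),
            "kind": [COVARIATE] * len(cov.columns),
            "gene": [""] * len(cov.columns),
            "annotation": [""] * len(cov.columns),
            "penalty_class": [UNPENALIZED] * len(cov.columns),
        }
    )
    return CollapsedDesign(
        values=cov.to_numpy(dtype=float),
        columns=columns,
        individual_ids=list(g.individual_ids),
    )
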