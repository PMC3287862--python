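"""Synthetic mini-exome generator.

Emulates the structure of a workshop-style simulated exome study: a single
fixed genotype matrix dominated by rare variants, fixed covariates, and many
phenotype replicates drawn over those genotypes with a known causal truth set.
Four trait models are provided:

* ``Q1`` — covariates (Age, Smoke) plus causal-variant effects plus noise;
* ``Q2`` — causal-variant effects plus noise, no covariate effects;
* ``Q4`` — covariates (Age, Sex, Smoke) plus noise, no genetic effects;
* ``disease`` — a liability-threshold trait whose liability combines the
  three quantitative traits with an additional set of causal variants.

All causal variants are nonsynonymous and rare.  Genotypes and covariates are
fixed across replicates; only the phenotypes are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import (
    DISEASE_TRAIT,
    NONSYNONYMOUS,
    QUANTITATIVE_TRAITS,
    SYNONYMOUS,
    GenotypeSet,
    ReplicateSet,
    TruthSet,
)

RARE_MAF_DEFAULT = 0.05


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture MAF spectrum: rare-skewed Beta component plus a uniform common tail.

    With probability ``1 - fraction_common`` the allele frequency is
    ``rare_max * Beta(beta_a, beta_b)`` (concentrated well below the
    rare/common boundary); otherwise it is Uniform(common_low, common_high).
    """

    fraction_common: float = 0.1
    beta_a: float = 0.5
    beta_b: float = 6.0
    rare_max: float = RARE_MAF_DEFAULT
    common_low: float = RARE_MAF_DEFAULT
    common_high: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_common <= 1.0:
            raise ConfigurationError("fraction_common must be in [0, 1]")
        if min(self.beta_a, self.beta_b) <= 0:
            raise ConfigurationError("Beta parameters must be positive")
        if not 0.0 < self.common_low <= self.common_high <= 0.5:
            raise ConfigurationError("common range must satisfy 0 < low <= high <= 0.5")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        common = rng.random(size) < self.fraction_common
        freqs = self.rare_max * rng.beta(self.beta_a, self.beta_b, size=size)
        freqs[common] = rng.uniform(self.common_low, self.common_high, size=common.sum())
        return freqs

    def mean(self) -> float:
        rare_mean = self.rare_max * self.beta_a / (self.beta_a + self.beta_b)
        common_mean = 0.5 * (self.common_low + self.common_high)
        return (1 - self.fraction_common) * rare_mean + self.fraction_common * common_mean

    def variance(self) -> float:
        a, b = self.beta_a, self.beta_b
        rare_m = self.rare_max * a / (a + b)
        rare_v = self.rare_max**2 * a * b / ((a + b) ** 2 * (a + b + 1))
        common_m = 0.5 * (self.common_low + self.common_high)
        common_v = (self.common_high - self.common_low) ** 2 / 12.0
        fc = self.fraction_common
        m = self.mean()
        return (
            (1 - fc) * (rare_v + rare_m**2) + fc * (common_v + common_m**2) - m**2
        )


@dataclass(frozen=True)
class PoissonVariants:
    """Per-gene variant count: 1 + Poisson(mean - 1)."""

    mean: float = 8.0

    def __post_init__(self) -> None:
        if self.mean < 1:
            raise ConfigurationError("mean variants per gene must be >= 1")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return 1 + rng.poisson(self.mean - 1.0, size=size)


def _as_maf_spectrum(spec) -> "MafSpectrum | float":
    if isinstance(spec, MafSpectrum):
        return spec
    if isinstance(spec, (int, float)):
        if not 0.0 <= spec <= 0.5:
            raise ConfigurationError("fixed MAF must lie in [0, 0.5]")
        return float(spec)
    raise ConfigurationError(f"invalid MAF spectrum spec: {spec!r}")


def _as_variant_counts(spec) -> "PoissonVariants | int":
    if isinstance(spec, PoissonVariants):
        return spec
    if isinstance(spec, (int, np.integer)):
        if spec < 1:
            raise ConfigurationError("variants per gene must be >= 1")
        return int(spec)
    raise ConfigurationError(f"invalid variants-per-gene spec: {spec!r}")


def simulate_genotypes(
    n_individuals: int,
    n_genes: int,
    variants_per_gene=PoissonVariants(),
    maf_spectrum=MafSpectrum(),
    nonsyn_fraction: float = 0.5,
    seed: int = 0,
) -> GenotypeSet:
    """Draw a fixed genotype matrix under per-variant Hardy–Weinberg sampling.

    Each variant's population allele frequency comes from ``maf_spectrum``
    (a :class:`MafSpectrum` or a fixed float) and dosages are Binomial(2, p)
    per individual.  Columns are re-oriented so the stored dosage always
    counts the *sample* minor allele; the stored MAF is the empirical one.
    """
    if n_individuals < 2:
        raise ConfigurationError("need at least 2 individuals")
    if n_genes < 1:
        raise ConfigurationError("need at least 1 gene")
    if not 0.0 <= nonsyn_fraction <= 1.0:
        raise ConfigurationError("nonsyn_fraction must be in [0, 1]")
    spectrum = _as_maf_spectrum(maf_spectrum)
    counts_spec = _as_variant_counts(variants_per_gene)

    rng = np.random.default_rng(seed)
    if isinstance(counts_spec, int):
        counts = np.full(n_genes, counts_spec)
    else:
        counts = counts_spec.draw(rng, n_genes)
    n_variants = int(counts.sum())

    if isinstance(spectrum, float):
        freqs = np.full(n_variants, spectrum)
    else:
        freqs = spectrum.draw(rng, n_variants)

    dosages = rng.binomial(2, freqs, size=(n_individuals, n_variants))
    # orient toward the sample minor allele
    alt_freq = dosages.mean(axis=0) / 2.0
    flip = alt_freq > 0.5
    dosages[:, flip] = 2 - dosages[:, flip]

    gene_names = [f"G{k + 1:04d}" for k in range(n_genes)]
    variant_ids: list[str] = []
    gene_of: dict[str, str] = {}
    for gene, k in zip(gene_names, counts):
        for j in range(k):
            vid = f"{gene}_V{j + 1}"
            variant_ids.append(vid)
            gene_of[vid] = gene
    is_ns = rng.random(n_variants) < nonsyn_fraction
    annotation_of = {
        v: (NONSYNONYMOUS if ns else SYNONYMOUS) for v, ns in zip(variant_ids, is_ns)
    }

    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    g = GenotypeSet(
        individual_ids=[f"IND{i + 1:05d}" for i in range(n_individuals)],
        variant_ids=variant_ids,
        dosages=dosages.astype(np.int8),
        gene_of=gene_of,
        annotation_of=annotation_of,
        maf=maf,
    )
    return g


def simulate_covariates(n_individuals: int, seed: int = 0) -> pd.DataFrame:
    """Age (years), Sex (0/1), Smoke (0/1) and a categorical population label."""
    rng = np.random.default_rng(seed)
    age = np.clip(np.round(rng.normal(50.0, 10.0, n_individuals)), 18, 90)
    sex = rng.integers(0, 2, n_individuals)
    smoke = (rng.random(n_individuals) < 0.3).astype(int)
    population = rng.choice(["POP1", "POP2", "POP3"], size=n_individuals, p=[0.5, 0.3, 0.2])
    return pd.DataFrame(
        {
            "Age": age,
            "Sex": sex,
            "Smoke": smoke,
            "population": population,
        },
        index=[f"IND{i + 1:05d}" for i in range(n_individuals)],
    )


def choose_causal_variants(
    g: GenotypeSet,
    n_causal_genes: int,
    variants_per_causal_gene: int = 3,
    rare_maf_threshold: float = RARE_MAF_DEFAULT,
    seed: int = 0,
) -> tuple[set[str], dict[str, float]]:
    """Pick causal variants: nonsynonymous, rare, polymorphic, clustered in genes.

    Returns the causal-variant set and raw (unscaled) per-allele effect sizes;
    the phenotype simulator rescales the genetic component to the target
    heritability, so only relative effect magnitudes matter here.
    """
    rng = np.random.default_rng(seed)
    eligible_by_gene: dict[str, list[str]] = {}
    for v in g.variant_ids:
        if g.annotation_of[v] != NONSYNONYMOUS:
            continue
        m = g.maf[g._index[v]]
        if m <= 0 or m > rare_maf_threshold:
            continue
        eligible_by_gene.setdefault(g.gene_of[v], []).append(v)
    candidates = sorted(gene for gene, vs in eligible_by_gene.items() if len(vs) >= 1)
    if len(candidates) < n_causal_genes:
        raise ConfigurationError(
            f"only {len(candidates)} genes have eligible causal variants, "
            f"need {n_causal_genes}"
        )
    genes = rng.choice(candidates, size=n_causal_genes, replace=False)
    causal: set[str] = set()
    effects: dict[str, float] = {}
    for gene in genes:
        pool = eligible_by_gene[gene]
        k = min(variants_per_causal_gene, len(pool))
        picked = rng.choice(pool, size=k, replace=False)
        for v in picked:
            causal.add(v)
            effects[v] = rng.uniform(0.5, 1.5)
    return causal, effects


def _genetic_component(g: GenotypeSet, effects: dict[str, float]) -> np.ndarray:
    if not effects:
        return np.zeros(g.n_individuals)
    variants = sorted(effects)
    beta = np.array([effects[v] for v in variants])
    return g.columns(variants) @ beta


def _genetic_scale(comp: np.ndarray, var_cov: float, h2: float, sigma2_e: float) -> float:
    """Multiplier putting the genetic component at var(G)/var(Y) = h2.

    The noise variance is held fixed and the effects are rescaled, so any
    target in (0, 1) is feasible: var(G) = h2 (var_C + sigma2_e) / (1 - h2).
    """
    var_g = float(np.var(comp))
    if var_g <= 0:
        raise ConfigurationError("genetic component has zero variance")
    if not 0 < h2 < 1:
        raise ConfigurationError("heritability target must be in (0, 1)")
    target = h2 * (var_cov + sigma2_e) / (1.0 - h2)
    return float(np.sqrt(target / var_g))


DEFAULT_COVARIATE_EFFECTS = {
    "Q1": {"Age": 0.02, "Smoke": 0.4},
    "Q4": {"Age": 0.03, "Sex": 0.8, "Smoke": 0.8},
}


def _covariate_component(covariates: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    comp = np.zeros(len(covariates))
    for name, beta in effects.items():
        col = covariates[name].to_numpy(dtype=float)
        comp = comp + beta * (col - col.mean())
    return comp


def simulate_phenotypes(
    g: GenotypeSet,
    truth: TruthSet,
    trait_model: str,
    covariate_effects: dict | None = None,
    heritability_params: dict | None = None,
    R: int = 200,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> ReplicateSet:
    """Draw R phenotype replicates for one trait over fixed genotypes/covariates.

    For quantitative traits the genetic component is rescaled so the realized
    narrow-sense fraction var(G)/var(Y) matches ``heritability_params['h2']``
    in expectation.  For the disease trait, the liability combines internally
    simulated Q1/Q2/Q4 replicates with the trait's own causal variants and is
    thresholded at the quantile implied by ``heritability_params['prevalence']``.
    """
    if covariates is None:
        covariates = simulate_covariates(g.n_individuals, seed=seed)
    if len(covariates) != g.n_individuals:
        raise ConfigurationError("covariate table does not match genotype individuals")
    h2p = dict(heritability_params or {})
    rng = np.random.default_rng(seed)

    if trait_model in QUANTITATIVE_TRAITS:
        y = _simulate_quantitative(
            g, truth, trait_model, covariates, covariate_effects, h2p, R, rng
        )
        return ReplicateSet(covariates=covariates, traits={trait_model: y}, R=R)
    if trait_model == DISEASE_TRAIT:
        traits = _simulate_all_traits(g, truth, covariates, covariate_effects, h2p, R, rng)
        return ReplicateSet(
            covariates=covariates, traits={DISEASE_TRAIT: traits[DISEASE_TRAIT]}, R=R
        )
    raise ConfigurationError(f"unknown trait model {trait_model!r}")


def _simulate_quantitative(g, truth, trait, covariates, covariate_effects, h2p, R, rng):
    h2 = h2p.get("h2", 0.3)
    if covariate_effects is None:
        covariate_effects = DEFAULT_COVARIATE_EFFECTS.get(trait, {})
    cov_comp = _covariate_component(covariates, covariate_effects)
    var_cov = float(np.var(cov_comp))

    effects = truth.effect_sizes.get(trait, {})
    if trait == "Q4" or not effects:
        # covariates-only trait: noise variance set so covariates explain
        # `covariate_fraction` of the total variance (default 0.3)
        frac = h2p.get("covariate_fraction", 0.3)
        if not 0 < frac < 1:
            raise ConfigurationError("covariate_fraction must be in (0, 1)")
        if var_cov <= 0:
            sigma2_e = h2p.get("noise_variance", 1.0)
        else:
            sigma2_e = var_cov * (1.0 - frac) / frac
        gen_comp = np.zeros(g.n_individuals)
    else:
        sigma2_e = h2p.get("noise_variance", 1.0)
        gen_comp = _genetic_component(g, effects)
        gen_comp = gen_comp * _genetic_scale(gen_comp, var_cov, h2, sigma2_e)

    base = cov_comp + gen_comp
    noise = rng.normal(0.0, np.sqrt(sigma2_e), size=(g.n_individuals, R))
    return base[:, None] + noise


def _simulate_all_traits(g, truth, covariates, covariate_effects, h2p, R, rng):
    traits: dict[str, np.ndarray] = {}
    for q in QUANTITATIVE_TRAITS:
        traits[q] = _simulate_quantitative(
            g, truth, q, covariates, covariate_effects, h2p, R, rng
        )
    prevalence = h2p.get("prevalence", 0.3)
    if not 0.0 < prevalence < 1.0:
        raise ConfigurationError("prevalence must be in (0, 1)")
    weights = h2p.get("liability_weights", (0.4, 0.4, 0.2))
    direct = _genetic_component(g, truth.effect_sizes.get(DISEASE_TRAIT, {}))
    if direct.std() > 0:
        direct = direct / direct.std()
    liab_noise_sd = np.sqrt(h2p.get("liability_noise_variance", 1.0))

    disease = np.empty((g.n_individuals, R))
    for r in range(R):
        liab = np.zeros(g.n_individuals)
        for w, q in zip(weights, QUANTITATIVE_TRAITS):
            col = traits[q][:, r]
            liab += w * (col - col.mean()) / col.std()
        liab += direct + rng.normal(0.0, liab_noise_sd, g.n_individuals)
        thresh = np.quantile(liab, 1.0 - prevalence)
        disease[:, r] = (liab > thresh).astype(float)
    traits[DISEASE_TRAIT] = disease
    return traits


@dataclass
class SimulationParams:
    """Bundle of generator settings for a complete synthetic study."""

    n_individuals: int = 1000
    n_genes: int = 100
    variants_per_gene: PoissonVariants | int = field(default_factory=PoissonVariants)
    maf_spectrum: MafSpectrum | float = field(default_factory=MafSpectrum)
    nonsyn_fraction: float = 0.5
    n_causal_genes: int = 5
    variants_per_causal_gene: int = 3
    h2: float = 0.3
    prevalence: float = 0.3
    R: int = 200


def simulate_dataset(
    params: SimulationParams = SimulationParams(), seed: int = 0
) -> tuple[GenotypeSet, ReplicateSet, TruthSet]:
    """Generate a coherent study: genotypes, covariates, all four traits, truth.

    Q1 and Q2 get independent causal-gene draws; the disease trait inherits
    the Q1/Q2 causal variants through its liability and adds its own direct
    causal set.  All randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)
    g = simulate_genotypes(
        params.n_individuals,
        params.n_genes,
        params.variants_per_gene,
        params.maf_spectrum,
        params.nonsyn_fraction,
        seed=int(sub[0]),
    )
    covariates = simulate_covariates(params.n_individuals, seed=int(sub[1]))

    truth = TruthSet()
    for trait, s in zip(("Q1", "Q2", DISEASE_TRAIT), sub[2:5]):
        causal, effects = choose_causal_variants(
            g,
            params.n_causal_genes,
            params.variants_per_causal_gene,
            seed=int(s),
        )
        truth.causal_variants[trait] = causal
        truth.causal_genes[trait] = {g.gene_of[v] for v in causal}
        truth.effect_sizes[trait] = effects
    truth.causal_variants["Q4"] = set()
    truth.causal_genes["Q4"] = set()
    truth.effect_sizes["Q4"] = {}

    # store per-allele effects on the realized trait scale (after the
    # heritability rescaling the phenotype simulator applies)
    for trait in ("Q1", "Q2"):
        effects = truth.effect_sizes[trait]
        comp = _genetic_component(g, effects)
        cov_eff = DEFAULT_COVARIATE_EFFECTS.get(trait, {})
        var_cov = float(np.var(_covariate_component(covariates, cov_eff)))
        scale = _genetic_scale(comp, var_cov, params.h2, 1.0)
        truth.effect_sizes[trait] = {v: e * scale for v, e in effects.items()}

    h2p = {"h2": params.h2, "prevalence": params.prevalence}
    rng_ph = np.random.default_rng(int(sub[5]))
    traits = _simulate_all_traits(g, truth, covariates, None, h2p, params.R, rng_ph)
    reps = ReplicateSet(covariates=covariates, traits=traits, R=params.R)

    # the liability makes Q1/Q2 causal variants causal for disease as well
    truth.causal_variants[DISEASE_TRAIT] = (
        truth.causal_variants[DISEASE_TRAIT]
        | truth.causal_variants["Q1"]
        | truth.causal_variants["Q2"]
    )
    truth.causal_genes[DISEASE_TRAIT] = {
        g.gene_of[v] for v in truth.causal_variants[DISEASE_TRAIT]
    }
    return g, reps, truth
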