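"""Core containers for genotype, phenotype-replicate, and truth-set data.

The data model mirrors a workshop-style simulated mini-exome: one fixed
genotype matrix (individuals x variants, minor-allele dosages 0/1/2) with
per-variant gene assignment and nonsynonymous/synonymous annotation, a set
of phenotype replicates drawn over those fixed genotypes and covariates,
and a truth set recording which variants/genes were made causal for each
trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"

QUANTITATIVE_TRAITS = ("Q1", "Q2", "Q4")
DISEASE_TRAIT = "disease"
TRAITS = QUANTITATIVE_TRAITS + (DISEASE_TRAIT,)


@dataclass
class GenotypeSet:
    """Fixed dosage matrix plus per-variant metadata.

    Attributes
    ----------
    individual_ids : list of str
    variant_ids : list of str
    dosages : ndarray of shape (n_individuals, n_variants), values in {0, 1, 2}
        Minor-allele counts; orientation is always toward the sample minor
        allele, so column means never exceed 1.
    gene_of : dict mapping variant id -> gene symbol
    annotation_of : dict mapping variant id -> "nonsynonymous" | "synonymous"
    maf : ndarray of per-variant minor-allele frequencies in [0, 0.5]
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    gene_of: dict[str, str]
    annotation_of: dict[str, str]
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.maf = np.asarray(self.maf, dtype=float)
        self._index = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._index[variant_id]]

    def columns(self, variant_ids) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.dosages[:, idx]

    @property
    def genes(self) -> list[str]:
        """Gene symbols in order of first appearance along the variant axis."""
        seen: dict[str, None] = {}
        for v in self.variant_ids:
            seen.setdefault(self.gene_of[v], None)
        return list(seen)

    def variants_in_gene(self, gene: str) -> list[str]:
        return [v for v in self.variant_ids if self.gene_of[v] == gene]

    def computed_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is violated."""
        if self.dosages.shape != (self.n_individuals, self.n_variants):
            raise ValueError("dosage matrix shape does not match id lists")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if not np.allclose(self.maf, self.computed_maf(), atol=1e-12):
            raise ValueError("stored maf does not match dosage-derived maf")
        missing = [v for v in self.variant_ids if v not in self.gene_of]
        if missing:
            raise ValueError(f"variants without gene assignment: {missing[:5]}")
        bad = [
            v
            for v in self.variant_ids
            if self.annotation_of.get(v) not in (NONSYNONYMOUS, SYNONYMOUS)
        ]
        if bad:
            raise ValueError(f"variants without valid annotation: {bad[:5]}")


@dataclass
class ReplicateSet:
    """Phenotype replicates over fixed genotypes and covariates.

    ``traits`` maps a trait name to an (n_individuals, R) array; the disease
    trait is binary 0/1.  Covariates (Age, Sex, Smoke, population) are shared
    across replicates — only the phenotypes are resampled.
    """

    covariates: pd.DataFrame
    traits: dict[str, np.ndarray]
    R: int

    def __post_init__(self) -> None:
        self.traits = {k: np.asarray(v, dtype=float) for k, v in self.traits.items()}

    @property
    def n_individuals(self) -> int:
        return len(self.covariates)

    def trait_replicate(self, trait: str, replicate: int) -> np.ndarray:
        return self.traits[trait][:, replicate]

    def validate(self) -> None:
        for name, arr in self.traits.items():
            if arr.shape != (self.n_individuals, self.R):
                raise ValueError(f"trait {name} has shape {arr.shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"trait {name} contains non-finite values")
            if name == DISEASE_TRAIT and not np.isin(arr, (0.0, 1.0)).all():
                raise ValueError("disease trait must be binary 0/1")


@dataclass
class TruthSet:
    """Causal variants/genes per trait, with per-variant effect sizes."""

    causal_variants: dict[str, set[str]] = field(default_factory=dict)
    causal_genes: dict[str, set[str]] = field(default_factory=dict)
    effect_sizes: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, g: GenotypeSet) -> None:
        for trait, variants in self.causal_variants.items():
            for v in variants:
                if g.annotation_of[v] != NONSYNONYMOUS:
                    raise ValueError(f"causal variant {v} is not nonsynonymous")
            genes = {g.gene_of[v] for v in variants}
            if genes != self.causal_genes.get(trait, set()):
                raise ValueError(
                    f"causal genes for {trait} are not the genes of its causal variants"
                )
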