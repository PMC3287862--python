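import numpy as np
import pytest

from burdenlasso import (
    CollapseConfig,
    GenotypeSet,
    SimulationParams,
    TruthSet,
    simulate_dataset,
)
from burdenlasso.types import NONSYNONYMOUS, SYNONYMOUS


def make_genotypes(dosages, genes, annotations, individual_ids=None):
    """Build a GenotypeSet from a dense dosage array and per-variant metadata."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    variant_ids = [f"v{j + 1}" for j in range(m)]
    freq = dosages.mean(axis=0) / 2.0
    return GenotypeSet(
        individual_ids=individual_ids or [f"i{k + 1}" for k in range(n)],
        variant_ids=variant_ids,
        dosages=dosages,
        gene_of=dict(zip(variant_ids, genes)),
        annotation_of=dict(zip(variant_ids, annotations)),
        maf=np.minimum(freq, 1 - freq),
    )


@pytest.fixture
def toy_genotypes():
    """8 individuals; gene A: 5 rare sites; gene B: 1 rare + 1 common site.

    Column MAFs: v1..v5 and v6 are rare (<= 0.05 boundary set by design
    threshold in tests via small-sample frequencies), v7 is common.
    """
    dosages = np.array(
        [
            # v1 v2 v3 v4 v5 | v6 v7
            [1, 0, 2, 0, 0, 0, 1],
            [0, 0, 0, 0, 0, 1, 2],
            [0, 1, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 1],
            [0, 0, 0, 1, 0, 0, 2],
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 1],
            [0, 0, 0, 0, 0, 0, 1],
        ]
    )
    genes = ["A", "A", "A", "A", "A", "B", "B"]
    annos = [
        NONSYNONYMOUS,
        SYNONYMOUS,
        NONSYNONYMOUS,
        NONSYNONYMOUS,
        SYNONYMOUS,
        NONSYNONYMOUS,
        SYNONYMOUS,
    ]
    return make_genotypes(dosages, genes, annos)


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic simulated study shared across tests."""
    params = SimulationParams(
        n_individuals=300, n_genes=25, n_causal_genes=4, h2=0.3, R=10
    )
    return simulate_dataset(params, seed=42)
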